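"""Synthetic fixtures with the statistical structure the method assumes.

Generates well-separated subtype centroids, archetypal samples sitting on
top of them, borderline ("gray-area") samples between two centroids,
heteroscedastic repeated measures, and labeled cohorts with a truth
manifest.  Expression values live on a log-scale-like range of [0, 10],
matching the magnitude of qPCR-style relative expression, and per-subtype
error slopes differ so that the sigma surface genuinely depends on both
expression level and subtype — the feature the cohort error model exists to
capture.  No attempt is made to imitate real centroid values or gene names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import rho_to_centroids
from .errors import ValidationError
from .io import CentroidSet, ExpressionMatrix, ExpressionProfile, RepeatedMeasuresSet

DEFAULT_SUBTYPES = (
    "Luminal A", "Luminal B", "HER2-enriched", "Basal-like", "Normal-like"
)

# affine sigma(e) = intercept + slope * e per subtype; the HER2-like subtype
# gets the largest error at low expression (weakly expressed genes are the
# hardest to quantify there), the Luminal A-like subtype the smallest.
DEFAULT_SIGMA_PARAMS: dict[str, tuple[float, float]] = {
    "Luminal A": (0.05, 0.004),
    "Luminal B": (0.07, 0.005),
    "HER2-enriched": (0.18, -0.008),
    "Basal-like": (0.09, 0.006),
    "Normal-like": (0.08, 0.005),
}
_FALLBACK_SIGMA = (0.08, 0.005)

EXPRESSION_RANGE = (0.0, 10.0)


def affine_sigma(subtype: str) -> Callable[[float], float]:
    """Default heteroscedastic error profile for a subtype (nonnegative affine)."""
    a, b = DEFAULT_SIGMA_PARAMS.get(subtype, _FALLBACK_SIGMA)
    return lambda e: max(a + b * float(e), 1e-6)


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 50
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    seed: int = 0
    separation_rho: float = 0.3     # max pairwise Spearman rho between centroids
    jitter_sd: float = 0.1          # archetype jitter: 1% of the dynamic range
    borderline_mix: float = 0.5     # default lambda for gray-area samples
    n_replicates: int = 12
    sigma_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValidationError("need >=3 genes")
        if not 0.0 <= self.borderline_mix <= 1.0:
            raise ValidationError("borderline_mix must be in [0, 1]")
        lo, hi = EXPRESSION_RANGE
        for name, (a, b) in self.sigma_params.items():
            if min(a + b * lo, a + b * hi) < 0:
                raise ValidationError(f"sigma function for {name!r} goes negative")

    def sigma_function(self, subtype: str) -> Callable[[float], float]:
        a, b = self.sigma_params.get(subtype, _FALLBACK_SIGMA)
        return lambda e: max(a + b * float(e), 1e-6)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(1, self.n_genes + 1)]


def _rng(spec: SyntheticSpec, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed % 2**31, *salt]))


def _random_involution(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random fixed-point-free pairing of indices (one fixed point if n is odd)."""
    order = rng.permutation(n)
    perm = np.arange(n)
    for k in range(0, n - 1, 2):
        i, j = order[k], order[k + 1]
        perm[i], perm[j] = j, i
    return perm


def make_centroids(spec: SyntheticSpec, max_attempts: int = 1000) -> CentroidSet:
    """K centroid profiles with pairwise Spearman rho below the separation threshold.

    The first centroid is a uniform draw over the expression range; each
    subsequent centroid applies a seeded random involutive gene swap to the
    previous one, with rejection until the candidate is sufficiently
    uncorrelated with every accepted centroid.  Because the swap is an
    involution, adjacent centroids are exchangeable: the value-space midpoint
    between them correlates *exactly* equally with both, so gray-area samples
    mixed from adjacent pairs are maximally ambiguous by construction.
    Deterministic for a fixed spec seed.
    """
    lo, hi = EXPRESSION_RANGE
    rng = _rng(spec, 1)
    accepted: list[np.ndarray] = [rng.uniform(lo, hi, size=spec.n_genes)]
    attempts = 0
    while len(accepted) < len(spec.subtypes):
        if attempts >= max_attempts:
            raise ValidationError(
                f"could not reach pairwise rho <= {spec.separation_rho} "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        perm = _random_involution(rng, spec.n_genes)
        cand = accepted[-1][perm]
        mat = np.column_stack(accepted)
        rho = rho_to_centroids(cand, mat)[:, 0]
        if np.abs(rho).max() > spec.separation_rho:
            continue
        accepted.append(cand)
    df = pd.DataFrame(
        np.column_stack(accepted), index=spec.gene_ids, columns=list(spec.subtypes)
    )
    return CentroidSet(df)


def make_archetype(
    centroid: pd.Series, spec: SyntheticSpec, *, sample_id: str | None = None,
    jitter_sd: float | None = None, salt: int = 2,
) -> ExpressionProfile:
    """A sample sitting essentially on a centroid: centroid plus small jitter."""
    jitter = spec.jitter_sd if jitter_sd is None else jitter_sd
    rng = _rng(spec, salt, _name_salt(centroid.name))
    values = centroid.to_numpy(dtype=float) + rng.standard_normal(len(centroid)) * jitter
    sid = sample_id or f"archetype_{centroid.name}"
    return ExpressionProfile(sid, pd.Series(values, index=centroid.index))


def make_borderline(
    c1: pd.Series, c2: pd.Series, lam: float, spec: SyntheticSpec, *,
    sample_id: str | None = None, jitter_sd: float | None = None, salt: int = 3,
) -> ExpressionProfile:
    """A gray-area sample: value-wise mix lam*c1 + (1-lam)*c2 plus jitter."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("lambda must be in [0, 1]")
    jitter = spec.jitter_sd if jitter_sd is None else jitter_sd
    rng = _rng(spec, salt, _name_salt(c1.name), _name_salt(c2.name), int(lam * 10_000))
    values = (
        lam * c1.to_numpy(dtype=float)
        + (1.0 - lam) * c2.to_numpy(dtype=float)
        + rng.standard_normal(len(c1)) * jitter
    )
    sid = sample_id or f"borderline_{c1.name}_{c2.name}_{lam:g}"
    return ExpressionProfile(sid, pd.Series(values, index=c1.index))


def make_repeated_measures(
    parent: ExpressionProfile,
    sigma_function: Callable[[float], float],
    n_replicates: int = 12,
    seed: int = 0,
    *,
    archetype_id: str | None = None,
    subtype: str = "",
) -> RepeatedMeasuresSet:
    """Replicate measurements of one sample under heteroscedastic Gaussian error."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 4]))
    values = parent.values.to_numpy(dtype=float)
    sig = np.array([sigma_function(v) for v in values], dtype=float)
    reps = values[:, None] + rng.standard_normal((values.size, n_replicates)) * sig[:, None]
    df = pd.DataFrame(
        reps,
        index=parent.values.index,
        columns=[f"rep{j:02d}" for j in range(1, n_replicates + 1)],
    )
    return RepeatedMeasuresSet(archetype_id or parent.sample_id, subtype, df)


def make_cohort(
    spec: SyntheticSpec,
    n_archetypal: int,
    n_borderline: int,
    *,
    centroids: CentroidSet | None = None,
    borderline_jitter: float | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """A labeled mixture of archetypal and gray-area samples plus a truth manifest.

    Archetypal samples cycle through the subtypes; borderline samples cycle
    through adjacent centroid pairs at the spec's mixing weight.  The
    manifest records, per sample, the generating kind, source subtype(s),
    lambda, and the seed salt, enabling parameter-recovery tests.
    """
    cents = centroids or make_centroids(spec)
    names = cents.subtype_names
    profiles: list[ExpressionProfile] = []
    rows: list[dict] = []
    for i in range(n_archetypal):
        subtype = names[i % len(names)]
        p = make_archetype(
            cents.profiles[subtype], spec, sample_id=f"arch_{i:03d}_{subtype}",
            salt=100 + i,
        )
        profiles.append(p)
        rows.append({
            "sample_id": p.sample_id, "kind": "archetypal", "subtype_1": subtype,
            "subtype_2": "", "lambda": 1.0, "salt": 100 + i,
        })
    for i in range(n_borderline):
        s1 = names[i % len(names)]
        s2 = names[(i + 1) % len(names)]
        p = make_borderline(
            cents.profiles[s1], cents.profiles[s2], spec.borderline_mix, spec,
            sample_id=f"gray_{i:03d}_{s1}_{s2}", jitter_sd=borderline_jitter,
            salt=200 + i,
        )
        profiles.append(p)
        rows.append({
            "sample_id": p.sample_id, "kind": "borderline", "subtype_1": s1,
            "subtype_2": s2, "lambda": spec.borderline_mix, "salt": 200 + i,
        })
    matrix = ExpressionMatrix(
        pd.DataFrame(
            {p.sample_id: p.values for p in profiles}, index=spec.gene_ids
        )
    )
    manifest = pd.DataFrame(rows)
    return matrix, manifest


def make_archetype_suite(
    spec: SyntheticSpec, *, subtypes: Sequence[str] | None = None,
    centroids: CentroidSet | None = None,
) -> tuple[CentroidSet, list[tuple[ExpressionProfile, str, RepeatedMeasuresSet]]]:
    """Centroids plus one archetype and its replicate set per requested subtype.

    Convenience for the characterize stage: returns the inputs of the error
    model exactly as the study design collects them (one well-measured
    sample per subtype, replicated n_replicates times).
    """
    cents = centroids or make_centroids(spec)
    use = list(subtypes) if subtypes is not None else cents.subtype_names
    out = []
    for k, subtype in enumerate(use):
        parent = make_archetype(cents.profiles[subtype], spec, salt=10 + k)
        rm = make_repeated_measures(
            parent, spec.sigma_function(subtype), spec.n_replicates,
            seed=spec.seed + 17 * (k + 1), archetype_id=parent.sample_id,
            subtype=subtype,
        )
        out.append((parent, subtype, rm))
    return cents, out


def _name_salt(name) -> int:
    import hashlib

    return int.from_bytes(
        hashlib.blake2b(str(name).encode(), digest_size=4).digest(), "big"
    ) % 2**31
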