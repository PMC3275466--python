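"""Seeded Monte Carlo engine for classification-reproducibility estimates.

Each simulated sample perturbs every gene of a parent sample independently
with Gaussian measurement error: value ~ Normal(parent value, sigma_gene).
Because every Gaussian is centered on the parent's own value, genes that are
coordinately up- or down-regulated stay so in the simulated samples — only
the *measurement error* is assumed independent across genes, not the
expression values themselves.  Simulated samples are classified against the
centroid set and tallied; the fraction classified like the parent
(``prop_identical``) estimates the classification's reproducibility under
the assay's intrinsic error.

Randomness is organized as counter-based per-parent substreams derived from
(master seed, parent id, scenario), so each parent's tally is bit-identical
regardless of batch composition, processing order, or parallel execution.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import classify_sample, rho_to_centroids
from .errors import SimulationError, ValidationError
from .error_model import Scenario, SigmaModel
from .io import CentroidSet, ExpressionMatrix, ExpressionProfile, align_genes

logger = logging.getLogger(__name__)

UNCLASSIFIABLE = "unclassifiable"

SigmaSource = Mapping[str, float] | Callable[[str, float], float] | Sequence[float] | np.ndarray


@dataclass(frozen=True)
class SimulationConfig:
    n_sims: int = 100_000
    master_seed: int = 0
    scenario: Scenario = Scenario.AVERAGE
    strict: bool = True          # abort on an unclassifiable simulated sample
    chunk_size: int = 50_000     # bound peak memory of the vectorized draw

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")


@dataclass(frozen=True)
class ReproducibilityResult:
    parent_sample_id: str
    parent_subtype: str
    counts_by_subtype: dict[str, int]
    n_sims: int
    scenario: str
    seed: int

    @property
    def prop_identical(self) -> float:
        return self.counts_by_subtype.get(self.parent_subtype, 0) / self.n_sims

    def __post_init__(self) -> None:
        if sum(self.counts_by_subtype.values()) != self.n_sims:
            raise ValidationError("tally does not sum to n_sims")


def _substream(master_seed: int, parent_id: str, scenario: str) -> tuple[np.random.Generator, int]:
    """Per-(parent, scenario) RNG stream, independent of batch order."""
    h = int.from_bytes(
        hashlib.blake2b(f"{parent_id}|{scenario}".encode(), digest_size=4).digest(), "big"
    ) % 2**31
    seed_seq = np.random.SeedSequence([master_seed % 2**31, h])
    return np.random.default_rng(seed_seq), h


def _resolve_sigma(parent_genes: Sequence[str], values: np.ndarray, sigma: SigmaSource) -> np.ndarray:
    if callable(sigma):
        vec = np.array([sigma(g, v) for g, v in zip(parent_genes, values)], dtype=float)
    elif isinstance(sigma, Mapping):
        missing = [g for g in parent_genes if g not in sigma]
        if missing:
            raise ValidationError(f"sigma undefined for genes: {missing[:5]}")
        vec = np.array([sigma[g] for g in parent_genes], dtype=float)
    else:
        vec = np.asarray(sigma, dtype=float)
        if vec.shape != (len(parent_genes),):
            raise ValidationError("sigma vector length does not match the gene set")
    if (vec < 0).any() or not np.isfinite(vec).all():
        raise ValidationError("sigma values must be finite and >= 0")
    return vec


def simulate_one(
    parent: ExpressionProfile, sigma_for_gene: SigmaSource, rng: np.random.Generator
) -> ExpressionProfile:
    """Draw one simulated sample: each gene Normal(parent value, sigma_gene)."""
    values = parent.values.to_numpy(dtype=float)
    sig = _resolve_sigma(parent.gene_ids, values, sigma_for_gene)
    noisy = values + rng.standard_normal(values.size) * sig
    return ExpressionProfile(
        parent.sample_id, pd.Series(noisy, index=parent.values.index)
    )


def run_reproducibility(
    parent: ExpressionProfile,
    parent_subtype: str,
    centroids: CentroidSet,
    sigma_for_gene: SigmaSource,
    config: SimulationConfig,
) -> ReproducibilityResult:
    """Simulate ``n_sims`` perturbed copies of one parent and tally assignments.

    The tally always conserves: sum of counts over subtypes (plus, in lenient
    mode, an ``unclassifiable`` bucket) equals ``n_sims``.
    """
    # validates the parent is classifiable before burning simulation time
    classify_sample(parent, centroids)
    aligned = align_genes(parent, centroids)
    x = aligned.sample_values
    sig = _resolve_sigma(aligned.gene_ids, x, sigma_for_gene)
    scenario_name = str(getattr(config.scenario, "value", config.scenario))
    rng, stream_id = _substream(config.master_seed, parent.sample_id, scenario_name)

    names = aligned.subtype_names
    counts = np.zeros(len(names), dtype=np.int64)
    n_unclassifiable = 0
    remaining = config.n_sims
    while remaining > 0:
        m = min(remaining, config.chunk_size)
        draws = x[:, None] + rng.standard_normal((x.size, m)) * sig[:, None]
        rho = rho_to_centroids(draws, aligned.centroid_matrix)
        bad = np.isnan(rho[0])
        if bad.any():
            if config.strict:
                raise SimulationError(
                    f"parent {parent.sample_id!r}: {int(bad.sum())} simulated samples "
                    "had zero rank variance (strict mode)"
                )
            n_unclassifiable += int(bad.sum())
            rho = rho[:, ~bad]
        if rho.shape[1]:
            assigned = np.argmax(rho, axis=0)  # first max: declaration order
            counts += np.bincount(assigned, minlength=len(names))
        remaining -= m

    tally = {name: int(c) for name, c in zip(names, counts)}
    if n_unclassifiable:
        tally[UNCLASSIFIABLE] = n_unclassifiable
    return ReproducibilityResult(
        parent_sample_id=parent.sample_id,
        parent_subtype=parent_subtype,
        counts_by_subtype=tally,
        n_sims=config.n_sims,
        scenario=scenario_name,
        seed=stream_id,
    )


@dataclass(frozen=True)
class CohortRun:
    results: list[ReproducibilityResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (sample_id, reason)


def run_cohort(
    samples: ExpressionMatrix,
    centroids: CentroidSet,
    model: SigmaModel,
    config: SimulationConfig,
    scenarios: Sequence[Scenario | str] = (Scenario.AVERAGE,),
) -> CohortRun:
    """Reproducibility of every cohort sample under one or more error scenarios.

    Each parent's original classification selects the sigma curve used to
    perturb it.  Parents whose subtype has no fitted curve (and no pooled
    fallback) are skipped with a warning and recorded, not silently dropped.
    """
    scenario_list = [Scenario(s) for s in scenarios]
    results: list[ReproducibilityResult] = []
    skipped: list[tuple[str, str]] = []
    for profile in samples.profiles():
        res = classify_sample(profile, centroids)
        subtype = res.assigned_subtype
        if res.is_tie:
            logger.warning(
                "parent %s: tied original classification; simulating as %s",
                profile.sample_id, subtype,
            )
        try:
            model.curve_for(subtype)
        except ValidationError as exc:
            logger.warning("skipping parent %s: %s", profile.sample_id, exc)
            skipped.append((profile.sample_id, str(exc)))
            continue
        values = profile.values.to_numpy(dtype=float)
        for scenario in scenario_list:
            sigma_vec = model.predict(values, subtype, scenario)
            cfg = replace(config, scenario=scenario)
            results.append(
                run_reproducibility(profile, subtype, centroids, sigma_vec, cfg)
            )
    return CohortRun(results=results, skipped=skipped)


# --- flat-file round trip for the CLI and reports -------------------------

def results_to_frame(results: Sequence[ReproducibilityResult]) -> pd.DataFrame:
    subtypes: list[str] = []
    for r in results:
        for s in r.counts_by_subtype:
            if s not in subtypes:
                subtypes.append(s)
    rows = []
    for r in results:
        row = {
            "parent_sample_id": r.parent_sample_id,
            "parent_subtype": r.parent_subtype,
            "scenario": r.scenario,
            "n_sims": r.n_sims,
            "seed": r.seed,
        }
        for s in subtypes:
            row[f"count_{s}"] = r.counts_by_subtype.get(s, 0)
        row["prop_identical"] = r.prop_identical
        rows.append(row)
    return pd.DataFrame(rows)


def results_from_frame(df: pd.DataFrame) -> list[ReproducibilityResult]:
    count_cols = [c for c in df.columns if c.startswith("count_")]
    out = []
    for _, row in df.iterrows():
        counts = {c[len("count_"):]: int(row[c]) for c in count_cols}
        out.append(
            ReproducibilityResult(
                parent_sample_id=str(row["parent_sample_id"]),
                parent_subtype=str(row["parent_subtype"]),
                counts_by_subtype=counts,
                n_sims=int(row["n_sims"]),
                scenario=str(row["scenario"]),
                seed=int(row["seed"]),
            )
        )
    return out


def write_results_tsv(results: Sequence[ReproducibilityResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results_tsv(path) -> list[ReproducibilityResult]:
    return results_from_frame(pd.read_csv(path, sep="\t"))
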