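"""Measurement-error characterization and the sigma(expression, subtype) surface.

Two error models are supported, mirroring the two stages of the study design:

* **Archetype mode** — per-gene Gaussians fitted directly to replicate
  measurements of an archetypal sample (mean and n-1 standard deviation of
  the replicates).  Pooling the median-centered replicates across archetypes
  gives enough points per gene to judge the Gaussian assumption by
  descriptive diagnostics.

* **Cohort mode** — a smooth heteroscedastic surface: one locally weighted
  linear regression (loess, span 0.75, degree 1, robust bisquare
  reweighting) of replicate standard deviation on mean expression per
  subtype, because the error magnitude depends on both the expression level
  and the subtype (weakly expressed genes are harder to quantify, and
  subtypes differ in which genes they express weakly).  A seeded bootstrap
  gives a 95% confidence band around each fitted curve; the lower band,
  fit, and upper band define best-, average- and worst-case scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .io import RepeatedMeasuresSet

POOLED_KEY = "__pooled__"


class Scenario(str, Enum):
    """Which band of the sigma surface drives the simulation."""

    BEST = "best"        # lower 95% CI band: smallest error
    AVERAGE = "average"  # the fitted curve
    WORST = "worst"      # upper 95% CI band: largest error


@dataclass(frozen=True)
class GeneGaussian:
    """Gaussian error model of one gene in one archetypal sample."""

    gene_id: str
    archetype_id: str
    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma < 0 or not np.isfinite(self.mu):
            raise ValidationError(f"invalid Gaussian for gene {self.gene_id!r}")
        if self.n < 3:
            raise ValidationError(f"gene {self.gene_id!r}: need >=3 replicates, got {self.n}")


@dataclass(frozen=True)
class PooledGeneDistribution:
    """Median-centered replicate values of one gene, pooled across archetypes."""

    gene_id: str
    centered_points: np.ndarray


@dataclass(frozen=True)
class NormalitySummary:
    gene_id: str
    n: int
    skewness: float
    excess_kurtosis: float
    shapiro_p: float


def fit_gene_gaussians(rm: RepeatedMeasuresSet) -> list[GeneGaussian]:
    """Per-gene mean and sample standard deviation (n-1 denominator) of replicates."""
    out = []
    vals = rm.replicates.to_numpy(dtype=float)
    mus = vals.mean(axis=1)
    sigmas = vals.std(axis=1, ddof=1)
    for gene, mu, sigma in zip(rm.gene_ids, mus, sigmas):
        out.append(GeneGaussian(gene, rm.archetype_id, float(mu), float(sigma), rm.n_replicates))
    return out


def pool_median_centered(rms: Sequence[RepeatedMeasuresSet]) -> list[PooledGeneDistribution]:
    """Center each archetype's replicates by its per-gene median, then concatenate.

    Centering removes the subtype-specific expression level so the pooled
    points describe only the measurement error; pooling across archetypes is
    what makes the per-gene point count large enough to judge the error's
    distributional shape.
    """
    if not rms:
        raise ValidationError("need at least one repeated-measures set")
    genes = rms[0].gene_ids
    for rm in rms[1:]:
        if rm.gene_ids != genes:
            raise ValidationError(
                f"archetype {rm.archetype_id!r} has a different gene set than "
                f"{rms[0].archetype_id!r}"
            )
    pooled = []
    for gene in genes:
        parts = []
        for rm in rms:
            v = rm.replicates.loc[gene].to_numpy(dtype=float)
            parts.append(v - np.median(v))
        pooled.append(PooledGeneDistribution(gene, np.concatenate(parts)))
    return pooled


def normality_summary(pooled: PooledGeneDistribution) -> NormalitySummary:
    """Descriptive Gaussianity diagnostics; informational, never gates the pipeline."""
    x = np.asarray(pooled.centered_points, dtype=float)
    if x.size < 8:
        raise ValidationError(f"gene {pooled.gene_id!r}: need >=8 points, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValidationError(f"gene {pooled.gene_id!r}: constant input, diagnostics undefined")
    w = stats.shapiro(x)
    return NormalitySummary(
        gene_id=pooled.gene_id,
        n=int(x.size),
        skewness=float(stats.skew(x)),
        excess_kurtosis=float(stats.kurtosis(x)),
        shapiro_p=float(w.pvalue),
    )


def gaussians_to_points(
    gaussians: Iterable[GeneGaussian], subtype_by_archetype: dict[str, str]
) -> pd.DataFrame:
    """Arrange per-gene Gaussians as (expression, sigma, subtype) training points."""
    rows = [
        {
            "expression": g.mu,
            "sigma": g.sigma,
            "subtype": subtype_by_archetype[g.archetype_id],
        }
        for g in gaussians
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SigmaFitConfig:
    span: float = 0.75          # loess smoothing fraction
    degree: int = 1             # local linear fit
    robust_iters: int = 3       # Tukey-bisquare reweighting passes ("symmetric" family)
    n_boot: int = 500           # bootstrap resamples for the CI band
    ci_level: float = 0.95
    grid_size: int = 100
    floor: float = 1e-6         # hard lower bound on predicted sigma
    seed: int = 0
    pooled_fallback: bool = False  # also fit a curve pooled over all subtypes


@dataclass(frozen=True)
class SubtypeCurve:
    grid: np.ndarray    # query grid over the training range
    lower: np.ndarray   # lower 95% band
    fit: np.ndarray     # loess fit
    upper: np.ndarray   # upper 95% band
    train_min: float
    train_max: float

    def band(self, scenario: Scenario) -> np.ndarray:
        return {Scenario.BEST: self.lower, Scenario.AVERAGE: self.fit,
                Scenario.WORST: self.upper}[scenario]


def _loess_curve(x: np.ndarray, y: np.ndarray, cfg: SigmaFitConfig):
    """Fit loess and return an evaluator with linear boundary extrapolation.

    Outside the training range the curve is continued by the straight line
    through the two outermost fitted points (the local linear fit at the
    boundary), matching direct-surface extrapolation of a degree-1 smoother.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    if ux.size < 2:
        c = float(ys.mean())
        return lambda q: np.full_like(np.asarray(q, dtype=float), c)
    fitted = lowess(ys, xs, frac=cfg.span, it=cfg.robust_iters, return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x to their mean fitted value for interpolation
    gx, first = np.unique(fx, return_index=True)
    gy = np.array([fy[fx == v].mean() for v in gx])

    def evaluate(q):
        q = np.asarray(q, dtype=float)
        out = np.interp(q, gx, gy)
        if gx.size >= 2:
            lo_slope = (gy[1] - gy[0]) / (gx[1] - gx[0])
            hi_slope = (gy[-1] - gy[-2]) / (gx[-1] - gx[-2])
            below = q < gx[0]
            above = q > gx[-1]
            out = np.where(below, gy[0] + lo_slope * (q - gx[0]), out)
            out = np.where(above, gy[-1] + hi_slope * (q - gx[-1]), out)
        return out

    return evaluate


@dataclass(frozen=True)
class SigmaModel:
    """Fitted sigma(expression) curves per subtype with 95% CI scenario bands."""

    curves: dict[str, SubtypeCurve]
    config: SigmaFitConfig = field(default_factory=SigmaFitConfig)

    @property
    def subtypes(self) -> list[str]:
        return [s for s in self.curves if s != POOLED_KEY]

    def curve_for(self, subtype: str) -> SubtypeCurve:
        if subtype in self.curves:
            return self.curves[subtype]
        if POOLED_KEY in self.curves:
            return self.curves[POOLED_KEY]
        raise ValidationError(
            f"no sigma curve for subtype {subtype!r} and no pooled fallback; "
            f"known subtypes: {self.subtypes}"
        )

    def predict(self, expression, subtype: str, scenario: Scenario = Scenario.AVERAGE):
        """Predicted sigma at the given expression value(s), floor-clipped."""
        curve = self.curve_for(subtype)
        scenario = Scenario(scenario)
        band = curve.band(scenario)
        q = np.asarray(expression, dtype=float)
        out = np.interp(q, curve.grid, band)
        g, b = curve.grid, band
        lo_slope = (b[1] - b[0]) / (g[1] - g[0])
        hi_slope = (b[-1] - b[-2]) / (g[-1] - g[-2])
        out = np.where(q < g[0], b[0] + lo_slope * (q - g[0]), out)
        out = np.where(q > g[-1], b[-1] + hi_slope * (q - g[-1]), out)
        out = np.maximum(out, self.config.floor)
        return float(out) if np.isscalar(expression) else out

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                k: getattr(self.config, k)
                for k in ("span", "degree", "robust_iters", "n_boot", "ci_level",
                          "grid_size", "floor", "seed", "pooled_fallback")
            },
            "curves": {
                name: {
                    "grid": c.grid.tolist(),
                    "lower": c.lower.tolist(),
                    "fit": c.fit.tolist(),
                    "upper": c.upper.tolist(),
                    "train_range": [c.train_min, c.train_max],
                }
                for name, c in self.curves.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmaModel":
        cfg = SigmaFitConfig(**d["config"])
        curves = {
            name: SubtypeCurve(
                grid=np.asarray(c["grid"], dtype=float),
                lower=np.asarray(c["lower"], dtype=float),
                fit=np.asarray(c["fit"], dtype=float),
                upper=np.asarray(c["upper"], dtype=float),
                train_min=float(c["train_range"][0]),
                train_max=float(c["train_range"][1]),
            )
            for name, c in d["curves"].items()
        }
        return cls(curves=curves, config=cfg)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SigmaModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_sigma_model(points, config: SigmaFitConfig | None = None) -> SigmaModel:
    """Fit per-subtype loess curves of sigma on expression with bootstrap CI bands.

    ``points`` is a DataFrame with columns (expression, sigma, subtype) or an
    iterable of such triples — typically one point per gene per archetype.
    Bands are reordered pointwise so lower <= fit <= upper everywhere.
    """
    cfg = config or SigmaFitConfig()
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["expression", "sigma", "subtype"])
    if (points["sigma"] < 0).any():
        raise ValidationError("sigma training points must be nonnegative")
    groups: dict[str, pd.DataFrame] = {
        str(name): g for name, g in points.groupby("subtype", sort=False)
    }
    if cfg.pooled_fallback:
        groups[POOLED_KEY] = points
    curves: dict[str, SubtypeCurve] = {}
    for idx, (subtype, g) in enumerate(groups.items()):
        if len(g) < 10:
            raise ValidationError(
                f"subtype {subtype!r}: {len(g)} sigma points, need >=10 for a loess fit"
            )
        x = g["expression"].to_numpy(dtype=float)
        y = g["sigma"].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), cfg.grid_size)
        fit = _loess_curve(x, y, cfg)(grid)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % 2**31, idx]))
        boots = np.empty((cfg.n_boot, grid.size))
        for b in range(cfg.n_boot):
            take = rng.integers(0, x.size, size=x.size)
            boots[b] = _loess_curve(x[take], y[take], cfg)(grid)
        alpha = 100.0 * (1.0 - cfg.ci_level) / 2.0
        lower = np.percentile(boots, alpha, axis=0)
        upper = np.percentile(boots, 100.0 - alpha, axis=0)
        lower = np.minimum(lower, fit)
        upper = np.maximum(upper, fit)
        curves[subtype] = SubtypeCurve(
            grid=grid, lower=lower, fit=fit, upper=upper,
            train_min=float(x.min()), train_max=float(x.max()),
        )
    return SigmaModel(curves=curves, config=cfg)


def predict_sigma(
    model: SigmaModel, expression, subtype: str, scenario: Scenario = Scenario.AVERAGE
):
    """Functional alias for :meth:`SigmaModel.predict`."""
    return model.predict(expression, subtype, scenario)


def gene_gaussians_to_frame(gaussians: Iterable[GeneGaussian]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": g.gene_id, "archetype_id": g.archetype_id,
             "mu": g.mu, "sigma": g.sigma, "n": g.n}
            for g in gaussians
        ]
    )
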