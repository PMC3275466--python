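"""Nearest-centroid subtype assignment with Spearman's rank correlation.

A sample is compared against every centroid by Spearman's rho (Pearson
correlation of average-rank-transformed values) and assigned the subtype
whose centroid correlates best.  Rho is a similarity, so we maximize it;
the classification is therefore invariant under any strictly monotone
transform of the sample's values.  Exact ties in rho are broken
deterministically by the centroid set's declared subtype order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedCorrelationError, ValidationError
from .io import CentroidSet, ExpressionMatrix, ExpressionProfile, align_genes


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    assigned_subtype: str
    rho_by_subtype: dict[str, float]
    is_tie: bool


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average (fractional) ranks for ties.

    Raises :class:`UndefinedCorrelationError` if either vector is constant
    (zero rank variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValidationError("spearman_rho needs two equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError("spearman_rho needs vectors of length >=3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("spearman_rho inputs must be finite")
    rx = rankdata(x).astype(float)
    ry = rankdata(y).astype(float)
    rx -= rx.mean()
    ry -= ry.mean()
    nx = float(rx @ rx)
    ny = float(ry @ ry)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError("all values tied: rank variance is zero")
    return float(np.clip((rx @ ry) / np.sqrt(nx * ny), -1.0, 1.0))


def _centered_ranks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise centered ranks and their norms; zero norm marks a constant column."""
    ranks = rankdata(mat, axis=0).astype(float)
    ranks -= ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", ranks, ranks))
    return ranks, norms


def rho_to_centroids(values: np.ndarray, centroid_matrix: np.ndarray) -> np.ndarray:
    """Rho of each column of ``values`` (genes x m) against each centroid column.

    Returns an (n_subtypes, m) array; columns with zero rank variance get NaN.
    Used by the batch classifier and the Monte Carlo engine so both share one
    definition of the statistic.
    """
    if values.ndim == 1:
        values = values[:, None]
    cr, cn = _centered_ranks(centroid_matrix)
    if (cn == 0.0).any():
        raise UndefinedCorrelationError("a centroid has zero rank variance")
    sr, sn = _centered_ranks(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (cr.T @ sr) / (cn[:, None] * sn[None, :])
    rho[:, sn == 0.0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def classify_sample(sample: ExpressionProfile, centroids: CentroidSet) -> ClassificationResult:
    """Assign the subtype whose centroid has the highest Spearman rho.

    Requires >=3 shared genes after alignment.  ``is_tie`` is set when two
    centroids attain exactly the maximal rho; the earlier subtype in the
    centroid set's declared order wins.
    """
    aligned = align_genes(sample, centroids)
    if len(aligned.gene_ids) < 3:
        raise ValidationError(
            f"sample {sample.sample_id!r}: only {len(aligned.gene_ids)} shared genes; need >=3"
        )
    rho = rho_to_centroids(aligned.sample_values, aligned.centroid_matrix)[:, 0]
    if np.isnan(rho).any():
        raise UndefinedCorrelationError(
            f"sample {sample.sample_id!r} has zero rank variance on the shared genes"
        )
    best = int(np.argmax(rho))  # first max: stable, declaration order
    is_tie = bool(np.sum(rho == rho[best]) > 1)
    return ClassificationResult(
        sample_id=sample.sample_id,
        assigned_subtype=aligned.subtype_names[best],
        rho_by_subtype=dict(zip(aligned.subtype_names, rho.tolist())),
        is_tie=is_tie,
    )


def classify_matrix(
    samples: ExpressionMatrix, centroids: CentroidSet, *, strict: bool = True
) -> list[ClassificationResult | None]:
    """Classify every column of an expression matrix, order preserved.

    In strict mode (default) the first per-sample error aborts the batch; in
    lenient mode failing samples yield ``None`` and the error is logged.
    """
    import logging

    out: list[ClassificationResult | None] = []
    for profile in samples.profiles():
        try:
            out.append(classify_sample(profile, centroids))
        except Exception:
            if strict:
                raise
            logging.getLogger(__name__).exception(
                "sample %s failed classification", profile.sample_id
            )
            out.append(None)
    return out
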