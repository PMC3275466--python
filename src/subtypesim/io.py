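"""Data model and TSV readers/writers for expression matrices, centroid sets,
and repeated-measures sets.

All tabular files share one dialect: tab-separated, UTF-8, '.' decimal, a
header row whose first cell is the literal ``gene_id``, and gene identifiers
in the first column.  Matching between gene sets is exact, case-sensitive
string comparison — silent fuzzy matching would hide assay mismatches.
Missing values are rejected rather than imputed.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

HEADER_KEY = "gene_id"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def _check_finite(frame: pd.DataFrame, what: str) -> None:
    if not np.isfinite(frame.to_numpy(dtype=float)).all():
        bad = frame.stack()
        bad = bad[~np.isfinite(bad)]
        gene, col = bad.index[0]
        raise ValidationError(f"non-finite value in {what} at gene {gene!r}, column {col!r}")


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's expression signature: a mapping gene -> log-scale value."""

    sample_id: str
    values: pd.Series  # index: gene ids, float values

    def __post_init__(self) -> None:
        s = self.values
        if len(s) < 3:
            raise ValidationError(f"profile {self.sample_id!r} has {len(s)} genes; need >=3")
        _check_unique(list(s.index), "gene id")
        if not np.isfinite(s.to_numpy(dtype=float)).all():
            raise ValidationError(f"non-finite value in profile {self.sample_id!r}")
        object.__setattr__(self, "values", s.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples table of log-scale relative expression values."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(list(df.index), "gene id")
        _check_unique(list(df.columns), "sample id")
        _check_finite(df, "expression matrix")
        object.__setattr__(self, "values", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def profile(self, sample_id: str) -> ExpressionProfile:
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        return ExpressionProfile(sample_id, self.values[sample_id])

    def profiles(self) -> list[ExpressionProfile]:
        return [self.profile(s) for s in self.sample_ids]


@dataclass(frozen=True)
class CentroidSet:
    """Reference expression profiles, one column per subtype.

    Column order is the declared subtype order used for deterministic
    tie-breaking in classification.
    """

    profiles: pd.DataFrame  # index: gene ids, columns: subtype names

    def __post_init__(self) -> None:
        df = self.profiles
        if df.shape[1] < 2:
            raise ValidationError("a centroid set needs >=2 subtypes")
        _check_unique(list(df.index), "gene id")
        _check_unique(list(df.columns), "subtype name")
        _check_finite(df, "centroid set")
        object.__setattr__(self, "profiles", df.astype(float))

    @property
    def subtype_names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)


@dataclass(frozen=True)
class RepeatedMeasuresSet:
    """Replicate measurements (genes x replicates) of one archetypal sample."""

    archetype_id: str
    assigned_subtype: str
    replicates: pd.DataFrame  # index: gene ids, columns: replicate ids

    def __post_init__(self) -> None:
        df = self.replicates
        if df.shape[1] < 3:
            raise ValidationError(
                f"archetype {self.archetype_id!r} has {df.shape[1]} replicates; need >=3"
            )
        _check_unique(list(df.index), "gene id")
        _check_unique(list(df.columns), "replicate id")
        _check_finite(df, f"repeated measures for {self.archetype_id!r}")
        object.__setattr__(self, "replicates", df.astype(float))

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.replicates.index)


def _read_table(source, *, what: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read the shared TSV dialect into a float DataFrame.

    Leading ``#key=value`` comment lines are returned as metadata.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        start += 1
        body = line[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    if start >= len(lines):
        raise ParseError(f"{what}: no header row found")
    header = lines[start].split("\t")
    if header[0] != HEADER_KEY:
        raise ParseError(
            f"{what}: first header cell must be {HEADER_KEY!r}, got {header[0]!r}"
        )
    raw = pd.read_csv(
        _io.StringIO("\n".join(lines[start:])), sep="\t", dtype=str, index_col=0
    )
    _check_unique(list(raw.index), "gene id")
    _check_unique(list(raw.columns), "column id")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        stacked = bad.stack()
        gene, col = stacked[stacked].index[0]
        cell = raw.loc[gene, col]
        if pd.isna(cell):
            raise ValidationError(f"{what}: missing value at gene {gene!r}, column {col!r}")
        raise ParseError(
            f"{what}: non-numeric cell {cell!r} at gene {gene!r}, column {col!r}"
        )
    # Python's float() is correctly rounded, so repr-formatted output
    # round-trips bit-exactly (pandas' fast parser can be off by one ulp).
    exact = raw.map(float)
    return exact, meta


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV."""
    df, _ = _read_table(path, what=str(path))
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix in the shared TSV dialect (full precision)."""
    _write_frame(matrix.values, path)


def read_centroid_tsv(path) -> CentroidSet:
    """Read a centroid set: same layout as an expression matrix, columns = subtypes."""
    df, _ = _read_table(path, what=str(path))
    return CentroidSet(df)


def write_centroid_tsv(centroids: CentroidSet, path) -> None:
    _write_frame(centroids.profiles, path)


def read_repeated_measures_tsv(
    path, *, archetype_id: str | None = None, subtype: str | None = None
) -> RepeatedMeasuresSet:
    """Read one archetype's replicate table.

    The assigned subtype comes from a ``#subtype=<name>`` comment line unless
    passed explicitly; the archetype id defaults to the file stem.
    """
    df, meta = _read_table(path, what=str(path))
    subtype = subtype or meta.get("subtype")
    if subtype is None:
        raise ValidationError(f"{path}: no subtype given and no '#subtype=' header line")
    if archetype_id is None:
        archetype_id = meta.get("archetype", Path(str(path)).stem)
    return RepeatedMeasuresSet(archetype_id, subtype, df)


def write_repeated_measures_tsv(rm: RepeatedMeasuresSet, path) -> None:
    header = f"#subtype={rm.assigned_subtype}\n#archetype={rm.archetype_id}\n"
    _write_frame(rm.replicates, path, preamble=header)


def _write_frame(df: pd.DataFrame, path, preamble: str = "") -> None:
    buf = _io.StringIO()
    out = df.copy()
    out.index.name = HEADER_KEY
    out.to_csv(buf, sep="\t", lineterminator="\n")
    Path(path).write_text(preamble + buf.getvalue(), encoding="utf-8")


@dataclass(frozen=True)
class AlignedPair:
    """Sample values and centroid matrix restricted to the shared gene set."""

    gene_ids: list[str]
    sample_values: np.ndarray          # shape (n_genes,)
    centroid_matrix: np.ndarray        # shape (n_genes, n_subtypes)
    subtype_names: list[str] = field(default_factory=list)
    n_dropped_sample: int = 0
    n_dropped_centroids: int = 0


def align_genes(sample: ExpressionProfile, centroids: CentroidSet) -> AlignedPair:
    """Restrict a sample and a centroid set to their shared genes.

    Genes are ordered by the sorted intersection so the result is invariant
    under permutation of either input's row order.  Genes present on only one
    side are dropped and counted; dropping more than half of the sample's
    genes logs a warning, an empty intersection is an error.
    """
    sample_genes = set(sample.gene_ids)
    centroid_genes = set(centroids.gene_ids)
    shared = sorted(sample_genes & centroid_genes)
    if not shared:
        raise AlignmentError(
            f"sample {sample.sample_id!r} shares no genes with the centroid set"
        )
    n_drop_s = len(sample_genes) - len(shared)
    n_drop_c = len(centroid_genes) - len(shared)
    if n_drop_s > len(sample_genes) / 2:
        logger.warning(
            "sample %s: dropped %d of %d genes during alignment",
            sample.sample_id, n_drop_s, len(sample_genes),
        )
    return AlignedPair(
        gene_ids=shared,
        sample_values=sample.values.loc[shared].to_numpy(dtype=float),
        centroid_matrix=centroids.profiles.loc[shared].to_numpy(dtype=float),
        subtype_names=centroids.subtype_names,
        n_dropped_sample=n_drop_s,
        n_dropped_centroids=n_drop_c,
    )
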