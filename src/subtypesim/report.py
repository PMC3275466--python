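"""Summary artifacts: confusion tables, change histograms, scorecards, and
the binomial sample-size justification for the number of simulations.

All internal arithmetic is full precision; rounding (2 decimals for tables,
1 decimal for scorecards) happens only at rendering time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import ReproducibilityResult


@dataclass(frozen=True)
class CIParams:
    """Wald confidence-half-width bookkeeping for a simulated proportion."""

    z: float
    theta: float
    n: int
    W: float


def ci_width(z: float, theta: float, n: int) -> float:
    """Half-width of the normal-approximation CI for a proportion.

    W = z * sqrt(theta * (1 - theta) / n).  With z = 1.96, an expected
    misclassification proportion theta = 0.02 and n = 100,000 simulations
    this gives +/- 0.00087, the justification for the default simulation
    count: the Monte Carlo uncertainty on any reported percentage is far
    below the differences of interest.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValidationError(f"theta must be in [0, 1], got {theta}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    return float(z) * math.sqrt(theta * (1.0 - theta) / n)


def ci_params(z: float, theta: float, n: int) -> CIParams:
    return CIParams(z=z, theta=theta, n=n, W=ci_width(z, theta, n))


@dataclass(frozen=True)
class ConfusionSummary:
    """Original-subtype x assigned-subtype percentages of simulated samples."""

    scenario: str
    table: pd.DataFrame        # rows: original subtype, cols: assigned; percent
    row_totals: pd.Series      # simulated samples per original subtype

    def rendered(self) -> pd.DataFrame:
        return self.table.round(2)

    def to_tsv(self, path) -> None:
        out = self.rendered().copy()
        out.insert(0, "simulated_samples", self.row_totals)
        out.index.name = "original_subtype"
        out.to_csv(path, sep="\t", lineterminator="\n")


def _subtype_order(results: Sequence[ReproducibilityResult]) -> list[str]:
    order: list[str] = []
    for r in results:
        for s in r.counts_by_subtype:
            if s not in order:
                order.append(s)
    return order


def confusion_table(
    results: Sequence[ReproducibilityResult], scenario: str | None = None
) -> ConfusionSummary:
    """Aggregate tallies into per-original-subtype assignment percentages.

    Cell(original, assigned) = 100 * total simulated samples with that pair /
    total simulated samples whose parent had that original subtype.  Every
    row sums to 100 by construction.
    """
    if not results:
        raise ValidationError("confusion_table needs at least one result")
    scenarios = {r.scenario for r in results}
    if scenario is None:
        if len(scenarios) > 1:
            raise ValidationError(f"mixed scenarios in results: {sorted(scenarios)}")
        scenario = next(iter(scenarios))
    elif scenarios != {scenario}:
        raise ValidationError(f"results carry scenarios {sorted(scenarios)}, expected {scenario!r}")

    cols = _subtype_order(results)
    originals = []
    for r in results:
        if r.parent_subtype not in originals:
            originals.append(r.parent_subtype)
    counts = pd.DataFrame(0, index=originals, columns=cols, dtype=float)
    totals = pd.Series(0, index=originals, dtype=int)
    for r in results:
        for s, c in r.counts_by_subtype.items():
            counts.loc[r.parent_subtype, s] += c
        totals[r.parent_subtype] += r.n_sims
    table = 100.0 * counts.div(totals, axis=0)
    return ConfusionSummary(scenario=scenario, table=table, row_totals=totals)


def change_histogram(
    results: Sequence[ReproducibilityResult], bucket_width: float = 5.0
) -> pd.DataFrame:
    """Per-subtype histogram of the percentage of simulations that changed class.

    Buckets are [0,w), [w,2w), ..., closed on the left; a parent whose every
    simulation changed (100%) lands in the last bucket.  Bucket counts per
    subtype sum to the number of parents of that subtype.
    """
    if not results:
        raise ValidationError("change_histogram needs at least one result")
    if bucket_width <= 0 or abs(100.0 / bucket_width - round(100.0 / bucket_width)) > 1e-9:
        raise ValidationError(f"bucket width {bucket_width} must divide 100")
    n_buckets = int(round(100.0 / bucket_width))
    labels = [
        f"[{i * bucket_width:g},{(i + 1) * bucket_width:g})" for i in range(n_buckets)
    ]
    labels[-1] = labels[-1][:-1] + "]"
    subtypes = []
    for r in results:
        if r.parent_subtype not in subtypes:
            subtypes.append(r.parent_subtype)
    hist = pd.DataFrame(0, index=labels, columns=subtypes, dtype=int)
    for r in results:
        changed_pct = 100.0 * (1.0 - r.prop_identical)
        idx = min(int(changed_pct // bucket_width), n_buckets - 1)
        hist.loc[labels[idx], r.parent_subtype] += 1
    hist.index.name = "pct_changed"
    return hist


def never_change_summary(results: Sequence[ReproducibilityResult]) -> pd.DataFrame:
    """Per subtype: how many parents never changed class in any simulation."""
    if not results:
        raise ValidationError("never_change_summary needs at least one result")
    rows: dict[str, dict[str, float]] = {}
    for r in results:
        rec = rows.setdefault(r.parent_subtype, {"never_change": 0, "total": 0})
        rec["total"] += 1
        if r.counts_by_subtype.get(r.parent_subtype, 0) == r.n_sims:
            rec["never_change"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["fraction"] = df["never_change"] / df["total"]
    df.index.name = "subtype"
    return df.astype({"never_change": int, "total": int})


@dataclass(frozen=True)
class Scorecard:
    """Clinician-facing per-sample report of assignment probabilities."""

    sample_id: str
    original_subtype: str
    probability_by_subtype: dict[str, float]  # percent, descending
    scenario: str
    n_sims: int

    def to_json_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "original_subtype": self.original_subtype,
            "scenario": self.scenario,
            "n_simulations": self.n_sims,
            "probability_percent": {
                s: round(p, 1) for s, p in self.probability_by_subtype.items()
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), indent=2), encoding="utf-8"
        )

    def to_markdown(self) -> str:
        lines = [
            f"# Subtype scorecard — {self.sample_id}",
            "",
            f"Original classification: **{self.original_subtype}** "
            f"({self.scenario}-case error model, {self.n_sims:,} simulations)",
            "",
            "| Subtype | Probability |",
            "| --- | --- |",
        ]
        for s, p in self.probability_by_subtype.items():
            lines.append(f"| {s} | {p:.1f}% |")
        lines.append("")
        lines.append(
            "Probabilities are the share of simulated measurement-error replicates "
            "of this sample assigned to each subtype."
        )
        return "\n".join(lines)


def scorecard(result: ReproducibilityResult) -> Scorecard:
    """Turn one reproducibility tally into assignment probabilities (percent)."""
    probs = {
        s: 100.0 * c / result.n_sims for s, c in result.counts_by_subtype.items()
    }
    ordered = dict(
        sorted(probs.items(), key=lambda kv: (-kv[1], list(probs).index(kv[0])))
    )
    return Scorecard(
        sample_id=result.parent_sample_id,
        original_subtype=result.parent_subtype,
        probability_by_subtype=ordered,
        scenario=result.scenario,
        n_sims=result.n_sims,
    )
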