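"""Validation scoring of temperature estimates.

A prediction scores [1] when the true exposure temperature falls inside the
assigned cluster's temperature range (the upper bound of an open-ended
cluster counts as +infinity) and [0] otherwise.  "Correct" is thus *range
containment*: the model never claims a point temperature, only a range, so
a genuinely unheated sample assigned to cluster 1 (minimum 0 °C) counts as
correct — an interpretation worth keeping in mind when reading accuracies.

Accuracies are reported per test-set partition as ``100 · mean(score)``,
plus two overall means: weighted by partition size (the default, matching
the convention of reporting one figure over all samples) and unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colour import DomainError
from .dataset import ColourDataset
from .decision import ClusterAssignment, DecisionThresholds, assign_clusters, temperature_range

__all__ = ["ScoredPrediction", "AccuracyReport", "score_prediction", "score_dataset", "accuracy_report"]


@dataclass(frozen=True)
class ScoredPrediction:
    sample_id: str
    true_temperature_c: float
    cluster: int
    t_min_c: float
    t_max_c: float  # +inf when open-ended
    score: int
    partition: str = "all"

    def __post_init__(self) -> None:
        ok = self.t_min_c <= self.true_temperature_c <= self.t_max_c
        if self.score != int(ok):
            raise DomainError("score inconsistent with range containment")


def score_prediction(true_temperature_c: float, assignment: ClusterAssignment | int) -> int:
    """1 if the true temperature lies within the assigned cluster's range, else 0."""
    rng = (
        assignment.temperature
        if isinstance(assignment, ClusterAssignment)
        else temperature_range(assignment)
    )
    return int(rng.contains(true_temperature_c))


def score_dataset(
    ds: ColourDataset | pd.DataFrame,
    thresholds: DecisionThresholds | None = None,
    partition_col: str | None = None,
) -> pd.DataFrame:
    """Classify every record and score it against its known temperature.

    Returns one row per sample: true temperature, assigned cluster, range
    and binary score, plus the partition label (from ``partition_col`` when
    given, otherwise a single ``"all"`` partition).
    """
    frame = ds.frame if isinstance(ds, ColourDataset) else ds
    if "temperature_c" not in frame.columns:
        raise DomainError("scoring needs a temperature_c column with the true temperatures")
    clusters = assign_clusters(
        frame["L_star"].to_numpy(dtype=float),
        frame["B_star"].to_numpy(dtype=float),
        thresholds,
    )
    rows = []
    for (_, rec), cid in zip(frame.iterrows(), clusters):
        rng = temperature_range(int(cid))
        true_t = float(rec["temperature_c"])
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "true_temperature_c": true_t,
                "cluster": int(cid),
                "t_min_c": rng.t_min_c,
                "t_max_c": rng.upper_bound,
                "score": int(rng.contains(true_t)),
                "partition": str(rec[partition_col]) if partition_col else "all",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AccuracyReport:
    """Per-partition accuracy plus overall means (percent, 0-100)."""

    table: pd.DataFrame  # index: partition; columns: n, accuracy_pct
    mean_weighted_pct: float
    mean_unweighted_pct: float

    def rounded(self) -> pd.Series:
        """Display-style integer rounding of the per-partition accuracies."""
        return self.table["accuracy_pct"].round(0).astype(int)


def accuracy_report(scored: pd.DataFrame, partition_col: str = "partition") -> AccuracyReport:
    """Aggregate binary scores into per-partition and overall accuracies.

    Empty partitions are excluded with a warning.  The weighted mean pools
    all samples; the unweighted mean averages the partition percentages.
    """
    if len(scored) == 0:
        raise DomainError("no predictions to aggregate")
    if partition_col not in scored.columns:
        raise DomainError(f"missing partition column {partition_col!r}")

    rows = []
    for name, grp in scored.groupby(partition_col, sort=False):
        if len(grp) == 0:  # pragma: no cover - groupby drops these, kept for clarity
            warnings.warn(f"partition {name!r} is empty; excluded from the report")
            continue
        rows.append({"partition": name, "n": len(grp), "accuracy_pct": 100.0 * grp["score"].mean()})
    table = pd.DataFrame(rows).set_index("partition")
    weighted = 100.0 * scored["score"].mean()
    unweighted = float(table["accuracy_pct"].mean())
    return AccuracyReport(
        table=table,
        mean_weighted_pct=float(np.round(weighted, 10)),
        mean_unweighted_pct=float(np.round(unweighted, 10)),
    )
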