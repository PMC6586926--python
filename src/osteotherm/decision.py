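"""The seven-cluster L*/B* threshold decision model.

Heated bone traverses a characteristic colour path — ivory, brownish-black
(carbonisation), grey (inversion), white (calcination) — and the published
decision model partitions the (L*, b*) plane into seven clusters, each tied
to an exposure-temperature range and a heat-induced (HI) change stage:

====== =============================================== ========== ==========
cluster rule (as resolved below)                        T min (C)  T max (C)
====== =============================================== ========== ==========
1      B > 11 and L >= 40                                       0        350
2      B > 11 and L < 40                                      250        350
3      B <= 11 and L < 32.5                                   300        600
4      B <= 11 and 32.5 <= L < 75 and B >= 6.5                450        600
5      B < 6.5 and 32.5 <= L < 75                             450        700
6      B <= 11 and L >= 75 and L <= -25*B + 200               700   open(>=900)
7      B <= 11 and L >= 75 and L > -25*B + 200                800   open(>=900)
====== =============================================== ========== ==========

The printed rules overlap (cluster 4's "B < 11" contains cluster 5's
"B < 6.5") and do not say what happens exactly on a threshold.  This module
resolves both with a half-open scheme that yields a total, mutually
exclusive partition: points go to the ``B <= 11`` branch on the tie, and
threshold ties on L go to the cluster listed first in the tree below, which
is always the lower-temperature (forensically conservative) choice.  The a*
coordinate is accepted but ignored: L* and b* carry the discriminating
information.

The upper bound of clusters 6 and 7 is open-ended: 900 C was merely the
highest temperature in the underlying experiment, so it is reported as
">= 900 C" rather than a hard maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colour import DomainError, LabTriple

__all__ = [
    "DecisionThresholds",
    "DEFAULT_THRESHOLDS",
    "TemperatureRange",
    "ClusterAssignment",
    "CLUSTER_STAGES",
    "assign_cluster",
    "assign_clusters",
    "temperature_range",
    "classify_measurement",
    "classify_measurements",
]


@dataclass(frozen=True)
class DecisionThresholds:
    """The published threshold constants (immutable defaults).

    ``l_carbonised`` separates clusters 1/2 at high b*; ``l_charred`` and
    ``l_calcined`` bracket the mid-lightness band at low b*; ``b_upper``
    splits the plane into the high/low-b* branches; ``b_calcination``
    separates clusters 4/5; clusters 6/7 are divided by the line
    ``L = line_slope * B + line_intercept``.
    """

    l_carbonised: float = 40.0
    l_charred: float = 32.5
    l_calcined: float = 75.0
    b_upper: float = 11.0
    b_calcination: float = 6.5
    line_slope: float = -25.0
    line_intercept: float = 200.0

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionThresholds":
        return cls(**d)


DEFAULT_THRESHOLDS = DecisionThresholds()

#: HI-stage label per cluster.
CLUSTER_STAGES = {
    1: "Unheated - carbonization",
    2: "Carbonization",
    3: "Completely charred",
    4: "Inversion",
    5: "Inversion - calcination",
    6: "Completely calcined",
    7: "Completely calcined",
}

# (t_min, t_max, open-ended display minimum for the open bound)
_CLUSTER_RANGES = {
    1: (0.0, 350.0, None),
    2: (250.0, 350.0, None),
    3: (300.0, 600.0, None),
    4: (450.0, 600.0, None),
    5: (450.0, 700.0, None),
    6: (700.0, None, 900.0),
    7: (800.0, None, 900.0),
}


@dataclass(frozen=True)
class TemperatureRange:
    """Exposure-temperature range of a cluster; ``t_max_c is None`` = open."""

    t_min_c: float
    t_max_c: float | None
    open_display_c: float | None = None

    @property
    def is_open(self) -> bool:
        return self.t_max_c is None

    @property
    def upper_bound(self) -> float:
        """Numeric upper bound for containment checks (inf when open)."""
        return math.inf if self.is_open else self.t_max_c

    def contains(self, temperature_c: float) -> bool:
        return self.t_min_c <= temperature_c <= self.upper_bound

    def display(self) -> str:
        if self.is_open:
            return f"{self.t_min_c:g}–(≥{self.open_display_c:g}) °C"
        return f"{self.t_min_c:g}–{self.t_max_c:g} °C"


@dataclass(frozen=True)
class ClusterAssignment:
    """One measurement's cluster, temperature range and HI stage."""

    cluster: int
    temperature: TemperatureRange
    stage: str
    L: float
    B: float


def temperature_range(cluster_id: int) -> TemperatureRange:
    """Exposure-temperature range associated with a cluster id (1-7)."""
    try:
        t_min, t_max, open_disp = _CLUSTER_RANGES[int(cluster_id)]
    except (KeyError, ValueError, TypeError):
        raise DomainError(f"unknown cluster id {cluster_id!r}; expected 1..7") from None
    return TemperatureRange(t_min, t_max, open_disp)


def assign_clusters(L, B, thresholds: DecisionThresholds | None = None) -> np.ndarray:
    """Vectorised cluster assignment from L* and b* arrays.

    Implements the decision tree documented in the module docstring; the a*
    coordinate plays no role.  Raises :class:`DomainError` on non-finite
    input or L* outside [0, 100].
    """
    th = thresholds or DEFAULT_THRESHOLDS
    L = np.asarray(L, dtype=float)
    B = np.asarray(B, dtype=float)
    if not (np.isfinite(L).all() and np.isfinite(B).all()):
        raise DomainError("non-finite L*/b* value")
    if (L < 0).any() or (L > 100).any():
        raise DomainError("L* outside [0, 100]")

    L, B = np.broadcast_arrays(L, B)
    out = np.empty(L.shape, dtype=np.int8)

    high_b = B > th.b_upper
    out[high_b & (L >= th.l_carbonised)] = 1
    out[high_b & (L < th.l_carbonised)] = 2

    low_b = ~high_b
    out[low_b & (L < th.l_charred)] = 3
    mid = low_b & (L >= th.l_charred) & (L < th.l_calcined)
    out[mid & (B >= th.b_calcination)] = 4
    out[mid & (B < th.b_calcination)] = 5

    hot = low_b & (L >= th.l_calcined)
    boundary = th.line_slope * B + th.line_intercept
    out[hot & (L <= boundary)] = 6
    out[hot & (L > boundary)] = 7
    return out


def assign_cluster(lab, thresholds: DecisionThresholds | None = None) -> ClusterAssignment:
    """Assign a single Lab colour to its temperature cluster.

    ``lab`` may be a :class:`~osteotherm.colour.LabTriple` or any (L, A, B)
    sequence.  A* is ignored by the model.
    """
    if isinstance(lab, LabTriple):
        L, B = lab.L, lab.B
    else:
        arr = np.asarray(lab, dtype=float)
        if arr.shape != (3,):
            raise DomainError("expected an (L, A, B) triple")
        L, B = float(arr[0]), float(arr[2])
    cid = int(assign_clusters(np.array(L), np.array(B), thresholds))
    return ClusterAssignment(
        cluster=cid,
        temperature=temperature_range(cid),
        stage=CLUSTER_STAGES[cid],
        L=float(L),
        B=float(B),
    )


def classify_measurement(measurement, thresholds: DecisionThresholds | None = None) -> dict:
    """Bind a ROI colour measurement to its cluster assignment.

    Returns a flat report record (dict) suitable for a DataFrame row:
    sample id, the L*/b* used, cluster, temperature range, HI stage and any
    flags carried by the measurement.
    """
    lab = np.asarray(measurement.mean_lab, dtype=float)
    a = assign_cluster(lab, thresholds)
    return {
        "sample_id": measurement.sample_id,
        "L_star": a.L,
        "A_star": float(lab[1]),
        "B_star": a.B,
        "cluster": a.cluster,
        "t_min_c": a.temperature.t_min_c,
        "t_max_c": a.temperature.upper_bound,
        "open_ended": a.temperature.is_open,
        "temperature_range": a.temperature.display(),
        "hi_stage": a.stage,
        "flags": ";".join(getattr(measurement, "flags", ()) or ()),
    }


def classify_measurements(measurements, thresholds: DecisionThresholds | None = None) -> pd.DataFrame:
    """Order-preserving batch version of :func:`classify_measurement`."""
    return pd.DataFrame([classify_measurement(m, thresholds) for m in measurements])
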