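"""Tabular colour datasets: one row per heated bone sample.

The canonical schema (column names as written by :mod:`osteotherm.roi` plus
experimental covariates):

==============  =====================================================
column          meaning
==============  =====================================================
sample_id       unique sample identifier
temperature_c   exposure temperature (°C)
duration_min    exposure duration (minutes)
medium          "air" or "adipose" (soft-tissue proxy)
element         skeletal element: radius / ulna / humerus
sex             m / f
age_group       "<60", "60-80", ">80"
R, G, B         mean RGB over the ROI, 0-255 scale
L_star, A_star, B_star   mean CIE L*a*b* over the ROI
==============  =====================================================

External tables rarely match this layout, so :meth:`ColourDataset.from_csv`
accepts a column-mapping dict (``{"their name": "our name"}``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .colour import DomainError

__all__ = ["ColourDataset", "MEDIA", "ELEMENTS", "AGE_GROUPS", "COLOUR_COLUMNS"]

MEDIA = ("air", "adipose")
ELEMENTS = ("radius", "ulna", "humerus")
AGE_GROUPS = ("<60", "60-80", ">80")
COLOUR_COLUMNS = ("R", "G", "B", "L_star", "A_star", "B_star")

_REQUIRED = ("sample_id", "L_star", "B_star")


@dataclass
class ColourDataset:
    """An ordered collection of sample records with a learning/test role tag."""

    frame: pd.DataFrame
    role: str = "learning"

    def __post_init__(self) -> None:
        if self.role not in ("learning", "test"):
            raise DomainError(f"role must be 'learning' or 'test', got {self.role!r}")
        if len(self.frame) == 0:
            raise DomainError("dataset is empty")
        missing = [c for c in _REQUIRED if c not in self.frame.columns]
        if missing:
            raise DomainError(f"dataset is missing required columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise DomainError(f"duplicate sample ids: {sorted(set(dupes))[:5]} ...")
        if "medium" in self.frame.columns:
            bad = set(self.frame["medium"].dropna()) - set(MEDIA)
            if bad:
                raise DomainError(f"unknown media {sorted(bad)}; expected {MEDIA}")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path, role: str = "learning", column_map: dict | None = None) -> "ColourDataset":
        """Load a per-sample CSV, optionally renaming columns first."""
        frame = pd.read_csv(path)
        if column_map:
            frame = frame.rename(columns=column_map)
        return cls(frame, role=role)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
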