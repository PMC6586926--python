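"""Chart-based colour calibration.

Scanners and cameras are calibrated against a 24-patch ColorChecker Classic
chart imaged alongside the samples.  A least-squares linear (3x3) or affine
(3x3 + offset) map is fitted in *linearised* RGB from the measured patch
colours to the chart's reference colours; the affine default absorbs any
scanner black-level offset.  Fit quality is summarised as per-patch ΔE*ab
against the reference in Lab.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .colour import DomainError, delta_e, srgb_compand, srgb_decompand, srgb_to_lab

__all__ = [
    "ChartObservation",
    "ColourCorrection",
    "FitError",
    "load_reference_chart",
    "fit_colour_correction",
    "apply_colour_correction",
]


class FitError(ValueError):
    """Calibration fit is under-determined or rank-deficient."""


def load_reference_chart() -> pd.DataFrame:
    """Reference sRGB and Lab values of the 24-patch ColorChecker Classic.

    Nominal post-2005 sRGB coordinates; Lab (D65) is derived at load time by
    the package's own conversion so both colour views stay consistent.
    """
    with resources.files("osteotherm.data").joinpath("colorchecker_classic_srgb.csv").open() as fh:
        df = pd.read_csv(fh)
    unit = df[["r", "g", "b"]].to_numpy(dtype=float) / 255.0
    lab = srgb_to_lab(unit)
    df[["L_star", "A_star", "B_star"]] = lab
    return df


@dataclass(frozen=True)
class ChartObservation:
    """Paired (reference, measured) patch colours, unit-scale sRGB."""

    patch_ids: tuple
    reference_srgb: np.ndarray  # (n, 3) in [0, 1]
    measured_srgb: np.ndarray  # (n, 3) in [0, 1]

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_srgb, dtype=float)
        meas = np.asarray(self.measured_srgb, dtype=float)
        if ref.shape != meas.shape or ref.ndim != 2 or ref.shape[1] != 3:
            raise DomainError("reference and measured patch arrays must both be (n, 3)")
        if len(self.patch_ids) != ref.shape[0]:
            raise DomainError("patch id count does not match patch colour count")
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise DomainError("patch ids must be unique")
        object.__setattr__(self, "reference_srgb", ref)
        object.__setattr__(self, "measured_srgb", meas)

    @property
    def n_patches(self) -> int:
        return self.reference_srgb.shape[0]

    @classmethod
    def against_reference(cls, measured_srgb, patch_ids=None) -> "ChartObservation":
        """Pair a full 24-patch measurement with the packaged reference chart."""
        chart = load_reference_chart()
        ref = chart[["r", "g", "b"]].to_numpy(dtype=float) / 255.0
        ids = tuple(chart["patch_id"]) if patch_ids is None else tuple(patch_ids)
        return cls(ids, ref, np.asarray(measured_srgb, dtype=float))


@dataclass
class ColourCorrection:
    """Fitted device-to-reference transform, applied in linear RGB."""

    matrix: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    model: str  # "linear" | "affine"
    delta_e_per_patch: np.ndarray | None = None
    mean_delta_e: float | None = None
    rmse: float | None = None
    white_point: str = "D65"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise FitError("correction matrix is singular")

    @classmethod
    def identity(cls) -> "ColourCorrection":
        return cls(np.eye(3), np.zeros(3), model="linear")

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "mean_delta_e": self.mean_delta_e,
            "rmse": self.rmse,
            "white_point": self.white_point,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ColourCorrection":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            np.array(payload["matrix"]),
            np.array(payload["offset"]),
            model=payload["model"],
            mean_delta_e=payload.get("mean_delta_e"),
            rmse=payload.get("rmse"),
            white_point=payload.get("white_point", "D65"),
        )


def fit_colour_correction(obs: ChartObservation, model: str = "affine") -> ColourCorrection:
    """Least-squares fit of measured -> reference patch colours in linear RGB.

    ``model="linear"`` fits a pure 3x3 mixing matrix; ``"affine"`` (default)
    adds an offset vector.  Requires at least 4 patches and a full-rank
    design; per-patch ΔE*ab residuals (reference vs corrected measurement)
    are stored on the result.
    """
    if model not in ("linear", "affine"):
        raise FitError(f"unknown correction model {model!r}")
    if obs.n_patches < 4:
        raise FitError(f"need >= 4 patches for a fit, got {obs.n_patches}")

    meas_lin = srgb_decompand(obs.measured_srgb)
    ref_lin = srgb_decompand(obs.reference_srgb)

    if model == "affine":
        design = np.hstack([meas_lin, np.ones((obs.n_patches, 1))])
    else:
        design = meas_lin
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("patch set is rank-deficient; cannot identify the colour map")

    coef, *_ = np.linalg.lstsq(design, ref_lin, rcond=None)
    if model == "affine":
        matrix, offset = coef[:3].T, coef[3]
    else:
        matrix, offset = coef.T, np.zeros(3)

    corr = ColourCorrection(matrix, offset, model=model)
    corrected, _ = apply_colour_correction(obs.measured_srgb, corr)
    residuals = delta_e(srgb_to_lab(obs.reference_srgb), srgb_to_lab(corrected))
    corr.delta_e_per_patch = residuals
    corr.mean_delta_e = float(residuals.mean())
    corr.rmse = float(np.sqrt((residuals**2).mean()))
    return corr


def apply_colour_correction(colours, corr: ColourCorrection):
    """Apply a fitted correction to unit-scale sRGB colours or images.

    Linearises, applies the map, recompands.  Returns ``(corrected, clipped)``
    where ``clipped`` flags whether any output channel fell outside [0, 1]
    and was clipped (flagged, not fatal).
    """
    arr = np.asarray(colours, dtype=float)
    if arr.shape[-1] != 3:
        raise DomainError("expected colour array with trailing dimension 3")
    lin = srgb_decompand(arr)
    out = lin @ corr.matrix.T + corr.offset
    clipped = bool(((out < -1e-9) | (out > 1.0 + 1e-9)).any())
    out = srgb_compand(np.clip(out, 0.0, 1.0))
    return np.clip(out, 0.0, 1.0), clipped
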