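"""sRGB <-> CIE 1976 L*a*b* conversion.

All heavy lifting happens on float64 arrays of shape ``(..., 3)`` with sRGB
channels on the unit scale [0, 1].  The CIELAB side uses the conventional
scales: L* in [0, 100], a* and b* signed (nominally [-128, 127]).  The
reference white defaults to D65, the native white of sRGB and the common
choice of flatbed-scanner/ImageJ workflows; D50 is available via Bradford
chromatic adaptation.

The decision thresholds used elsewhere in this package (40, 32.5, 75 on L*;
11, 6.5 on b*) are only coherent on these standard CIE scales, so L* is
never rescaled to 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RGBTriple",
    "LabTriple",
    "DomainError",
    "srgb_to_lab",
    "lab_to_srgb",
    "delta_e",
    "srgb_decompand",
    "srgb_compand",
    "WHITE_POINTS",
]


class DomainError(ValueError):
    """Input colour value outside its declared domain."""


#: CIE standard illuminant white points (2-degree observer), XYZ with Y = 1.
WHITE_POINTS = {
    "D65": np.array([0.95047, 1.00000, 1.08883]),
    "D50": np.array([0.96422, 1.00000, 0.82521]),
}

# Linear sRGB -> XYZ (D65), IEC 61966-2-1 primaries.  Rows are renormalised
# so that RGB (1,1,1) maps *exactly* to the D65 white point (the published
# 7-digit constants are off by ~1e-7, which would put white at L* > 100).
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_M_RGB2XYZ *= (WHITE_POINTS["D65"] / _M_RGB2XYZ.sum(axis=1))[:, None]
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

# Bradford chromatic adaptation, D65 -> D50.
_M_D65_TO_D50 = np.array(
    [
        [1.0478112, 0.0228866, -0.0501270],
        [0.0295424, 0.9904844, -0.0170491],
        [-0.0092345, 0.0150436, 0.7521316],
    ]
)
_M_D50_TO_D65 = np.linalg.inv(_M_D65_TO_D50)

_DELTA = 6.0 / 29.0  # CIE f(t) kink


@dataclass(frozen=True)
class RGBTriple:
    """A single RGB colour on a declared scale.

    ``scale`` is ``"8bit"`` (channels in 0-255) or ``"unit"`` (0-1); the
    flag travels with the value so no caller has to guess.
    """

    r: float
    g: float
    b: float
    scale: str = "8bit"

    def __post_init__(self) -> None:
        if self.scale not in ("8bit", "unit"):
            raise DomainError(f"unknown RGB scale {self.scale!r}")
        hi = 255.0 if self.scale == "8bit" else 1.0
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not np.isfinite(v) or v < 0 or v > hi:
                raise DomainError(
                    f"channel {name} value {v!r} outside [0, {hi:g}] for scale {self.scale!r}"
                )

    def as_unit(self) -> np.ndarray:
        arr = np.array([self.r, self.g, self.b], dtype=float)
        return arr / 255.0 if self.scale == "8bit" else arr

    @classmethod
    def from_unit(cls, arr, scale: str = "8bit") -> "RGBTriple":
        arr = np.asarray(arr, dtype=float)
        if scale == "8bit":
            arr = arr * 255.0
        return cls(float(arr[0]), float(arr[1]), float(arr[2]), scale=scale)


@dataclass(frozen=True)
class LabTriple:
    """A CIE 1976 L*a*b* colour point (the space the decision model lives in)."""

    L: float
    A: float
    B: float

    def __post_init__(self) -> None:
        for name, v in (("L", self.L), ("A", self.A), ("B", self.B)):
            if not np.isfinite(v):
                raise DomainError(f"Lab coordinate {name} is not finite: {v!r}")
        if not 0.0 <= self.L <= 100.0:
            raise DomainError(f"L* value {self.L!r} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.A, self.B], dtype=float)


def srgb_decompand(srgb: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: companded [0,1] -> linear [0,1]."""
    srgb = np.asarray(srgb, dtype=float)
    return np.where(srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4)


def srgb_compand(linear: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_decompand` (linear -> companded)."""
    linear = np.asarray(linear, dtype=float)
    lin = np.clip(linear, 0.0, None)  # guard fractional power on tiny negatives
    return np.where(linear <= 0.0031308, 12.92 * linear, 1.055 * lin ** (1 / 2.4) - 0.055)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _finv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t**3, 3 * _DELTA**2 * (t - 4.0 / 29.0))


def _white(white_point: str) -> np.ndarray:
    try:
        return WHITE_POINTS[white_point]
    except KeyError:
        raise DomainError(
            f"unknown white point {white_point!r}; expected one of {sorted(WHITE_POINTS)}"
        ) from None


def srgb_to_lab(rgb, white_point: str = "D65"):
    """Convert sRGB to CIE 1976 L*a*b*.

    Parameters
    ----------
    rgb : RGBTriple or array-like of shape (..., 3)
        Arrays are interpreted on the unit scale [0, 1]; an
        :class:`RGBTriple` carries its own scale flag.
    white_point : {"D65", "D50"}
        Reference white for the Lab normalisation.  D50 is reached from the
        sRGB-native D65 tristimulus by Bradford adaptation.

    Returns
    -------
    LabTriple or ndarray matching the input form.
    """
    if isinstance(rgb, RGBTriple):
        lab = srgb_to_lab(rgb.as_unit(), white_point=white_point)
        return LabTriple(float(lab[0]), float(lab[1]), float(lab[2]))

    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise DomainError("expected colour array with trailing dimension 3")
    if not np.isfinite(arr).all():
        raise DomainError("non-finite channel value in colour array")
    if arr.min() < 0.0 or arr.max() > 1.0:
        bad = "r" if ((arr[..., 0] < 0) | (arr[..., 0] > 1)).any() else (
            "g" if ((arr[..., 1] < 0) | (arr[..., 1] > 1)).any() else "b"
        )
        raise DomainError(f"channel {bad} outside the unit scale [0, 1]")

    xyz = srgb_decompand(arr) @ _M_RGB2XYZ.T
    if white_point == "D50":
        xyz = xyz @ _M_D65_TO_D50.T
    white = _white(white_point)
    f = _f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_srgb(lab, white_point: str = "D65"):
    """Convert CIE 1976 L*a*b* to sRGB, clipping out-of-gamut results.

    Returns ``(rgb, clipped)`` where ``rgb`` has the same leading shape as
    the input (unit scale) and ``clipped`` flags whether any channel had to
    be clipped into [0, 1].  Clipping is flagged, never fatal.
    """
    triple = isinstance(lab, LabTriple)
    arr = lab.as_array() if triple else np.asarray(lab, dtype=float)
    if arr.shape[-1] != 3:
        raise DomainError("expected Lab array with trailing dimension 3")
    if not np.isfinite(arr).all():
        raise DomainError("non-finite Lab coordinate")

    fy = (arr[..., 0] + 16.0) / 116.0
    fx = fy + arr[..., 1] / 500.0
    fz = fy - arr[..., 2] / 200.0
    white = _white(white_point)
    xyz = np.stack([_finv(fx), _finv(fy), _finv(fz)], axis=-1) * white
    if white_point == "D50":
        xyz = xyz @ _M_D50_TO_D65.T
    linear = xyz @ _M_XYZ2RGB.T

    clipped_mask = (linear < -1e-9) | (linear > 1.0 + 1e-9)
    rgb = srgb_compand(np.clip(linear, 0.0, 1.0))
    rgb = np.clip(rgb, 0.0, 1.0)
    clipped = bool(clipped_mask.any())

    if triple:
        return RGBTriple.from_unit(rgb, scale="unit"), clipped
    return rgb, clipped


def delta_e(lab1, lab2) -> np.ndarray:
    """CIE 1976 colour difference ΔE*ab: Euclidean distance in Lab."""
    a1 = lab1.as_array() if isinstance(lab1, LabTriple) else np.asarray(lab1, dtype=float)
    a2 = lab2.as_array() if isinstance(lab2, LabTriple) else np.asarray(lab2, dtype=float)
    return np.sqrt(((a1 - a2) ** 2).sum(axis=-1))
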