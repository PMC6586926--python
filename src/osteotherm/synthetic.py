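"""Synthetic heated-bone colour data and images.

Real learning data for this problem are transverse slices of human long
bone heated between room temperature and 900 °C.  Their mean colour follows
a characteristic path through Lab space — ivory (high L*, clearly positive
b*), brownish-black around carbonisation (L* drops), grey through inversion
(b* collapses towards 0, L* recovers) and finally calcined white (high L*,
b* near 0).  The generator reproduces that structure with a piecewise-linear
trajectory through temperature-anchored Lab means, small additive duration
and medium effects (temperature dominates, as in the real data), and i.i.d.
Gaussian noise per channel emulating the small within-subgroup spread.

Anchor means are illustrative, not measured: each default anchor is placed
at least ~2σ (σ = 2 Lab units) inside the decision-model region of the
cluster whose temperature range contains that anchor temperature, so that
generated subgroups classify overwhelmingly into the "right" cluster.  All
of it is configurable.

Images: :func:`render_sample_image` draws an elliptical bone "slice" on a
white background with optional per-pixel noise and a contaminated outer rim
of stated physical width (the fixture for rim-exclusion tests), and
:func:`render_chart_image` lays measured patch colours out as a 4x6
ColorChecker-style chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .colour import DomainError, lab_to_srgb
from .dataset import AGE_GROUPS, ELEMENTS, MEDIA, ColourDataset
from .decision import DecisionThresholds, assign_cluster
from .roi import SampleImage

__all__ = [
    "TrajectoryModel",
    "DesignSpec",
    "DEFAULT_TRAJECTORY",
    "sample_colour",
    "expected_cluster",
    "generate_dataset",
    "render_sample_image",
    "render_chart_image",
    "extract_chart_patches",
]

#: Reference duration (min): duration effects are expressed relative to this.
REFERENCE_DURATION_MIN = 20.0

#: Default anchors: exposure temperature (°C) -> mean (L*, a*, b*).
#: Each anchor sits >= ~2σ (σ = 2) inside the region of a cluster whose
#: temperature range contains the anchor temperature, so subgroup means
#: form separable clumps — the structure the decision model was cut from.
DEFAULT_ANCHORS = (
    (20.0, (65.0, 7.0, 18.0)),  # unheated ivory          -> cluster 1
    (200.0, (46.0, 6.5, 18.0)),  # darkening ivory        -> cluster 1
    (300.0, (26.0, 6.0, 16.0)),  # carbonised brown-black -> cluster 2
    (400.0, (25.0, 3.0, 6.0)),  # charring                -> cluster 3
    (500.0, (24.0, 2.0, 5.0)),  # completely charred      -> cluster 3
    (650.0, (58.0, 1.0, 1.5)),  # inversion grey          -> cluster 5
    (800.0, (85.0, 0.5, 0.5)),  # calcining               -> cluster 6
    (900.0, (93.0, 0.3, 0.2)),  # calcined white          -> cluster 6
)


@dataclass(frozen=True)
class TrajectoryModel:
    """Temperature -> mean colour trajectory with noise and covariate shifts.

    ``duration_slope`` is the Lab shift per minute away from the 20-minute
    reference; ``medium_shift`` is added for adipose-wrapped samples.  Both
    are an order of magnitude below the temperature effect, mirroring the
    finding that exposure temperature dominates.
    """

    anchors: tuple = DEFAULT_ANCHORS
    sigma: float = 2.0  # per-channel Gaussian noise, Lab units
    duration_slope: tuple = (-0.02, 0.0, -0.02)
    medium_shift: tuple = (0.5, 0.0, 0.2)

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.anchors]
        if len(temps) < 2 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise DomainError("anchors must be strictly increasing in temperature")
        if self.sigma < 0:
            raise DomainError("noise sigma must be >= 0")
        for t, lab in self.anchors:
            assignment = assign_cluster(np.asarray(lab, dtype=float))
            if not assignment.temperature.contains(t):
                raise DomainError(
                    f"anchor at {t:g} °C maps to cluster {assignment.cluster} whose range "
                    f"{assignment.temperature.display()} does not contain it"
                )

    @property
    def span(self) -> tuple:
        return self.anchors[0][0], self.anchors[-1][0]

    def mean_colour(self, temperature_c: float, duration_min: float = REFERENCE_DURATION_MIN,
                    medium: str = "air") -> np.ndarray:
        """Noise-free mean Lab at a temperature/duration/medium combination."""
        lo, hi = self.span
        if not lo <= temperature_c <= hi:
            raise DomainError(
                f"temperature {temperature_c:g} °C outside the anchor span [{lo:g}, {hi:g}]; "
                "refusing to extrapolate"
            )
        if medium not in MEDIA:
            raise DomainError(f"unknown medium {medium!r}; expected one of {MEDIA}")
        temps = np.array([t for t, _ in self.anchors])
        labs = np.array([lab for _, lab in self.anchors], dtype=float)
        mean = np.array(
            [np.interp(temperature_c, temps, labs[:, k]) for k in range(3)]
        )
        mean = mean + np.asarray(self.duration_slope) * (duration_min - REFERENCE_DURATION_MIN)
        if medium == "adipose":
            mean = mean + np.asarray(self.medium_shift)
        return mean


DEFAULT_TRAJECTORY = TrajectoryModel()


def sample_colour(
    temperature_c: float,
    duration_min: float = REFERENCE_DURATION_MIN,
    medium: str = "air",
    rng: np.random.Generator | None = None,
    model: TrajectoryModel = DEFAULT_TRAJECTORY,
) -> np.ndarray:
    """Draw one sample's Lab colour: trajectory mean + Gaussian noise."""
    mean = model.mean_colour(temperature_c, duration_min, medium)
    if model.sigma == 0 or rng is None:
        lab = mean.copy()
    else:
        lab = mean + rng.normal(0.0, model.sigma, size=3)
    lab[0] = np.clip(lab[0], 0.0, 100.0)
    return lab


def expected_cluster(
    temperature_c: float,
    model: TrajectoryModel = DEFAULT_TRAJECTORY,
    thresholds: DecisionThresholds | None = None,
) -> int:
    """Cluster of the noise-free trajectory mean at this temperature."""
    return assign_cluster(model.mean_colour(temperature_c), thresholds).cluster


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of a generated dataset.

    Defaults echo the experimental layout: temperatures from room
    temperature to 900 °C, durations of 10-30 min, air and adipose media
    (adipose only up to 450 °C, above which it autoignites), and >= 10
    samples per temperature-duration subgroup in a learning set.
    """

    temperatures: tuple = (20.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0)
    durations: tuple = (10.0, 20.0, 30.0)
    media: tuple = MEDIA
    n_per_subgroup: int = 10
    seed: int = 0
    role: str = "learning"
    adipose_max_c: float = 450.0
    model: TrajectoryModel = field(default=DEFAULT_TRAJECTORY)

    def __post_init__(self) -> None:
        if self.n_per_subgroup < 1:
            raise DomainError("n_per_subgroup must be >= 1")
        if any(d <= 0 for d in self.durations):
            raise DomainError("durations must be positive")

    def subgroups(self):
        for t in self.temperatures:
            for d in self.durations:
                for m in self.media:
                    if m == "adipose" and t > self.adipose_max_c:
                        continue
                    yield float(t), float(d), m


def generate_dataset(spec: DesignSpec) -> ColourDataset:
    """Generate a learning- or test-set-like colour table.

    One record per draw; element, sex and age group are assigned uniformly
    at random and carry no colour effect (they had none in the real data).
    RGB columns are derived from each sample's Lab via sRGB rendering.
    Fixing ``spec.seed`` fixes the dataset byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = "T" if spec.role == "test" else "L"
    rows = []
    i = 0
    for t, d, m in spec.subgroups():
        for _ in range(spec.n_per_subgroup):
            i += 1
            lab = sample_colour(t, d, m, rng=rng, model=spec.model)
            rgb, _ = lab_to_srgb(lab)
            rows.append(
                {
                    "sample_id": f"{prefix}{i:05d}",
                    "temperature_c": t,
                    "duration_min": d,
                    "medium": m,
                    "element": ELEMENTS[rng.integers(len(ELEMENTS))],
                    "sex": ("f", "m")[rng.integers(2)],
                    "age_group": AGE_GROUPS[rng.integers(len(AGE_GROUPS))],
                    "R": rgb[0] * 255.0,
                    "G": rgb[1] * 255.0,
                    "B": rgb[2] * 255.0,
                    "L_star": lab[0],
                    "A_star": lab[1],
                    "B_star": lab[2],
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["seed"] = spec.seed
    return ColourDataset(frame, role=spec.role)


def render_sample_image(
    mean_lab,
    shape: tuple = (200, 260),
    dpi: float = 300.0,
    noise_sigma: float = 0.0,
    rim_lab=None,
    rim_mm: float = 1.0,
    rng: np.random.Generator | None = None,
    quantize: bool = True,
    sample_id: str | None = None,
) -> SampleImage:
    """Render an elliptical bone "slice" on a white background.

    ``rim_lab``/``rim_mm`` paint a contaminated outer rim (e.g. soot) of the
    stated physical width just inside the boundary — the fixture for testing
    rim exclusion.  ``noise_sigma`` adds per-pixel Gaussian noise in Lab.
    ``quantize`` rounds to 8-bit, as a real scanner file would be.
    """
    h, w = shape
    if h * w <= 0:
        raise DomainError("image shape must have positive area")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.35 * h, 0.35 * w
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    lab_field = np.zeros((h, w, 3))
    lab_field[mask] = np.asarray(mean_lab, dtype=float)
    if rim_lab is not None and rim_mm > 0:
        depth = ndimage.distance_transform_edt(mask)
        rim = mask & (depth <= rim_mm * dpi / 25.4)
        lab_field[rim] = np.asarray(rim_lab, dtype=float)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        lab_field[mask] += rng.normal(0.0, noise_sigma, size=(int(mask.sum()), 3))
        lab_field[..., 0] = np.clip(lab_field[..., 0], 0.0, 100.0)

    rgb = np.ones((h, w, 3))
    rgb[mask], _ = lab_to_srgb(lab_field[mask])
    if quantize:
        rgb = np.round(rgb * 255.0) / 255.0
    return SampleImage(rgb, dpi=dpi, sample_id=sample_id)


def render_chart_image(patch_srgb, patch_px: int = 16, dpi: float = 300.0) -> SampleImage:
    """Lay 24 unit-scale patch colours out as a 4x6 chart image."""
    patches = np.asarray(patch_srgb, dtype=float)
    if patches.shape != (24, 3):
        raise DomainError("expected 24 patches of unit-scale sRGB")
    img = np.zeros((4 * patch_px, 6 * patch_px, 3))
    for idx in range(24):
        r, c = divmod(idx, 6)
        img[r * patch_px : (r + 1) * patch_px, c * patch_px : (c + 1) * patch_px] = patches[idx]
    return SampleImage(img, dpi=dpi, sample_id="chart")


def extract_chart_patches(img: SampleImage, rows: int = 4, cols: int = 6, margin: float = 0.25) -> np.ndarray:
    """Mean colour of each chart cell, sampled away from the cell borders."""
    h, w = img.shape
    ph, pw = h // rows, w // cols
    my, mx = int(margin * ph), int(margin * pw)
    out = np.empty((rows * cols, 3))
    for idx in range(rows * cols):
        r, c = divmod(idx, cols)
        cell = img.pixels[r * ph + my : (r + 1) * ph - my, c * pw + mx : (c + 1) * pw - mx]
        out[idx] = cell.reshape(-1, 3).mean(axis=0)
    return out
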