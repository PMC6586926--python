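"""Per-pixel cluster maps: the thermal gradient across a bone surface.

Burning in a real fire is rarely uniform, so a single ROI mean can hide a
gradient.  Classifying every foreground pixel with the decision model and
rendering the cluster labels as an image makes that gradient visible, and
the union of the temperature ranges of the clusters present gives a
combined exposure envelope (minimum of the minima, maximum of the maxima,
open-ended if cluster 6 or 7 appears).

Per-pixel classification is noisier than the ROI-mean pathway: each pixel's
Lab is averaged over a small square window (within the mask) before the
thresholds are applied, to suppress sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from . import calibration
from .colour import DomainError, srgb_to_lab
from .decision import DecisionThresholds, assign_clusters, temperature_range
from .roi import EmptyROIError, ROIMask, SampleImage

__all__ = ["ClusterMap", "classify_pixels", "summarise_map", "render_cluster_map", "PALETTE"]

#: Display colours per label (0 = background) for the indexed PNG legend.
PALETTE = {
    0: (255, 255, 255),  # background
    1: (222, 205, 160),  # ivory
    2: (122, 78, 50),  # brownish-black
    3: (40, 36, 34),  # charred black
    4: (105, 105, 110),  # dark grey
    5: (160, 160, 165),  # grey
    6: (215, 215, 218),  # light grey
    7: (240, 240, 248),  # calcined white
}


@dataclass
class ClusterMap:
    """Integer label grid (0 = background, 1-7 = cluster) plus summaries."""

    labels: np.ndarray
    fractions: dict  # cluster id -> fraction of foreground pixels
    smooth_px: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_foreground(self) -> int:
        return int((self.labels > 0).sum())

    @property
    def clusters_present(self) -> list:
        return sorted(c for c, f in self.fractions.items() if f > 0)


def classify_pixels(
    img: SampleImage,
    roi: ROIMask,
    smooth_px: int = 5,
    thresholds: DecisionThresholds | None = None,
    corr: calibration.ColourCorrection | None = None,
) -> ClusterMap:
    """Assign every foreground pixel to a temperature cluster.

    Each pixel's Lab value is replaced by its mean over a ``smooth_px`` x
    ``smooth_px`` window restricted to the mask (masked normalised box
    filter), then passed through the decision thresholds.  ``smooth_px``
    must be odd and >= 1; 1 disables smoothing.
    """
    if smooth_px < 1 or smooth_px % 2 == 0:
        raise DomainError(f"smooth_px must be an odd integer >= 1, got {smooth_px!r}")
    if roi.mask.shape != img.shape:
        raise DomainError("mask shape does not match image shape")
    if roi.pixel_count == 0:
        raise EmptyROIError("cannot classify an empty ROI")

    pixels = img.pixels
    if corr is not None:
        pixels, _ = calibration.apply_colour_correction(pixels, corr)
    lab = srgb_to_lab(pixels)

    if smooth_px > 1:
        w = roi.mask.astype(float)
        den = ndimage.uniform_filter(w, size=smooth_px)
        num = ndimage.uniform_filter(lab * w[..., None], size=(smooth_px, smooth_px, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            lab = np.where(den[..., None] > 0, num / np.maximum(den, 1e-12)[..., None], 0.0)

    labels = np.zeros(img.shape, dtype=np.int8)
    L = np.clip(lab[..., 0][roi.mask], 0.0, 100.0)  # guard filter round-off
    B = lab[..., 2][roi.mask]
    labels[roi.mask] = assign_clusters(L, B, thresholds)

    fg = labels[roi.mask]
    counts = np.bincount(fg, minlength=8)
    fractions = {c: counts[c] / fg.size for c in range(1, 8)}
    return ClusterMap(
        labels,
        fractions,
        smooth_px=smooth_px,
        provenance={"mask": dict(roi.provenance), "corrected": corr is not None},
    )


def summarise_map(cm: ClusterMap) -> dict:
    """Cluster fractions and the combined temperature envelope.

    The envelope spans from the smallest minimum to the largest maximum of
    the ranges of the clusters present; it is open-ended whenever cluster 6
    or 7 contributes.
    """
    present = cm.clusters_present
    if not present:
        raise EmptyROIError("cluster map has no foreground pixels")
    ranges = [temperature_range(c) for c in present]
    open_ended = any(r.is_open for r in ranges)
    t_min = min(r.t_min_c for r in ranges)
    t_max = None if open_ended else max(r.t_max_c for r in ranges)
    return {
        "clusters_present": present,
        "fractions": {c: float(cm.fractions[c]) for c in range(1, 8)},
        "n_foreground": cm.n_foreground,
        "t_min_c": t_min,
        "t_max_c": t_max,
        "open_ended": open_ended,
        "smooth_px": cm.smooth_px,
    }


def render_cluster_map(cm: ClusterMap, path=None) -> Image.Image:
    """Render the label grid as an indexed PNG with the fixed 7-colour legend."""
    im = Image.fromarray(cm.labels.astype(np.uint8), mode="P")
    palette = []
    for idx in range(8):
        palette.extend(PALETTE[idx])
    im.putpalette(palette + [0, 0, 0] * (256 - 8))
    if path is not None:
        im.save(path)
    return im
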