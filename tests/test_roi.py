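"""Segmentation, rim erosion and mean-colour measurement."""

import numpy as np
import pytest

from conftest import make_disk_mask
from osteotherm.colour import delta_e, lab_to_srgb, srgb_to_lab
from osteotherm.roi import (
    DEFAULT_RIM_MM,
    EmptyROIError,
    ROIMask,
    SampleImage,
    TooSmallROIError,
    erode_rim,
    load_image,
    load_mask,
    measure_mean_colour,
    measurements_to_frame,
    rim_pixels,
    save_image,
    segment_sample,
)
from osteotherm.synthetic import render_sample_image

BONE_GREY = np.array([58.0, 1.0, 1.5])  # inversion-grey Lab
SOOT = np.array([20.0, 1.0, 4.0])


def image_with_disk(radius=50, colour_lab=BONE_GREY, pad=15, dpi=300.0):
    mask = make_disk_mask(radius, pad=pad)
    rgb = np.ones(mask.shape + (3,))
    fg, _ = lab_to_srgb(colour_lab)
    rgb[mask] = fg
    return SampleImage(rgb, dpi=dpi), mask


class TestSegmentation:
    def test_uniform_white_image_has_no_roi(self):
        img = SampleImage(np.ones((40, 40, 3)), dpi=300)
        with pytest.raises(EmptyROIError):
            segment_sample(img)

    def test_disk_area_recovered_within_one_percent(self):
        img, truth = image_with_disk(radius=50)
        roi = segment_sample(img)
        assert roi.pixel_count == pytest.approx(np.pi * 50**2, rel=0.01)
        assert (roi.mask == truth).all()

    def test_only_largest_blob_retained(self):
        img, truth = image_with_disk(radius=40)
        # paint a second, smaller blob
        img.pixels[5:15, 5:15] = 0.2
        roi = segment_sample(img)
        assert (roi.mask == truth).all()

    def test_holes_are_filled(self):
        img, truth = image_with_disk(radius=40)
        c = truth.shape[0] // 2
        img.pixels[c - 3 : c + 3, c - 3 : c + 3] = 1.0  # white hole inside
        roi = segment_sample(img)
        assert (roi.mask == truth).all()

    def test_otsu_fallback(self):
        img, truth = image_with_disk(radius=40)
        roi = segment_sample(img, bg_lightness_threshold=None)
        assert roi.provenance["threshold_method"] == "otsu"
        assert (roi.mask == truth).all()


class TestErodeRim:
    def test_zero_rim_is_identity(self):
        roi = ROIMask(make_disk_mask(30))
        out = erode_rim(roi, 0.0, dpi=300)
        assert (out.mask == roi.mask).all()

    def test_rim_width_to_pixels(self):
        assert rim_pixels(1.5, 300) == 18  # 1.5 mm at 300 dpi
        assert rim_pixels(2.0, 300) == 24

    def test_eroded_disk_matches_analytic_area(self):
        roi = ROIMask(make_disk_mask(50, pad=25))
        out = erode_rim(roi, 1.5, dpi=300)  # 18 px -> residual radius 32
        assert out.pixel_count == pytest.approx(np.pi * 32**2, rel=0.03)
        assert (out.mask <= roi.mask).all()  # subset

    def test_over_erosion_raises_with_counts(self):
        roi = ROIMask(make_disk_mask(10, pad=30))
        with pytest.raises(TooSmallROIError, match="px"):
            erode_rim(roi, 2.0, dpi=300)

    def test_erosion_monotone_in_rim_width(self):
        roi = ROIMask(make_disk_mask(50, pad=25))
        counts = [
            erode_rim(roi, rim, dpi=300).pixel_count for rim in (0.0, 0.5, 1.0, 1.5, 2.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMeasurement:
    def test_uniform_sample_measured_exactly(self):
        img, mask = image_with_disk(colour_lab=BONE_GREY)
        m = measure_mean_colour(img, ROIMask(mask))
        assert delta_e(m.mean_lab, BONE_GREY) < 1e-9
        assert m.n_pixels == int(mask.sum())

    def test_two_tone_sample_gives_arithmetic_mean_lab(self):
        lab1, lab2 = np.array([30.0, 0, 5.0]), np.array([80.0, 2.0, 1.0])
        c1, _ = lab_to_srgb(lab1)
        c2, _ = lab_to_srgb(lab2)
        rgb = np.ones((10, 10, 3))
        rgb[:5] = c1
        rgb[5:] = c2
        m = measure_mean_colour(SampleImage(rgb, dpi=300), ROIMask(np.ones((10, 10), bool)))
        assert np.allclose(m.mean_lab, (lab1 + lab2) / 2, atol=1e-9)

    def test_rotation_invariance(self):
        img, mask = image_with_disk(radius=30)
        img.pixels[20:40, 20:60] = 0.3  # texture
        base = measure_mean_colour(img, ROIMask(mask)).mean_lab
        rot = measure_mean_colour(
            SampleImage(np.rot90(img.pixels).copy(), dpi=300), ROIMask(np.rot90(mask).copy())
        ).mean_lab
        assert np.allclose(base, rot, atol=1e-12)

    def test_empty_mask_rejected(self):
        img, _ = image_with_disk()
        with pytest.raises(EmptyROIError):
            measure_mean_colour(img, ROIMask(np.zeros(img.shape, bool)))

    def test_soot_rim_excluded_by_default_rim_width(self):
        img = render_sample_image(BONE_GREY, shape=(200, 260), dpi=300, rim_lab=SOOT, rim_mm=1.0)
        seg = segment_sample(img)
        with_rim = measure_mean_colour(img, erode_rim(seg, DEFAULT_RIM_MM, img.dpi))
        without = measure_mean_colour(img, seg)
        assert delta_e(with_rim.mean_lab, BONE_GREY) < 0.5
        assert delta_e(without.mean_lab, BONE_GREY) > 0.5

    def test_noisy_render_recovers_mean_within_clt_bound(self, rng):
        sigma = 2.0
        img = render_sample_image(BONE_GREY, noise_sigma=sigma, rng=rng)
        seg = segment_sample(img)
        m = measure_mean_colour(img, seg)
        bound = 3 * sigma / np.sqrt(m.n_pixels) + 0.5
        assert delta_e(m.mean_lab, BONE_GREY) < bound


class TestImageIO:
    @pytest.mark.parametrize("ext", ["tif", "png"])
    def test_save_load_round_trip_with_dpi(self, tmp_path, ext):
        img = render_sample_image(BONE_GREY, shape=(60, 80), dpi=300)
        path = tmp_path / f"sample.{ext}"
        save_image(img, path)
        loaded = load_image(path)
        assert loaded.dpi == pytest.approx(300, abs=1)
        assert np.abs(loaded.pixels - img.pixels).max() <= 1.0 / 255

    def test_missing_dpi_requires_flag(self, tmp_path):
        from PIL import Image

        path = tmp_path / "nodpi.png"
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(path)
        with pytest.raises(Exception, match="dpi"):
            load_image(path)
        assert load_image(path, dpi=300).dpi == 300

    def test_manual_mask_import(self, tmp_path):
        from PIL import Image

        arr = np.zeros((20, 20), np.uint8)
        arr[5:15, 5:15] = 255
        path = tmp_path / "mask.png"
        Image.fromarray(arr).save(path)
        roi = load_mask(path)
        assert roi.pixel_count == 100
        assert roi.provenance["source"] == "manual"


def test_measurements_frame_schema():
    img, mask = image_with_disk()
    frame = measurements_to_frame([measure_mean_colour(img, ROIMask(mask))])
    assert list(frame.columns) == [
        "sample_id", "n_pixels", "R", "G", "B", "L_star", "A_star", "B_star", "rim_mm", "flags",
    ]
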