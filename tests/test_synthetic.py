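"""The synthetic generator: trajectory, factorial design, rendered slices."""

import numpy as np
import pytest

from osteotherm.colour import DomainError, delta_e, lab_to_srgb
from osteotherm.dataset import ColourDataset
from osteotherm.decision import assign_clusters
from osteotherm.synthetic import (
    DEFAULT_TRAJECTORY,
    REFERENCE_DURATION_MIN,
    DesignSpec,
    TrajectoryModel,
    expected_cluster,
    generate_dataset,
    render_sample_image,
    sample_colour,
)

NOISELESS = TrajectoryModel(sigma=0.0)


class TestTrajectory:
    def test_anchor_temperature_returns_anchor_mean_exactly(self):
        for t, lab in NOISELESS.anchors:
            assert np.allclose(sample_colour(t, model=NOISELESS), lab)

    def test_midway_temperature_is_linear_midpoint(self):
        (t0, lab0), (t1, lab1) = NOISELESS.anchors[0], NOISELESS.anchors[1]
        mid = sample_colour((t0 + t1) / 2, model=NOISELESS)
        assert np.allclose(mid, (np.asarray(lab0) + np.asarray(lab1)) / 2)

    def test_sample_mean_obeys_clt_bound(self, rng):
        t, lab = DEFAULT_TRAJECTORY.anchors[2]
        n = 200
        draws = np.array([sample_colour(t, rng=rng) for _ in range(n)])
        tol = 3 * DEFAULT_TRAJECTORY.sigma / np.sqrt(n)
        assert np.abs(draws.mean(axis=0) - np.asarray(lab)).max() < tol

    def test_extrapolation_rejected(self):
        with pytest.raises(DomainError, match="span"):
            sample_colour(1000.0, model=NOISELESS)

    def test_duration_and_medium_shifts_are_small_and_additive(self):
        base = NOISELESS.mean_colour(400.0)
        long = NOISELESS.mean_colour(400.0, duration_min=50.0)
        fat = NOISELESS.mean_colour(400.0, medium="adipose")
        assert 0 < np.abs(long - base).max() < 2.0  # order of magnitude below T effect
        assert np.allclose(fat - base, NOISELESS.medium_shift)

    def test_b_star_nonincreasing_above_carbonisation(self):
        anchors = [(t, lab) for t, lab in DEFAULT_TRAJECTORY.anchors if t >= 250]
        bs = [lab[2] for _, lab in anchors]
        assert all(a >= b for a, b in zip(bs, bs[1:]))

    def test_l_star_falls_to_charring_then_rises_to_calcination(self):
        ls = [lab[0] for _, lab in DEFAULT_TRAJECTORY.anchors]
        k = int(np.argmin(ls))
        assert 0 < k < len(ls) - 1
        assert all(a >= b for a, b in zip(ls[: k + 1], ls[1 : k + 1]))
        assert all(a <= b for a, b in zip(ls[k:], ls[k + 1 :]))

    def test_every_anchor_inside_a_containing_cluster(self):
        for t, lab in DEFAULT_TRAJECTORY.anchors:
            cid = expected_cluster(t)
            from osteotherm.decision import temperature_range

            assert temperature_range(cid).contains(t)

    def test_misplaced_anchor_rejected(self):
        with pytest.raises(DomainError, match="anchor"):
            TrajectoryModel(anchors=((20.0, (90.0, 0.0, 1.0)), (900.0, (93.0, 0.0, 0.5))))

    def test_non_monotone_anchor_temperatures_rejected(self):
        with pytest.raises(DomainError, match="increasing"):
            TrajectoryModel(anchors=((300.0, (26.0, 6.0, 16.0)), (20.0, (65.0, 7.0, 18.0))))


class TestGenerateDataset:
    def test_single_subgroup_counts_and_ids(self):
        spec = DesignSpec(temperatures=(500.0,), durations=(20.0,), media=("air",),
                          n_per_subgroup=10, seed=3)
        ds = generate_dataset(spec)
        assert len(ds) == 10
        assert ds.frame["sample_id"].is_unique
        assert (ds.frame["temperature_c"] == 500.0).all()
        assert (ds.frame["medium"] == "air").all()

    def test_full_factorial_count_with_adipose_cutoff(self):
        spec = DesignSpec(seed=0)
        n_air = len(spec.temperatures) * len(spec.durations)
        n_fat = sum(1 for t in spec.temperatures if t <= spec.adipose_max_c) * len(spec.durations)
        assert len(generate_dataset(spec)) == (n_air + n_fat) * spec.n_per_subgroup

    def test_seed_fixes_dataset_byte_for_byte(self):
        a = generate_dataset(DesignSpec(seed=5)).frame.to_csv(index=False)
        b = generate_dataset(DesignSpec(seed=5)).frame.to_csv(index=False)
        assert a == b
        c = generate_dataset(DesignSpec(seed=6)).frame.to_csv(index=False)
        assert a != c

    def test_rgb_columns_derive_from_lab(self, learning_set):
        row = learning_set.frame.iloc[0]
        rgb, _ = lab_to_srgb(np.array([row["L_star"], row["A_star"], row["B_star"]]))
        assert np.allclose(rgb * 255.0, row[["R", "G", "B"]].to_numpy(dtype=float), atol=1e-9)

    def test_is_valid_colour_dataset(self, learning_set):
        assert isinstance(learning_set, ColourDataset)
        assert learning_set.role == "learning"
        assert learning_set.frame.attrs["seed"] == 7

    def test_anchor_subgroups_classify_into_expected_clusters(self, learning_set):
        frame = learning_set.frame
        anchored = frame[frame["temperature_c"].isin([t for t, _ in DEFAULT_TRAJECTORY.anchors])]
        got = assign_clusters(anchored["L_star"].to_numpy(), anchored["B_star"].to_numpy())
        expected = anchored["temperature_c"].map(lambda t: expected_cluster(t)).to_numpy()
        assert (got == expected).mean() >= 0.95


class TestRenderSampleImage:
    def test_noiseless_render_is_uniform_quantized_mean(self):
        lab = np.array([58.0, 1.0, 1.5])
        img = render_sample_image(lab, shape=(60, 80), quantize=True)
        rgb, _ = lab_to_srgb(lab)
        expected = np.round(rgb * 255.0) / 255.0
        fg = ~np.all(img.pixels == 1.0, axis=-1)
        assert fg.sum() > 0
        assert np.abs(img.pixels[fg] - expected).max() == 0.0

    def test_rim_contamination_is_confined_to_stated_width(self):
        lab, soot = np.array([58.0, 1.0, 1.5]), np.array([20.0, 1.0, 4.0])
        img = render_sample_image(lab, shape=(120, 160), dpi=300, rim_lab=soot, rim_mm=1.0)
        clean = render_sample_image(lab, shape=(120, 160), dpi=300)
        diff = np.any(img.pixels != clean.pixels, axis=-1)
        # contaminated pixels exist but stay near the boundary
        assert diff.any()
        from scipy import ndimage

        fg = ~np.all(clean.pixels == 1.0, axis=-1)
        depth = ndimage.distance_transform_edt(fg)
        assert depth[diff].max() <= 1.0 * 300 / 25.4 + 1e-9

    def test_dpi_embedded(self):
        img = render_sample_image(np.array([58.0, 1.0, 1.5]), dpi=600)
        assert img.dpi == 600

    def test_rendered_mean_recovered(self):
        """ROI measurement of a rendered slice returns the generating mean."""
        from osteotherm.roi import measure_mean_colour, segment_sample

        lab = np.array([26.0, 6.0, 16.0])
        img = render_sample_image(lab, shape=(100, 130), quantize=False)
        m = measure_mean_colour(img, segment_sample(img))
        assert delta_e(m.mean_lab, lab) < 1e-9
        # 8-bit quantization displaces a uniform colour by at most ~1 ΔE
        q = render_sample_image(lab, shape=(100, 130), quantize=True)
        mq = measure_mean_colour(q, segment_sample(q))
        assert delta_e(mq.mean_lab, lab) < 1.0
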