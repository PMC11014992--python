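"""Macro-style fluorescence quantifications and their primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcoquant import (
    ImageStack,
    ParticleFilter,
    Roi,
    TmreConfig,
    count_particles,
    gaussian_blur,
    generate_fillet_image,
    generate_two_channel,
    isodata_threshold,
    max_project,
    muscle_integrity,
    nuclear_ratio,
    percent_active_mitochondria,
    remove_outliers,
    tccf,
    to_8bit,
)
from sarcoquant.synth import tmre_field_spec
from conftest import exhaustive_intermeans_splits


class TestMaxProject:
    def test_single_plane_identity(self):
        plane = np.arange(12.0).reshape(3, 4)
        stack = ImageStack(plane, 0.1)
        np.testing.assert_array_equal(max_project(stack), plane)

    def test_pointwise_maximum(self):
        a = np.arange(12.0).reshape(3, 4)
        stack = ImageStack(np.stack([a, 2 * a]), 0.1)
        np.testing.assert_array_equal(max_project(stack), 2 * a)

    def test_identical_planes(self):
        a = np.random.default_rng(0).random((4, 4))
        stack = ImageStack(np.stack([a, a, a]), 0.1)
        np.testing.assert_array_equal(max_project(stack), a)


class TestTo8bit:
    def test_full_range_16bit(self):
        img = np.array([[0, 65535]])
        np.testing.assert_array_equal(to_8bit(img), [[0, 255]])

    def test_constant_maps_to_zero(self):
        assert (to_8bit(np.full((3, 3), 123.0)) == 0).all()

    def test_rounding_half_up(self):
        img = np.array([[0.0, 100.0, 200.0]])
        np.testing.assert_array_equal(to_8bit(img), [[0, 128, 255]])


class TestGaussianBlur:
    def test_sigma_zero_identity(self):
        img = np.random.default_rng(1).random((6, 6))
        np.testing.assert_array_equal(gaussian_blur(img, 0), img)

    def test_constant_preserved(self):
        img = np.full((8, 8), 5.0)
        np.testing.assert_allclose(gaussian_blur(img, 2.0), img)

    def test_interior_mass_conserved(self):
        rng = np.random.default_rng(2)
        img = np.zeros((64, 64))
        img[24:40, 24:40] = rng.random((16, 16)) * 100
        blurred = gaussian_blur(img, 1.5)
        assert blurred.sum() == pytest.approx(img.sum(), rel=1e-3)


class TestRemoveOutliers:
    def test_hot_pixel_despeckled(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 255.0
        out = remove_outliers(img, radius_px=2, threshold=50)
        assert out[4, 4] == 10.0
        np.testing.assert_array_equal(out, np.full((9, 9), 10.0))

    def test_unreachable_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (12, 12)).astype(float)
        np.testing.assert_array_equal(
            remove_outliers(img, 2, threshold=256), img
        )

    def test_uniform_gradient_unchanged(self):
        img = np.tile(np.arange(30.0), (10, 1))  # slope 1/px << threshold
        np.testing.assert_array_equal(remove_outliers(img, 2, 50), img)

    def test_dark_mode(self):
        img = np.full((9, 9), 200.0)
        img[4, 4] = 0.0
        out = remove_outliers(img, 2, 50, mode="dark")
        assert out[4, 4] == 200.0


class TestIsodata:
    def test_two_value_image(self):
        rng = np.random.default_rng(4)
        img = np.where(rng.random((20, 20)) < 0.5, 10.0, 200.0)
        t, mask = isodata_threshold(img)
        assert t == pytest.approx(105.0)
        np.testing.assert_array_equal(mask, img == 200)

    def test_bimodal_gaussians(self):
        rng = np.random.default_rng(5)
        img = np.concatenate(
            [rng.normal(50, 10, 500), rng.normal(200, 10, 500)]
        ).reshape(20, 50)
        t, _ = isodata_threshold(img)
        assert 115 <= t <= 135

    def test_offset_equivariance(self):
        rng = np.random.default_rng(6)
        img = np.where(rng.random((15, 15)) < 0.4, 30.0, 170.0) + rng.normal(
            0, 3, (15, 15)
        )
        t, mask = isodata_threshold(img)
        t2, mask2 = isodata_threshold(img + 37.5)
        assert t2 == pytest.approx(t + 37.5)
        np.testing.assert_array_equal(mask, mask2)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.full((4, 4), 9.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_fixed_point(self, seed):
        rng = np.random.default_rng(700 + seed)
        n0 = int(rng.integers(50, 200))
        n1 = int(rng.integers(50, 200))
        img = np.concatenate(
            [
                rng.normal(rng.uniform(20, 80), rng.uniform(5, 20), n0),
                rng.normal(rng.uniform(140, 230), rng.uniform(5, 20), n1),
            ]
        )
        img = np.clip(np.rint(img), 0, 255)
        t, _ = isodata_threshold(img)
        gaps = exhaustive_intermeans_splits(img)
        assert gaps, "no intermeans fixed point found by enumeration"
        assert any(lo <= t < hi for lo, hi in gaps)


class TestPercentActive:
    def test_identical_channels_are_fully_active(self):
        spec = tmre_field_spec(rng_seed=1)
        total, _, _ = generate_two_channel(spec, 0.5)
        res = percent_active_mitochondria(total, total)
        assert res.percent_active == pytest.approx(100.0)
        assert not res.flagged_over_100

    def test_signal_free_active_channel(self):
        # constant background in the active channel -> zero active area
        plane = np.full((64, 64), 20.0)
        plane[10:30, 10:30] = 180.0
        total = ImageStack(plane, 0.1)
        active = ImageStack(np.full((64, 64), 20.0), 0.1)
        res = percent_active_mitochondria(active_stack=active, total_stack=total)
        assert res.percent_active == 0.0

    @pytest.mark.parametrize("fraction", [0.2, 0.5, 0.8])
    def test_designed_fraction_recovered(self, fraction):
        spec = tmre_field_spec(rng_seed=31)
        total, active, _ = generate_two_channel(spec, fraction)
        res = percent_active_mitochondria(total, active)
        assert abs(res.percent_active - 100 * fraction) <= 5.0

    def test_mismatched_calibration_rejected(self):
        a = ImageStack(np.zeros((4, 4)) + np.eye(4), 0.1)
        b = ImageStack(np.zeros((4, 4)) + np.eye(4), 0.2)
        with pytest.raises(ValueError, match="calibration"):
            percent_active_mitochondria(a, b)


def _disk_mask(shape, centers, radius):
    mask = np.zeros(shape, bool)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return mask


class TestCountParticles:
    def test_three_disks_counted(self):
        mask = _disk_mask((60, 60), [(10, 10), (30, 30), (50, 50)], 4)
        count, areas, _ = count_particles(mask, ParticleFilter(0, 10), 0.2, 1.0)
        assert count == 3
        assert areas.size == 3

    def test_size_filter_partitions_at_boundary(self):
        # one small (area < 2 um^2) and one large disk
        mask = _disk_mask((60, 60), [(15, 15)], 2) | _disk_mask((60, 60), [(45, 45)], 8)
        px = 0.2
        counts = {}
        for name, filt in {
            "intra": ParticleFilter(0, 2.0),
            "extra": ParticleFilter(2.0, np.inf),
        }.items():
            counts[name], _, _ = count_particles(mask, filt, px, 1.0)
        assert counts["intra"] == 1
        assert counts["extra"] == 1

    def test_widening_filter_is_monotone(self):
        rng = np.random.default_rng(8)
        mask = rng.random((80, 80)) < 0.2
        px = 0.3
        prev = -1
        for hi in (0.5, 1.0, 5.0, np.inf):
            count, _, _ = count_particles(mask, ParticleFilter(0, hi), px, 1.0)
            assert count >= prev
            prev = count

    def test_density_normalisation(self):
        mask = _disk_mask((100, 100), [(20, 20), (60, 60)], 3)
        _, _, density = count_particles(mask, ParticleFilter(0, np.inf), 0.1, 0.01)
        assert density == pytest.approx(200.0)

    def test_eight_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True  # diagonal touch = one particle
        count, _, _ = count_particles(mask, ParticleFilter(0, np.inf), 1.0, 1.0)
        assert count == 1

    def test_invalid_filter(self):
        with pytest.raises(ValueError):
            ParticleFilter(5.0, 2.0)


class TestTccf:
    def test_uniform_image_gives_zero(self):
        img = np.full((30, 30), 42.0)
        res = tccf(
            img,
            Roi("rectangle", [(5, 5), (14, 14)]),
            [Roi("rectangle", [(20, 20), (28, 28)])],
        )
        assert res.tccf == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # 100-px cell ROI at 50 on a background of 10 -> 5000 - 100x10
        img = np.full((30, 30), 10.0)
        img[0:10, 0:10] = 50.0
        res = tccf(
            img,
            Roi("rectangle", [(0, 0), (9, 9)]),
            [Roi("rectangle", [(15, 15), (24, 24)])],
        )
        assert res.integrated_density == pytest.approx(5000.0)
        assert res.roi_area_px == 100
        assert res.background_mean == pytest.approx(10.0)
        assert res.tccf == pytest.approx(4000.0)

    @given(st.floats(min_value=-100, max_value=100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(9)
        img = rng.random((20, 20)) * 100
        cell = Roi("rectangle", [(2, 2), (8, 8)])
        bg = [Roi("rectangle", [(12, 12), (18, 18)])]
        base = tccf(img, cell, bg).tccf
        shifted = tccf(img + offset, cell, bg).tccf
        assert shifted == pytest.approx(base, abs=1e-6)

    def test_overlapping_rois_warn(self):
        img = np.ones((10, 10))
        with pytest.warns(UserWarning, match="overlap"):
            tccf(
                img,
                Roi("rectangle", [(0, 0), (5, 5)]),
                [Roi("rectangle", [(4, 4), (9, 9)])],
            )

    def test_polygon_roi(self):
        img = np.zeros((20, 20))
        img[:10, :] = 60.0
        cell = Roi("polygon", [(0, 0), (0, 19), (9, 19), (9, 0)])
        res = tccf(img, cell, [Roi("rectangle", [(15, 0), (19, 19)])])
        assert res.background_mean == 0.0
        assert res.tccf == pytest.approx(img[:10].sum())


class TestNuclearRatio:
    def test_identical_channels(self):
        img = np.random.default_rng(10).random((12, 12)) + 1
        rois = [Roi("rectangle", [(0, 0), (4, 4)]), Roi("rectangle", [(6, 6), (10, 10)])]
        assert nuclear_ratio(img, img, rois) == pytest.approx([1.0, 1.0])

    def test_doubled_numerator(self):
        img = np.random.default_rng(11).random((12, 12)) + 1
        rois = [Roi("rectangle", [(0, 0), (4, 4)])]
        assert nuclear_ratio(2 * img, img, rois) == pytest.approx([2.0])

    def test_mean_ratio(self):
        num = np.full((10, 10), 30.0)
        den = np.full((10, 10), 60.0)
        assert nuclear_ratio(num, den, [Roi("rectangle", [(1, 1), (5, 5)])]) == [0.5]

    def test_zero_denominator_is_nan_others_returned(self):
        num = np.ones((10, 10))
        den = np.ones((10, 10))
        den[:5, :] = 0.0
        rois = [Roi("rectangle", [(0, 0), (3, 3)]), Roi("rectangle", [(6, 6), (9, 9)])]
        with pytest.warns(UserWarning, match="denominator"):
            ratios = nuclear_ratio(num, den, rois)
        assert np.isnan(ratios[0])
        assert ratios[1] == pytest.approx(1.0)


class TestMuscleIntegrity:
    def test_fully_bright_roi(self):
        img = np.full((40, 40), 200.0)
        raw, norm = muscle_integrity(img, Roi("rectangle", [(0, 0), (39, 39)]))
        assert raw == 1.0
        assert norm is None

    def test_fillet_recovery_at_half(self):
        stack, realized = generate_fillet_image(attached_fraction=0.5, rng_seed=13)
        roi = Roi("rectangle", [(0, 0), (511, 511)])
        raw, _ = muscle_integrity(stack.max_projection(), roi)
        assert 0.45 <= raw <= 0.55

    def test_self_normalisation(self):
        stack, _ = generate_fillet_image(attached_fraction=0.4, rng_seed=14)
        roi = Roi("rectangle", [(0, 0), (511, 511)])
        raw, _ = muscle_integrity(stack.max_projection(), roi)
        _, norm = muscle_integrity(stack.max_projection(), roi, control_mean=raw)
        assert norm == pytest.approx(1.0)
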