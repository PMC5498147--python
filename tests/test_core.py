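"""Unit tests for the per-time-point tracking computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apextrack import (
    AxisMap,
    Displacement,
    FrameStack,
    LateralShift,
    StagePosition,
    TrackerConfig,
    ZeroVarianceError,
    crop_roi,
    filter_variants,
    max_intensity_project,
    predict_positions,
    robust_shift,
    update_displacement,
    xcorr_shift,
)
from apextrack.core import correlation_surface

from _oracles import (
    brute_force_correlation_surface,
    per_pixel_max_projection,
    smooth_texture,
)


def _stack(arr_czhw, **kwargs):
    defaults = dict(pixel_size=1.0, time_index=0, time_h=0.0, specimen_id="s")
    defaults.update(kwargs)
    return FrameStack(intensities=np.asarray(arr_czhw), **defaults)


class TestMaxIntensityProject:
    def test_single_plane_is_identity(self, rng):
        plane = rng.integers(0, 100, (1, 1, 8, 9))
        np.testing.assert_array_equal(
            max_intensity_project(_stack(plane), 0), plane[0, 0]
        )

    def test_max_with_zero_plane(self, rng):
        arbitrary = rng.integers(0, 1000, (7, 6))
        stack = np.stack([np.zeros((7, 6), int), arbitrary])[None]
        np.testing.assert_array_equal(max_intensity_project(_stack(stack), 0), arbitrary)

    def test_matches_per_pixel_loop_oracle(self, rng):
        stack = rng.integers(0, 500, (2, 4, 10, 11))
        for ch in range(2):
            np.testing.assert_array_equal(
                max_intensity_project(_stack(stack), ch),
                per_pixel_max_projection(stack, ch),
            )

    def test_invariant_to_z_permutation(self, rng):
        stack = rng.integers(0, 500, (1, 5, 6, 6))
        perm = rng.permutation(5)
        np.testing.assert_array_equal(
            max_intensity_project(_stack(stack), 0),
            max_intensity_project(_stack(stack[:, perm]), 0),
        )

    def test_invalid_channel_names_the_channel(self):
        with pytest.raises(IndexError, match="channel 3"):
            max_intensity_project(_stack(np.zeros((1, 1, 4, 4))), 3)


class TestFrameStackInvariants:
    def test_rejects_wrong_dimensionality(self):
        with pytest.raises(ValueError, match="4-D"):
            _stack(np.zeros((2, 4, 4)))

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError, match="pixel_size"):
            _stack(np.zeros((1, 1, 4, 4)), pixel_size=0.0)

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError, match="non-negative"):
            _stack(np.full((1, 1, 2, 2), -1.0))


class TestCropRoi:
    def test_study_frame_third(self):
        # a 1400 px frame cropped to one third -> 466 px centered window
        img = np.arange(1400 * 1400, dtype=float).reshape(1400, 1400)
        roi = crop_roi(img, 1 / 3)
        assert roi.shape == (466, 466)
        np.testing.assert_array_equal(roi, img[467:933, 467:933])

    def test_fraction_one_returns_largest_centered_square(self, rng):
        img = rng.random((12, 17))
        roi = crop_roi(img, 1.0)
        assert roi.shape == (12, 12)
        np.testing.assert_array_equal(roi, img[:, 2:14])
        square = rng.random((10, 10))
        np.testing.assert_array_equal(crop_roi(square, 1.0), square)

    def test_exact_division_center(self):
        img = np.arange(81, dtype=float).reshape(9, 9)
        np.testing.assert_array_equal(crop_roi(img, 1 / 3), img[3:6, 3:6])

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            crop_roi(np.zeros((5, 5)), bad)


class TestFilterVariants:
    def test_constant_image_preserved(self, default_config):
        img = np.full((6, 6), 7.0)
        for variant in filter_variants(img, default_config):
            np.testing.assert_allclose(variant, img)

    def test_kernel_one_is_identity(self, rng):
        img = rng.random((8, 8))
        cfg = TrackerConfig(mean_kernel_px=1, median_kernel_px=1)
        raw, mean_f, median_f = filter_variants(img, cfg)
        np.testing.assert_allclose(mean_f, img)
        np.testing.assert_allclose(median_f, img)

    def test_hot_pixel_removed_by_median_attenuated_by_mean(self, default_config):
        img = np.zeros((5, 5))
        img[2, 2] = 90.0
        _, mean_f, median_f = filter_variants(img, default_config)
        assert median_f[2, 2] == 0.0  # 3x3 window median of {0 x8, 90}
        assert mean_f[2, 2] == pytest.approx(10.0)  # 1/9 of the excess

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(mean_kernel_px=4)
        cfg = TrackerConfig()
        object.__setattr__(cfg, "median_kernel_px", 2)
        with pytest.raises(ValueError, match="odd"):
            filter_variants(np.zeros((4, 4)), cfg)


class TestXcorrShift:
    def test_identical_images_give_zero(self, rng):
        img = smooth_texture(rng)
        assert xcorr_shift(img, img) == LateralShift(0.0, 0.0)

    def test_recovers_constructed_circular_shift(self, rng):
        ref = smooth_texture(rng, (96, 96))
        cur = np.roll(ref, (-3, 5), axis=(0, 1))  # content moved dy=-3, dx=+5
        assert xcorr_shift(ref, cur) == LateralShift(5.0, -3.0)

    def test_surface_matches_brute_force_oracle(self, rng):
        for shape in [(16, 16), (32, 32), (13, 21)]:
            ref = rng.random(shape)
            cur = rng.random(shape)
            np.testing.assert_allclose(
                correlation_surface(ref, cur),
                brute_force_correlation_surface(ref, cur),
                rtol=1e-6,
                atol=1e-9,
            )

    def test_subpixel_refinement_on_half_pixel_offset(self):
        # band-limited pattern sampled at two offsets 2.5 px apart
        x = np.arange(64)
        xx, yy = np.meshgrid(x, x)

        def render(offset):
            return np.exp(-((xx - 30.0 - offset) ** 2 + (yy - 32.0) ** 2) / (2 * 6.0**2))

        shift = xcorr_shift(render(0.0), render(2.5), subpixel=True)
        assert shift.dy_px == pytest.approx(0.0, abs=0.3)
        assert shift.dx_px == pytest.approx(2.5, abs=0.3)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            xcorr_shift(rng.random((8, 8)), rng.random((8, 9)))

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ZeroVarianceError):
            xcorr_shift(np.full((8, 8), 3.0), rng.random((8, 8)))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        dy=st.integers(-15, 15),
        dx=st.integers(-15, 15),
    )
    def test_exact_recovery_of_integer_shifts(self, seed, dy, dx):
        """Any integer shift of magnitude < ROI/4 is recovered exactly."""
        r = np.random.default_rng(seed)
        ref = smooth_texture(r, (64, 64))
        cur = np.roll(ref, (dy, dx), axis=(0, 1))
        assert xcorr_shift(ref, cur) == LateralShift(float(dx), float(dy))


class TestRobustShift:
    def test_all_variants_agree(self, rng, default_config):
        ref = smooth_texture(rng, (96, 96))
        cur = np.roll(ref, (4, -2), axis=(0, 1))
        assert robust_shift(ref, cur, default_config) == LateralShift(-2.0, 4.0)

    def test_median_rejects_single_outlier_component(self):
        shifts = [(2.0, 1.0), (2.0, 1.0), (40.0, -40.0)]
        assert float(np.median([s[0] for s in shifts])) == 2.0
        assert float(np.median([s[1] for s in shifts])) == 1.0

    def test_salt_and_pepper_noise_does_not_derail_fused_shift(
        self, root_world, scaled_geometry, centered_position
    ):
        """Median-of-three recovers the true shift under 5% impulsive noise."""
        from apextrack import render_view

        true = LateralShift(8.0, 20.0)
        px = scaled_geometry["pixel_size"]
        f0 = render_view(root_world, centered_position, (160, 160), px, 1, 0.0)
        ref = crop_roi(f0.intensities[0, 0].astype(float), 1.0)
        cur = np.roll(ref, (int(true.dy_px), int(true.dx_px)), axis=(0, 1))
        r = np.random.default_rng(99)
        n_sp = int(0.05 * cur.size)
        idx = r.choice(cur.size, n_sp, replace=False)
        noisy = cur.copy().reshape(-1)
        noisy[idx[: n_sp // 2]] = 0
        noisy[idx[n_sp // 2 :]] = cur.max()
        noisy = noisy.reshape(cur.shape)
        assert robust_shift(ref, noisy, TrackerConfig()) == true

    def test_output_bounded_by_variant_shifts(self, rng, default_config):
        ref = smooth_texture(rng, (48, 48))
        cur = np.roll(ref, (3, 1), axis=(0, 1)) + rng.normal(0, 0.05, (48, 48))
        variants_r = filter_variants(ref, default_config)
        variants_c = filter_variants(cur, default_config)
        shifts = [xcorr_shift(a, b) for a, b in zip(variants_r, variants_c)]
        fused = robust_shift(ref, cur, default_config)
        assert min(s.dx_px for s in shifts) <= fused.dx_px <= max(s.dx_px for s in shifts)
        assert min(s.dy_px for s in shifts) <= fused.dy_px <= max(s.dy_px for s in shifts)


class TestDisplacementUpdate:
    def test_zero_shift_is_identity(self):
        d = update_displacement(Displacement(0, 0), LateralShift(0, 0), 0.457)
        assert d == Displacement(0.0, 0.0)

    def test_arithmetic_at_study_pixel_size(self):
        d = update_displacement(Displacement(10.0, -5.0), LateralShift(3.0, 2.0), 0.457)
        assert d.dx_um == pytest.approx(11.371)
        assert d.dy_um == pytest.approx(-4.086)

    def test_axis_flip_on_zero_component(self):
        amap = AxisMap(sign_y=-1)
        d = update_displacement(Displacement(1.0, 1.0), LateralShift(1.0, 0.0), 0.457, amap)
        assert d == Displacement(1.457, 1.0)

    def test_axis_swap(self):
        amap = AxisMap(swap_xy=True)
        d = update_displacement(Displacement(0, 0), LateralShift(2.0, 3.0), 1.0, amap)
        assert d == Displacement(3.0, 2.0)


class TestPredictPositions:
    def test_adds_displacement(self):
        p = StagePosition("a", 100.0, 200.0)
        (out,) = predict_positions([p], {"a": Displacement(5.0, -2.0)})
        assert (out.x_um, out.y_um) == (105.0, 198.0)

    def test_zero_displacement_unchanged(self):
        ps = [StagePosition("a", 1.0, 2.0), StagePosition("b", 3.0, 4.0)]
        zero = {pid: Displacement(0, 0) for pid in "ab"}
        assert predict_positions(ps, zero) == ps

    def test_inactive_kept_verbatim(self):
        p = StagePosition("a", 1.0, 2.0, active=False)
        (out,) = predict_positions([p], {"a": Displacement(100.0, 100.0)})
        assert out == p

    def test_missing_displacement_for_active_is_error(self):
        with pytest.raises(KeyError, match="'a'"):
            predict_positions([StagePosition("a", 0, 0)], {})

    def test_update_then_predict_is_linear(self):
        """Applying shifts Δ1 then Δ2 equals applying Δ1+Δ2 in one step."""
        p = StagePosition("a", 10.0, 20.0)
        px = 0.7
        zero = Displacement(0, 0)
        d1 = update_displacement(zero, LateralShift(3, -1), px)
        d2 = update_displacement(zero, LateralShift(-5, 4), px)
        d12 = update_displacement(zero, LateralShift(3 - 5, -1 + 4), px)
        (seq,) = predict_positions(predict_positions([p], {"a": d1}), {"a": d2})
        (one,) = predict_positions([p], {"a": d12})
        assert seq.x_um == pytest.approx(one.x_um)
        assert seq.y_um == pytest.approx(one.y_um)
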