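"""Drift compensation and fixed-image preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metquant.imageprep import (
    DriftTable,
    apply_drift,
    estimate_drift,
    restore_coordinates,
    subtract_background_paraboloid,
    threshold_stack_histogram,
    to_8bit_inverted,
)
from metquant.stack import MovieStack
from metquant.synthio import MovieSimParams, simulate_movie


def _textured_frame(rng, shape=(10, 64, 64)):
    frame = rng.normal(20, 3, shape)
    for _ in range(12):
        c = rng.uniform([2, 8, 8], np.array(shape) - [2, 8, 8])
        zz, yy, xx = np.indices(shape)
        frame += 80 * np.exp(
            -((zz - c[0]) ** 2 / 4 + (yy - c[1]) ** 2 / 8 + (xx - c[2]) ** 2 / 8)
        )
    return frame


class TestDrift:
    def test_constructed_integer_shift_recovered(self):
        rng = np.random.default_rng(0)
        f0 = _textured_frame(rng)
        f1 = np.roll(f0, (0, 3, 1), axis=(0, 1, 2))
        movie = MovieStack(np.stack([f0, f1]), (1.5, 0.5, 0.5), 2.0)
        drift = estimate_drift(movie)
        assert np.array_equal(drift.shifts[1], [0, 3, 1])

    def test_static_movie_gives_zero_table(self):
        rng = np.random.default_rng(1)
        f = _textured_frame(rng)
        movie = MovieStack(np.stack([f, f, f]), (1.5, 0.5, 0.5), 2.0)
        assert np.all(estimate_drift(movie).shifts == 0)

    def test_blank_frames_warn_and_zero(self):
        movie = MovieStack(np.zeros((3, 4, 16, 16)), (1.5, 0.5, 0.5), 2.0)
        with pytest.warns(UserWarning, match="blank"):
            drift = estimate_drift(movie)
        assert np.all(drift.shifts == 0)

    def test_subvoxel_drift_accumulates_within_one_voxel(self):
        """0.5 px/frame programmed drift: cumulative estimate within ±1
        voxel of ground truth at every frame."""
        params = MovieSimParams(
            image_shape_voxels=(12, 12, 128, 128),
            n_pmec=5, n_icp=5,
            speed_um_per_min=0.0,
            step_noise_sd_um=0.0,
            global_drift_um_per_frame=(0.0, 0.25, 0.25),
            seed=21,
        )
        movie, gt = simulate_movie(params)
        drift = estimate_drift(movie)
        truth_vox = (
            gt.drift[["dz_um", "dy_um", "dx_um"]].to_numpy()
            / np.array(params.voxel_size_um)
        )
        assert np.all(np.abs(drift.shifts - truth_vox) <= 1.0)

    def test_apply_zero_table_is_identity(self):
        rng = np.random.default_rng(2)
        f = _textured_frame(rng)
        movie = MovieStack(np.stack([f, f]), (1.5, 0.5, 0.5), 2.0)
        out = apply_drift(movie, DriftTable(np.zeros((2, 3), dtype=int)))
        assert np.array_equal(out.data, movie.data)

    def test_apply_then_estimate_residual_below_one_voxel(self):
        rng = np.random.default_rng(3)
        f0 = _textured_frame(rng)
        frames = [f0]
        for t in range(1, 4):
            frames.append(np.roll(f0, (0, 2 * t, -t), axis=(0, 1, 2)))
        movie = MovieStack(np.stack(frames), (1.5, 0.5, 0.5), 2.0)
        compensated = apply_drift(movie, estimate_drift(movie))
        residual = estimate_drift(compensated)
        assert np.all(np.abs(residual.shifts) <= 1)

    def test_excessive_shift_raises(self):
        movie = MovieStack(np.zeros((2, 4, 8, 8)) + 1.0, (1.5, 0.5, 0.5), 2.0)
        with pytest.raises(ValueError, match="extent"):
            apply_drift(movie, DriftTable([[0, 0, 0], [0, 0, 9]]))

    def test_restore_adds_back_cancelled_shift(self):
        drift = DriftTable([[0, 0, 0], [0, -3, -1]])
        points = pd.DataFrame(
            {"frame": [1], "z_um": [3.0], "y_um": [10.0], "x_um": [10.0]}
        )
        out = restore_coordinates(points, drift, (1.5, 0.5, 0.5))
        # frame content was shifted by (0, +3, +1) voxels to cancel a drift
        # of (0, -3, -1); restoration subtracts the applied shift in µm
        assert out.loc[0, "y_um"] == pytest.approx(10.0 - 3 * 0.5)
        assert out.loc[0, "x_um"] == pytest.approx(10.0 - 1 * 0.5)
        assert out.loc[0, "z_um"] == pytest.approx(3.0)

    def test_restore_zero_table_is_identity(self):
        drift = DriftTable(np.zeros((2, 3), dtype=int))
        points = pd.DataFrame(
            {"frame": [0, 1], "z_um": [1.0, 2.0], "y_um": [3.0, 4.0], "x_um": [5.0, 6.0]}
        )
        pd.testing.assert_frame_equal(
            restore_coordinates(points, drift, (1.5, 0.5, 0.5)), points
        )

    def test_restore_bad_frame_index_raises(self):
        drift = DriftTable(np.zeros((2, 3), dtype=int))
        points = pd.DataFrame({"frame": [5], "z_um": [0.0], "y_um": [0.0], "x_um": [0.0]})
        with pytest.raises(IndexError):
            restore_coordinates(points, drift, (1.5, 0.5, 0.5))

    def test_drift_table_frame0_must_be_zero(self):
        with pytest.raises(ValueError):
            DriftTable([[1, 0, 0], [0, 0, 0]])


class TestEightBitInverted:
    def test_extremes_map_to_0_and_255(self):
        image = np.array([[0.0, 4095.0]])
        out = to_8bit_inverted(image)
        assert out[0, 0] == 255 and out[0, 1] == 0

    def test_twice_equals_rescale_only(self):
        rng = np.random.default_rng(4)
        image = rng.uniform(0, 1000, (32, 32))
        once = to_8bit_inverted(image)
        twice = to_8bit_inverted(once)
        rescaled = np.round(
            (image - image.min()) * 255.0 / (image.max() - image.min())
        )
        assert np.max(np.abs(twice.astype(float) - rescaled)) <= 1.0

    def test_constant_image_inverts_to_255(self):
        assert np.all(to_8bit_inverted(np.full((4, 4), 7.0)) == 255)


class TestParaboloidBackground:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background_paraboloid(np.full((40, 40), 60.0), 20)
        assert np.allclose(out, 0.0)

    def test_narrow_spot_amplitude_preserved(self):
        """A spot much narrower than the paraboloid survives subtraction
        within 10% (morphological-opening oracle: the opening removes it)."""
        yy, xx = np.indices((80, 80))
        spot = 100.0 * np.exp(-((yy - 40) ** 2 + (xx - 40) ** 2) / (2 * 2.0**2))
        image = 30.0 + spot
        out = subtract_background_paraboloid(image, 50)
        assert abs(out.max() - 100.0) <= 10.0

    def test_broad_parabolic_background_removed(self):
        yy, xx = np.indices((80, 80))
        bg = 100.0 - ((yy - 40) ** 2 + (xx - 40) ** 2) / 400.0
        out = subtract_background_paraboloid(bg, 150)
        assert out.max() <= 0.05 * 100.0

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(5)
        yy, xx = np.indices((60, 60))
        image = 40 + 0.3 * yy + rng.normal(0, 2, (60, 60))
        image += 90 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 18.0)
        once = subtract_background_paraboloid(image, 30)
        twice = subtract_background_paraboloid(once, 30)
        assert np.max(np.abs(twice - once)) < 0.01 * 255.0  # 8-bit dynamic range

    def test_huge_radius_warns(self):
        with pytest.warns(UserWarning, match="radius"):
            subtract_background_paraboloid(np.ones((8, 8)), 100)


class TestStackHistogramThreshold:
    def test_exact_fraction_retained(self):
        stack = np.zeros(1000)
        stack[:30] = 255.0
        out = threshold_stack_histogram(stack, 0.03)
        assert (out > 0).sum() == 30
        assert np.all(out[:30] == 255.0)

    def test_fraction_one_keeps_everything(self):
        rng = np.random.default_rng(6)
        stack = rng.uniform(1, 10, (20, 20))
        assert np.array_equal(threshold_stack_histogram(stack, 1.0), stack)

    def test_constant_stack_fully_retained(self):
        stack = np.full((10, 10), 5.0)
        assert np.array_equal(threshold_stack_histogram(stack, 0.03), stack)

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            threshold_stack_histogram(np.ones(10), 0.0)
        with pytest.raises(ValueError):
            threshold_stack_histogram(np.ones(10), 1.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        f1=st.floats(0.01, 0.99),
        f2=st.floats(0.01, 0.99),
        seed=st.integers(0, 10),
    )
    def test_monotone_in_fraction(self, f1, f2, seed):
        """Increasing the retained fraction never removes a voxel."""
        lo, hi = sorted([f1, f2])
        stack = np.random.default_rng(seed).uniform(0, 100, 400)
        kept_lo = threshold_stack_histogram(stack, lo) > 0
        kept_hi = threshold_stack_histogram(stack, hi) > 0
        assert np.all(kept_hi | ~kept_lo)
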