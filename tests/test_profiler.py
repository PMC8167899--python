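"""Wide-line profiles, profile averaging, and nuclear mean-gray levels."""

import numpy as np
import pytest
from scipy import stats

from metquant.profiler import (
    IntensityProfile,
    LineROI,
    average_cell_profiles,
    condition_average,
    nuclear_mean_gray,
    sample_line_profile,
)
from metquant.synthio import EpitheliumSimParams, PeakSpec, simulate_epithelium

PX = 0.1


def _vertical_roi(x_um, length_um, width_px=11):
    return LineROI((0.0, x_um), (length_um, x_um), width_px=width_px)


class TestSampleLineProfile:
    def test_uniform_image_flat_profile(self):
        image = np.full((100, 100), 100.0)
        prof = sample_line_profile(image, _vertical_roi(5.0, 8.0), PX)
        assert np.allclose(prof.mean_gray, 100.0)
        assert prof.step_um == pytest.approx(PX)

    def test_linear_gradient_reproduced(self):
        image = np.tile(np.arange(100.0)[:, None], (1, 100))
        prof = sample_line_profile(image, _vertical_roi(5.0, 8.0), PX)
        assert prof.mean_gray[0] == pytest.approx(0.0, abs=0.5)
        assert prof.mean_gray[-1] == pytest.approx(80.0, abs=0.5)
        diffs = np.diff(prof.mean_gray)
        assert np.allclose(diffs, diffs[0], atol=1e-6)

    def test_apical_ridge_located(self):
        params = EpitheliumSimParams(
            peaks=(PeakSpec(2.0, 120.0, 1.0),),
            noise_sd=0.0, cell_length_jitter_um=0.0, background_level=0.0, seed=0,
        )
        image, gt = simulate_epithelium(params)
        row = gt.lines.iloc[0]
        roi = LineROI(
            (row.y_start_um, row.x_center_px * params.pixel_size_um),
            (row.y_end_um, row.x_center_px * params.pixel_size_um),
            width_px=60,
        )
        prof = sample_line_profile(image, roi, params.pixel_size_um)
        peak_at = prof.distances_um[np.argmax(prof.mean_gray)]
        assert abs(peak_at - 2.0) <= params.pixel_size_um

    def test_intensity_linearity(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 50, (80, 80))
        roi = _vertical_roi(3.0, 6.0)
        p1 = sample_line_profile(image, roi, PX)
        p3 = sample_line_profile(3.0 * image, roi, PX)
        assert np.allclose(p3.mean_gray, 3.0 * p1.mean_gray)

    def test_roi_outside_image_raises(self):
        image = np.zeros((50, 50))
        with pytest.raises(ValueError, match="outside"):
            sample_line_profile(image, _vertical_roi(4.9, 6.0, width_px=5), PX)

    def test_width_reduces_noise_variance(self):
        """Across repeated noisy renders of a laterally uniform cell, wider
        averaging bands give lower profile variance."""
        rng = np.random.default_rng(1)
        variances = []
        for width in (5, 21, 61):
            samples = []
            for _ in range(8):
                image = 50.0 + rng.normal(0, 10, (80, 120))
                prof = sample_line_profile(image, _vertical_roi(5.0, 6.0, width), PX)
                samples.append(prof.mean_gray)
            variances.append(np.var(np.stack(samples), axis=0).mean())
        assert variances[0] > variances[1] > variances[2]


class TestProfileAveraging:
    def _flat(self, value, length_um=15.0, step=PX):
        d = np.arange(0.0, length_um + step / 2, step)
        return IntensityProfile(d, np.full_like(d, float(value)))

    def test_identical_profiles_average_to_same(self):
        out = average_cell_profiles([self._flat(80.0)] * 10)
        assert np.allclose(out.mean_gray, 80.0)
        assert out.n == 10

    def test_two_flat_profiles_average(self):
        with pytest.warns(UserWarning, match="cell profiles"):
            out = average_cell_profiles([self._flat(50.0), self._flat(150.0)])
        assert np.allclose(out.mean_gray, 100.0)

    def test_relative_peak_position_preserved_across_lengths(self):
        profiles = []
        for L in (15.0, 15.9):
            d = np.arange(0.0, L + PX / 2, PX)
            v = 100.0 * np.exp(-((d - 0.4 * L) ** 2) / (2 * 0.5**2))
            profiles.append(IntensityProfile(d, v))
        with pytest.warns(UserWarning, match="cell profiles"):
            out = average_cell_profiles(profiles)
        peak_at = out.distances_um[np.argmax(out.mean_gray)]
        assert abs(peak_at - 0.4 * out.length_um) <= 2 * PX

    def test_length_outliers_dropped(self):
        profiles = [self._flat(100.0)] * 10 + [self._flat(100.0, length_um=18.0)]
        with pytest.warns(UserWarning, match="dropped"):
            out = average_cell_profiles(profiles)
        assert out.n == 10

    def test_too_few_admissible_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="admissible"):
                average_cell_profiles([self._flat(10.0)])

    def test_flat_profiles_conserved_by_resampling(self):
        out = average_cell_profiles(
            [self._flat(42.0, 15.0), self._flat(42.0, 15.4), self._flat(42.0, 14.8)],
            min_cells=3,
        )
        assert np.allclose(out.mean_gray, 42.0)

    def test_condition_average_identical(self):
        out = condition_average([self._flat(60.0)] * 6)
        assert np.allclose(out.mean_gray, 60.0)
        assert out.level == "condition" and out.n == 6

    def test_condition_average_of_peaks(self):
        d = np.arange(0.0, 15.0 + PX / 2, PX)
        mk = lambda a: IntensityProfile(d, a * np.exp(-((d - 2) ** 2) / 0.5))
        out = condition_average([mk(100.0), mk(140.0)])
        assert out.mean_gray.max() == pytest.approx(120.0, rel=1e-6)

    def test_condition_average_needs_two(self):
        with pytest.raises(ValueError):
            condition_average([self._flat(1.0)])


class TestNuclearMeanGray:
    def test_uniform_region(self):
        image = np.full((100, 100), 100.0)
        rois = [(10 + 2 * i, 50, 3, 4) for i in range(30)]
        assert nuclear_mean_gray(image, rois) == pytest.approx(100.0)

    def test_mixed_intensities_average(self):
        image = np.zeros((60, 120))
        image[:, :60] = 80.0
        image[:, 60:] = 120.0
        rois = [(30, 20, 4, 4)] * 15 + [(30, 100, 4, 4)] * 15
        assert nuclear_mean_gray(image, rois) == pytest.approx(100.0)

    def test_wrong_count_warns(self):
        image = np.ones((20, 20))
        with pytest.warns(UserWarning, match="ROIs"):
            nuclear_mean_gray(image, [(10, 10, 2, 2)])

    def test_programmed_intensity_drop_detected(self):
        """Two groups of embryos with a programmed nuclear intensity drop
        separate at p < 0.001 in an unpaired two-tailed t test."""
        rng = np.random.default_rng(4)

        def embryo_value(level):
            image = rng.normal(5, 1.0, (120, 120))
            centers = rng.uniform(10, 110, (30, 2))
            yy, xx = np.indices((120, 120))
            for cy, cx in centers:
                mask = ((yy - cy) / 3) ** 2 + ((xx - cx) / 3) ** 2 <= 1
                image[mask] = rng.normal(level, 1.0)
            rois = [(cy, cx, 3, 3) for cy, cx in centers]
            return nuclear_mean_gray(image, rois)

        pre = [embryo_value(100.0) for _ in range(6)]
        post = [embryo_value(40.0) for _ in range(6)]
        _, p = stats.ttest_ind(pre, post)
        assert p < 0.001
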