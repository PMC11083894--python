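import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant import (
    IntensitySeries,
    RoiRect,
    TrendModelSpec,
    VoxelGrid,
    build_series,
    compare_models_aic,
    fit_all_models,
    fit_trend,
    fold_variation,
    max_intensity_projection,
    roi_mean_intensity,
    simulate_intensity_series,
)
from oracles import mip_oracle, roi_mean_oracle

GEOM = (0.35, 0.325, 0.325)
ROI = RoiRect("r1", 0, 0, 31, 31)


def series_from_raw(raw, roi=ROI):
    return IntensitySeries(roi=roi, dye="TMRM", microscope="SDCM", raw=np.asarray(raw, float))


class TestMaxIntensityProjection:
    def test_single_slice_identity(self, rng):
        a = rng.random((1, 6, 7))
        np.testing.assert_array_equal(max_intensity_projection(VoxelGrid(a, *GEOM)), a[0])

    def test_uniformly_brightest_slice_wins(self):
        a = np.zeros((4, 5, 5))
        a[2] = 9.0
        np.testing.assert_array_equal(max_intensity_projection(VoxelGrid(a, *GEOM)), a[2])

    def test_matches_exhaustive_scan(self, rng):
        a = rng.random((5, 4, 4))
        np.testing.assert_array_equal(
            max_intensity_projection(VoxelGrid(a, *GEOM)), mip_oracle(a)
        )


class TestRoiMean:
    def test_uniform_image(self):
        img = np.full((40, 40), 5.0)
        assert roi_mean_intensity(img, ROI) == 5.0

    def test_2x2_example(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert roi_mean_intensity(img, RoiRect("r", 0, 0, 2, 2)) == 2.5

    def test_matches_sum_count_oracle(self, rng):
        img = rng.random((20, 25))
        roi = RoiRect("r", 3, 5, 7, 11)
        assert roi_mean_intensity(img, roi) == pytest.approx(
            roi_mean_oracle(img, 3, 5, 7, 11)
        )

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_intensity(np.zeros((10, 10)), ROI)


class TestSeries:
    def test_relative_normalization(self):
        s = series_from_raw([200, 180, 160])
        np.testing.assert_allclose(s.relative, [1.0, 0.9, 0.8])
        assert s.relative[0] == 1.0
        assert s.t[0] == 0.0 and s.t[-1] == 1.0
        assert np.all(np.diff(s.t) > 0)

    def test_constant_raw_gives_unit_relative(self):
        np.testing.assert_array_equal(series_from_raw([7, 7, 7, 7]).relative, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100), st.floats(min_value=5.0, max_value=50))
    def test_scale_invariance_offset_sensitivity(self, scale, offset):
        raw = np.array([200.0, 190.0, 170.0, 160.0])
        base = series_from_raw(raw).relative
        scaled = series_from_raw(raw * scale).relative
        np.testing.assert_allclose(scaled, base, rtol=1e-12)
        shifted = series_from_raw(raw + offset).relative
        assert not np.allclose(shifted, base)

    def test_build_series_from_stacks(self, rng):
        # 10 stacks with known per-acquisition decay of every voxel
        base = rng.random((3, 40, 40)) * 100 + 50
        factors = 0.97 ** np.arange(10)
        stacks = [VoxelGrid(base * f, *GEOM) for f in factors]
        series = build_series(stacks, [ROI], dye="TMRM", microscope="SDCM")
        assert len(series) == 1
        np.testing.assert_allclose(series[0].relative, factors, rtol=1e-12)

    def test_build_series_needs_two_stacks(self):
        with pytest.raises(ValueError):
            build_series([VoxelGrid(np.ones((2, 40, 40)), *GEOM)], [ROI], "TMRM", "SDCM")


class TestFitTrend:
    def test_noiseless_linear_slope_exact(self):
        t = np.arange(10) / 9
        s = [series_from_raw(200 * (1 - 0.14 * t))]
        fit = fit_trend(s, TrendModelSpec("linear", "constant"))
        assert fit.beta == pytest.approx(-0.14, abs=1e-9)
        assert fit.degenerate  # residual SD -> 0 flagged, not raised

    def test_constant_series_prefers_horizontal_line(self):
        s = [series_from_raw([200.0] * 10), series_from_raw([150.0] * 10)]
        fits = fit_all_models(s)
        best = compare_models_aic(fits)
        assert best.spec.location_form == "constant"
        assert abs(best.beta) < 1e-12

    def test_ml_slope_equals_ols_slope(self, rng):
        series = simulate_intensity_series(-0.16, 0.05, rng=rng)
        fit = fit_trend(series, TrendModelSpec("linear", "constant"))
        t = np.concatenate([s.t for s in series])
        y = np.concatenate([s.relative for s in series])
        keep = t > 0
        slope = np.polyfit(t[keep], y[keep], 1)[0]
        assert fit.beta == pytest.approx(slope, abs=1e-6)

    def test_slope_recovery_monte_carlo(self):
        rng = np.random.default_rng(7)
        est = [
            fit_trend(
                simulate_intensity_series(-0.16, 0.05, rng=rng),
                TrendModelSpec("linear", "constant"),
            ).beta
            for _ in range(150)
        ]
        assert np.mean(est) == pytest.approx(-0.16, abs=0.02)

    def test_aic_bookkeeping(self):
        rng = np.random.default_rng(8)
        series = simulate_intensity_series(-0.1, 0.05, rng=rng)
        for fit in fit_all_models(series):
            assert fit.aic == pytest.approx(fit.minus_log_likelihood + fit.n_params)
        # richer nested model never has worse -logL by more than numerical slack
        fits = {f.spec: f for f in fit_all_models(series)}
        simple = fits[TrendModelSpec("constant", "constant")]
        rich = fits[TrendModelSpec("linear", "loglinear")]
        assert rich.minus_log_likelihood <= simple.minus_log_likelihood + 1e-6

    def test_mixed_groups_rejected(self):
        a = series_from_raw([200, 190])
        b = IntensitySeries(roi=ROI, dye="JC-1", microscope="CLSM", raw=np.array([100.0, 90.0]))
        with pytest.raises(ValueError, match="group"):
            fit_trend([a, b])


class TestCompareModels:
    @staticmethod
    def _fit(nll, k):
        from mitoquant.photostability import TrendFitResult

        return TrendFitResult(
            spec=TrendModelSpec("linear", "constant"),
            alpha=1.0,
            beta=0.0,
            gamma=0.0,
            delta=0.0,
            minus_log_likelihood=nll,
            n_params=k,
            aic=nll + k,
            n_obs=45,
            converged=True,
            data_id=1,
        )

    def test_penalized_likelihood_arithmetic(self):
        best = compare_models_aic([self._fit(10.0, 2), self._fit(9.5, 3)])
        assert best.aic == 12.0  # 10 + 2 beats 9.5 + 3

    def test_tie_broken_to_fewer_parameters(self):
        best = compare_models_aic([self._fit(10.0, 3), self._fit(11.0, 2)])
        assert best.n_params == 2

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            compare_models_aic([self._fit(1.0, 2)])


class TestFoldVariation:
    def test_example(self):
        s1 = series_from_raw([100, 80])
        s2 = series_from_raw([100, 120])
        assert fold_variation([s1, s2], acquisition=1) == pytest.approx(1.5)

    def test_identical_series_fold_one(self):
        s = [series_from_raw([100, 90, 80]) for _ in range(3)]
        assert fold_variation(s, acquisition=2) == 1.0

    def test_fold_grows_with_roi_dispersion(self):
        folds = []
        for sd in (0.02, 0.08, 0.2):
            rng = np.random.default_rng(11)
            series = simulate_intensity_series(0.0, 0.01, roi_effect_sd=sd, rng=rng)
            folds.append(fold_variation(series, acquisition=9))
        assert folds[0] < folds[1] < folds[2]
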