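import dataclasses

import numpy as np
import pytest

from grassnpp import synthetic
from grassnpp.attribution import slope
from grassnpp.synthetic import SimParams, generate_climate, generate_ndvi


class TestGenerateClimate:
    def test_same_seed_identical_cubes(self, small_params):
        a = generate_climate(small_params)
        b = generate_climate(small_params)
        for field in ("temperature", "precip", "solar"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_different_seed_differs(self, small_params):
        a = generate_climate(small_params)
        b = generate_climate(dataclasses.replace(small_params, seed=8))
        assert not np.array_equal(a.precip, b.precip)

    def test_noiseless_precip_trend_recovered_exactly(self):
        p = SimParams(n_rows=8, n_cols=8, p_noise_sd=0.0, t_noise_sd=0.0)
        clim = generate_climate(p)
        grid_mean = clim.precip.sum(axis=1).mean(axis=(1, 2))
        assert slope(grid_mean) == pytest.approx(1.3, abs=1e-9)

    def test_noiseless_temperature_trend_recovered_exactly(self):
        p = SimParams(n_rows=8, n_cols=8, p_noise_sd=0.0, t_noise_sd=0.0)
        clim = generate_climate(p)
        grid_mean = clim.temperature.mean(axis=1).mean(axis=(1, 2))
        assert slope(grid_mean) == pytest.approx(0.01, abs=1e-9)

    def test_monthly_weights_concentrate_summer_rain(self, small_params):
        clim = generate_climate(small_params)
        jun_sep = clim.precip[:, 5:9].sum(axis=1)
        annual = clim.precip.sum(axis=1)
        frac = (jun_sep / annual).mean()
        assert frac == pytest.approx(0.70, abs=1e-9)

    def test_gradient_monotone_across_columns_when_noiseless(self):
        p = SimParams(n_rows=10, n_cols=10, p_noise_sd=0.0, t_noise_sd=0.0)
        clim = generate_climate(p)
        col_means = clim.precip.sum(axis=1).mean(axis=(0, 1))
        assert np.all(np.diff(col_means) >= 0)

    def test_trend_estimator_unbiased_over_replicates(self):
        slopes = []
        for seed in range(100):
            p = SimParams(n_rows=6, n_cols=6, seed=seed)
            clim = generate_climate(p)
            slopes.append(slope(clim.precip.sum(axis=1).mean(axis=(1, 2))))
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 1.3) < 3 * sem


class TestGenerateNdvi:
    def test_zero_response_zero_noise_spatially_constant(self):
        p = SimParams(n_rows=6, n_cols=6, ndvi_b=0.0, ndvi_c=0.0,
                      ndvi_noise_sd=0.0, p_noise_sd=0.0, t_noise_sd=0.0)
        ndvi = generate_ndvi(generate_climate(p), p)
        for y in range(p.n_years):
            for m in range(12):
                assert np.ptp(ndvi[y, m]) == 0.0

    def test_wetter_pixel_greener(self):
        p = SimParams(n_rows=4, n_cols=4, ndvi_noise_sd=0.0,
                      p_noise_sd=0.0, t_noise_sd=0.0, ndvi_c=0.0)
        ndvi = generate_ndvi(generate_climate(p), p)
        # precipitation increases along the diagonal; with only the P
        # response active NDVI must follow
        assert ndvi[0, 6, 0, 0] < ndvi[0, 6, -1, -1]

    def test_values_clipped_to_valid_range(self):
        p = SimParams(n_rows=5, n_cols=5, ndvi_b=5.0, ndvi_noise_sd=0.5, seed=3)
        ndvi = generate_ndvi(generate_climate(p), p)
        assert np.all(ndvi <= 1.0) and np.all(ndvi >= -1.0)

    def test_human_suppression_lowers_block_trend(self):
        p = synthetic.scenario_human_degradation(SimParams(n_rows=10, n_cols=10, seed=2))
        ndvi = generate_ndvi(generate_climate(p), p)
        july = ndvi[:, 6]
        trends = slope(july.reshape(p.n_years, -1)).reshape(10, 10)
        block = synthetic.human_block_mask(p)
        assert trends[block].mean() < trends[~block].mean()


class TestSurveyPoints:
    def test_zero_noise_measures_truth(self, rng):
        truth = rng.uniform(50, 300, (10, 10))
        spec = synthetic.SimParams(n_rows=10, n_cols=10).grid
        pts = synthetic.generate_survey_points(truth, 20, 0.0, 1, spec)
        np.testing.assert_allclose(
            pts["measured_npp"], truth[pts["row"], pts["col"]]
        )

    def test_survey_count_matches_request(self, rng):
        truth = rng.uniform(50, 300, (15, 15))
        spec = synthetic.SimParams(n_rows=15, n_cols=15).grid
        assert len(synthetic.generate_survey_points(truth, 102, 10.0, 1, spec)) == 102

    def test_more_points_than_pixels_rejected(self, rng):
        truth = rng.uniform(50, 300, (3, 3))
        spec = synthetic.SimParams(n_rows=3, n_cols=3).grid
        with pytest.raises(ValueError):
            synthetic.generate_survey_points(truth, 10, 0.0, 1, spec)

    def test_points_avoid_masked_pixels(self, rng):
        truth = rng.uniform(50, 300, (5, 5))
        truth[0] = np.nan
        spec = synthetic.SimParams(n_rows=5, n_cols=5).grid
        pts = synthetic.generate_survey_points(truth, 20, 0.0, 1, spec)
        assert (pts["row"] > 0).all()

    def test_noise_sd_for_target_r2_closed_form(self, rng):
        signal = rng.normal(200, 50, 500)
        sd = synthetic.noise_sd_for_r2(signal, 0.8)
        var = signal.var()
        assert var / (var + sd**2) == pytest.approx(0.8, rel=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(p_noise_sd=-1.0)
    with pytest.raises(ValueError):
        SimParams(month_weights=np.ones(12))
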