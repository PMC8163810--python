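import numpy as np
import pandas as pd
import pytest

from blowdown.allometry import (acd_change, agbd_to_acd, fit_allometry,
                                monte_carlo_acd, monte_carlo_acd_pair,
                                predict_agbd)
from blowdown.rasters import HeightRaster
from blowdown.synthetic import AllometrySimConfig, generate_plots


def _noise_free(a, b, tch):
    return pd.DataFrame({"plot_id": range(len(tch)), "tch_m": tch,
                         "agbd_mg_ha": a * np.asarray(tch) ** b})


class TestFitAllometry:
    @pytest.mark.parametrize("a,b", [(10.0, 1.0), (2.5, 1.6), (0.8, 2.1)])
    def test_noise_free_recovery_to_six_digits(self, a, b):
        tch = np.linspace(10, 35, 18)
        fit = fit_allometry(_noise_free(a, b, tch))
        assert fit.a == pytest.approx(a, rel=1e-7)
        assert fit.b == pytest.approx(b, rel=1e-7)
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_synthetic_generator_round_trip(self):
        cfg = AllometrySimConfig(a_true=2.5, b_true=1.6, residual_sd=0.0, seed=4)
        fit = fit_allometry(generate_plots(cfg))
        assert fit.a == pytest.approx(2.5, rel=1e-7)
        assert fit.b == pytest.approx(1.6, rel=1e-7)

    def test_fit_quality_at_realistic_scatter(self):
        """At residual scatter matching a ~9% RMSE plot network, the model
        explains about three quarters of AGBD variance (r2 near 0.74)."""
        r2s, rmses = [], []
        for seed in range(20):
            cfg = AllometrySimConfig(residual_sd=16.0, tch_range_m=(18, 25),
                                     seed=seed)
            fit = fit_allometry(generate_plots(cfg))
            r2s.append(fit.r2)
            rmses.append(fit.rmse_pct)
        assert 0.55 < np.median(r2s) < 0.9
        assert 6.0 < np.median(rmses) < 12.0

    def test_b_recovery_median_error_small(self):
        """Replicate plot networks at realistic scatter pin down the exponent
        and reproduce the true curve on noise-free evaluation heights."""
        tch = np.linspace(14, 30, 50)
        truth = 1.28 * tch**1.6
        errs, r2s = [], []
        for seed in range(20):
            fit = fit_allometry(generate_plots(AllometrySimConfig(seed=seed)))
            errs.append(abs(fit.b - 1.6))
            pred = fit.predict(tch)
            r2s.append(1 - np.sum((truth - pred) ** 2)
                       / np.sum((truth - truth.mean()) ** 2))
        assert np.median(errs) < 0.15
        assert np.median(r2s) > 0.99

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_allometry(_noise_free(2, 1.5, [20.0, 20.0, 20.0]))
        df = pd.DataFrame({"tch_m": [10, 20, 30], "agbd_mg_ha": [50.0, 50.0, 50.0]})
        with pytest.raises(ValueError):
            fit_allometry(df)


class TestPredictAndConvert:
    def test_linear_case_and_zero_boundary(self):
        fit = fit_allometry(_noise_free(10, 1.0, np.linspace(5, 30, 6)))
        r = HeightRaster(np.array([[20.0, 0.0, np.nan]]), 70.0)
        out = predict_agbd(fit, r)
        assert out.values[0, 0] == pytest.approx(200.0, rel=1e-6)
        assert out.values[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(out.values[0, 2])

    def test_matches_scalar_loop_oracle(self):
        fit = fit_allometry(_noise_free(2.5, 1.6, np.linspace(10, 30, 8)))
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 35, (4, 5))
        out = predict_agbd(fit, HeightRaster(v, 70.0))
        for i in range(4):
            for j in range(5):
                assert out.values[i, j] == pytest.approx(fit.a * v[i, j] ** fit.b)

    def test_carbon_fraction(self):
        assert agbd_to_acd(100.0) == pytest.approx(47.0)
        assert agbd_to_acd(0.0) == 0.0
        np.testing.assert_allclose(agbd_to_acd(np.array([10.0, 20.0])) / 0.47,
                                   [10.0, 20.0])
        # monotone + linear
        x = np.linspace(0, 300, 7)
        y = agbd_to_acd(x)
        assert (np.diff(y) >= 0).all()
        np.testing.assert_allclose(agbd_to_acd(2 * x), 2 * y)


class TestMonteCarlo:
    def _fit_with_sigma(self, sigma):
        rng = np.random.default_rng(1)
        tch = np.linspace(15, 30, 18)
        agbd = 1.28 * tch**1.6 + rng.normal(0, sigma, 18) if sigma else 1.28 * tch**1.6
        return fit_allometry(pd.DataFrame({"tch_m": tch, "agbd_mg_ha": agbd}))

    def test_zero_sigma_collapses_interval(self):
        fit = self._fit_with_sigma(0.0)
        r = HeightRaster(np.full((3, 3), 22.0), 70.0)
        m = monte_carlo_acd(fit, r, n_draws=200, seed=0)
        np.testing.assert_allclose(m.ci_low, m.values, atol=1e-9)
        np.testing.assert_allclose(m.ci_high, m.values, atol=1e-9)

    def test_interval_brackets_central_value(self):
        fit = self._fit_with_sigma(16.0)
        rng = np.random.default_rng(2)
        r = HeightRaster(rng.uniform(15, 30, (5, 5)), 70.0)
        m = monte_carlo_acd(fit, r, n_draws=500, seed=3)
        assert (m.ci_low <= m.values + 1e-9).all()
        assert (m.ci_high >= m.values - 1e-9).all()

    def test_landscape_ci_width_scales_with_cells(self):
        """Residual-only landscape-mean interval shrinks ~ 1/sqrt(n_cells)."""
        fit = self._fit_with_sigma(16.0)
        widths = []
        for n in (5, 20):
            r = HeightRaster(np.full((n, n), 22.0), 70.0)
            m = monte_carlo_acd(fit, r, n_draws=2000, seed=4)
            widths.append(m.landscape_ci[1] - m.landscape_ci[0])
        ratio = widths[0] / widths[1]
        assert 3.0 < ratio < 5.5  # expect ~4 for a 16x cell-count increase

    def test_deterministic_under_seed(self):
        fit = self._fit_with_sigma(16.0)
        r = HeightRaster(np.full((4, 4), 22.0), 70.0)
        a = monte_carlo_acd(fit, r, n_draws=100, seed=7)
        b = monte_carlo_acd(fit, r, n_draws=100, seed=7)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        assert a.landscape_ci == b.landscape_ci

    def test_rejects_too_few_draws(self):
        fit = self._fit_with_sigma(16.0)
        r = HeightRaster(np.full((2, 2), 22.0), 70.0)
        with pytest.raises(ValueError):
            monte_carlo_acd(fit, r, n_draws=1)


class TestAcdChange:
    def _pair(self, pre_val=100 / 0.47, post_val=82.4 / 0.47):
        fit = fit_allometry(_noise_free(1.0, 1.0, np.linspace(50, 300, 6)))
        pre = HeightRaster(np.full((4, 4), pre_val), 70.0)
        post = HeightRaster(np.full((4, 4), post_val), 70.0)
        return monte_carlo_acd_pair(fit, pre, post, n_draws=400, seed=0)

    def test_headline_percentage_arithmetic(self):
        pre, post = self._pair()
        ch = acd_change(pre, post)
        assert ch.landscape_pct == pytest.approx(-17.6, abs=1e-6)
        assert ch.landscape_delta == pytest.approx(-17.6, abs=1e-6)

    def test_identical_maps_zero_change(self):
        pre, post = self._pair(200.0, 200.0)
        ch = acd_change(pre, post)
        assert ch.landscape_delta == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(ch.delta, 0.0, atol=1e-9)

    def test_misaligned_maps_rejected(self):
        pre, _ = self._pair()
        fit = fit_allometry(_noise_free(1.0, 1.0, np.linspace(50, 300, 6)))
        other = monte_carlo_acd(fit, HeightRaster(np.full((3, 3), 100.0), 70.0),
                                n_draws=400, seed=0)
        with pytest.raises(ValueError):
            acd_change(pre, other)


def test_landscape_ci_covers_truth_with_parameter_uncertainty():
    """95% landscape-mean interval covers the generating-curve mean in
    >=17/20 replicate plot networks when fit uncertainty is propagated."""
    rng = np.random.default_rng(10)
    tch_cells = HeightRaster(rng.uniform(14, 30, (10, 10)), 70.0)
    truth = float(np.mean(0.47 * 1.28 * tch_cells.values**1.6))
    hits = 0
    for seed in range(20):
        plots = generate_plots(AllometrySimConfig(seed=seed))
        fit = fit_allometry(plots)
        m = monte_carlo_acd(fit, tch_cells, n_draws=500, seed=seed,
                            include_parameter_uncertainty=True)
        lo, hi = m.landscape_ci
        hits += lo <= truth <= hi
    assert hits >= 17
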