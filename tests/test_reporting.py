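"""Kernel machinery oracles and reporting-error pattern recovery."""

import numpy as np
import pytest
from scipy import integrate

from shapeincome.reporting import (
    ErrorSeries,
    KernelRegression,
    compute_reporting_errors,
    default_grid,
    epanechnikov,
    error_mean_regression,
    error_quantile_regression,
    kernel_conditional_mean,
    silverman_bandwidth,
    zero_crossing,
)


class TestErrorConstruction:
    def test_error_is_reported_minus_measured(self):
        s = compute_reporting_errors(np.array([180.0]), np.array([178.0]))
        assert s.error[0] == pytest.approx(2.0)

    def test_perfect_reporting_gives_zeros(self, rng):
        x = rng.normal(170, 7, size=50)
        s = compute_reporting_errors(x, x)
        np.testing.assert_array_equal(s.error, np.zeros(50))

    def test_generator_error_function_recovered_exactly(self):
        # zero reporting noise: errors equal the configured error functions
        from shapeincome.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(n_subjects=60, seed=2, male_fraction=0.0)
        cfg.noise_scales["reporting_height_cm"] = 0.0
        cfg.noise_scales["reporting_weight_kg"] = 0.0
        c = generate_cohort(cfg, include_meshes=False)
        t = c.table
        s = compute_reporting_errors(t["reported_weight"].to_numpy(),
                                     t["measured_weight"].to_numpy())
        expected = -cfg.weight_error_slope * (
            t["measured_weight"].to_numpy() - cfg.weight_signswitch_kg["female"])
        np.testing.assert_allclose(s.error, expected, atol=1e-12)


class TestKernelPrimitives:
    def test_epanechnikov_closed_form_values(self):
        assert epanechnikov(0.0) == pytest.approx(0.75)
        assert epanechnikov(1.0) == 0.0
        assert epanechnikov(-1.0) == 0.0
        assert epanechnikov(2.0) == 0.0
        assert epanechnikov(0.5) == pytest.approx(0.75 * 0.75)

    def test_epanechnikov_integrates_to_one(self):
        val, _ = integrate.quad(epanechnikov, -1, 1)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_silverman_formula_hand_computed(self):
        # 5 points with sd and IQR computed by hand
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        sd = np.std(x, ddof=1)                 # sqrt(2.5)
        iqr = 2.0                              # q75 - q25 = 3 - 1
        expected = 2.34 * min(sd, iqr / 1.349) * 5 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_silverman_scale_equivariant(self, rng):
        x = rng.normal(size=200)
        assert silverman_bandwidth(7.0 * x) == pytest.approx(
            7.0 * silverman_bandwidth(x), rel=1e-12)

    def test_silverman_sample_size_rate(self, rng):
        x = rng.normal(size=100)
        x16 = np.tile(x, 16)   # same spread (up to ddof), 16x the sample size
        assert (silverman_bandwidth(x) / silverman_bandwidth(x16)
                == pytest.approx(16 ** 0.2, rel=5e-3))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            silverman_bandwidth(np.ones(10))


class TestNadarayaWatson:
    def test_constant_response_reproduced_everywhere(self, rng):
        x = rng.uniform(0, 10, 100)
        s = ErrorSeries(x, np.full(100, 3.7))
        c = kernel_conditional_mean(s, np.linspace(1, 9, 11), 1.0)
        np.testing.assert_allclose(c.estimate, 3.7, atol=1e-12)

    def test_symmetric_three_points(self):
        s = ErrorSeries(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        c = kernel_conditional_mean(s, np.array([1.0]), 1.5)
        assert c.estimate[0] == pytest.approx(1.0, abs=1e-12)

    def test_estimate_is_convex_combination(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        c = KernelRegression(ErrorSeries(x, y)).fit()
        ok = np.isfinite(c.estimate)
        assert c.estimate[ok].min() >= y.min() - 1e-12
        assert c.estimate[ok].max() <= y.max() + 1e-12

    def test_matches_brute_force_sum(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        grid = np.linspace(-1.5, 1.5, 5)
        h = 0.9
        c = kernel_conditional_mean(ErrorSeries(x, y), grid, h)
        for gi, est in zip(grid, c.estimate):
            num = den = 0.0
            for xi, yi in zip(x, y):
                u = (xi - gi) / h
                w = 0.75 * (1 - u * u) if abs(u) <= 1 else 0.0
                num += w * yi
                den += w
            assert est == pytest.approx(num / den, abs=1e-12)

    def test_shift_equivariance_in_response(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        grid = np.linspace(-1, 1, 9)
        a = kernel_conditional_mean(ErrorSeries(x, y), grid, 0.8).estimate
        b = kernel_conditional_mean(ErrorSeries(x, y + 5.0), grid, 0.8).estimate
        np.testing.assert_allclose(b, a + 5.0, atol=1e-10)

    def test_grid_must_increase(self):
        from shapeincome.reporting import KernelCurve

        with pytest.raises(ValueError, match="increasing"):
            KernelCurve(grid=np.array([1.0, 1.0]), estimate=np.zeros(2),
                        bandwidth=1.0)


class TestBootstrapBands:
    def test_same_seed_identical_bands(self, rng):
        x = rng.uniform(0, 10, 150)
        y = 0.5 * x + rng.normal(size=150)
        kr = KernelRegression(ErrorSeries(x, y))
        a = kr.fit_with_bands(B=150, seed=4)
        b = kr.fit_with_bands(B=150, seed=4)
        np.testing.assert_array_equal(a.band_lower, b.band_lower)
        np.testing.assert_array_equal(a.band_upper, b.band_upper)

    def test_band_width_shrinks_with_sample_size(self, rng):
        def width(n):
            x = rng.uniform(0, 10, n)
            y = 1.0 + 0.3 * x            # noise-free linear response
            kr = KernelRegression(ErrorSeries(x, y))
            c = kr.fit_with_bands(grid=np.linspace(3, 7, 9), B=200, seed=0)
            return np.nanmean(c.band_upper - c.band_lower)

        assert width(4000) < width(250)

    def test_pointwise_coverage_near_nominal(self, rng):
        # known conditional mean m(x)=2x; coverage at interior points
        n, B, reps = 400, 200, 40
        grid = np.linspace(-1, 1, 7)
        hits = np.zeros(len(grid))
        counts = np.zeros(len(grid))
        for r in range(reps):
            x = rng.uniform(-1.5, 1.5, n)
            y = 2.0 * x + rng.normal(size=n)
            c = KernelRegression(ErrorSeries(x, y)).fit_with_bands(
                grid=grid, B=B, level=0.95, seed=r)
            ok = np.isfinite(c.band_lower)
            truth = 2.0 * grid
            hits[ok] += ((c.band_lower <= truth) & (truth <= c.band_upper))[ok]
            counts[ok] += 1
        coverage = hits.sum() / counts.sum()
        # smoothing-bias-afflicted nominal 95%: accept a generous window
        assert 0.80 <= coverage <= 1.0


class TestErrorRegressions:
    def test_exact_linear_error_recovered(self):
        truth = np.linspace(50, 100, 60)
        err = 2.0 - 0.05 * truth
        res = error_mean_regression(ErrorSeries(truth, err))
        assert res.params["const"] == pytest.approx(2.0, abs=1e-8)
        assert res.params["truth"] == pytest.approx(-0.05, abs=1e-10)

    def test_synthetic_weight_error_negative_and_significant(self):
        from shapeincome.synthetic import CohortConfig, generate_cohort

        c = generate_cohort(CohortConfig(n_subjects=2000, seed=17),
                            include_meshes=False)
        t = c.table[c.table["gender"] == "male"]
        s = compute_reporting_errors(t["reported_weight"].to_numpy(),
                                     t["measured_weight"].to_numpy())
        res = error_mean_regression(s)
        assert res.params["truth"] < 0
        assert abs(res.tvalues["truth"]) > 2

    def test_independent_error_slope_statistically_zero(self, rng):
        truth = rng.normal(80, 10, 1500)
        err = rng.normal(size=1500)
        res = error_mean_regression(ErrorSeries(truth, err))
        assert abs(res.params["truth"]) < 3 * res.bse["truth"]

    def test_collinear_covariate_rejected(self, rng):
        import pandas as pd

        truth = rng.normal(size=50)
        cov = pd.DataFrame({"copy": truth})
        with pytest.raises(ValueError, match="collinear"):
            error_mean_regression(ErrorSeries(truth, truth * 0.1), cov)


class TestQuantileRegression:
    def test_median_fit_matches_brute_force_grid(self):
        truth = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        err = np.array([0.5, 0.9, 2.4, 2.8, 4.6])
        res, _ = error_quantile_regression(ErrorSeries(truth, err), 0.5, n_boot=100)

        def check_loss(a, b):
            r = err - a - b * truth
            return np.sum(np.where(r >= 0, 0.5 * r, -0.5 * r))

        best = min(
            ((a, b) for a in np.linspace(-1, 2, 61)
             for b in np.linspace(0, 2, 81)),
            key=lambda p: check_loss(*p))
        assert check_loss(res.params["const"], res.params["truth"]) <= (
            check_loss(*best) + 1e-6)

    def test_location_shift_moves_intercept_only(self, rng):
        truth = rng.normal(size=300)
        err = 0.5 * truth + rng.normal(size=300)
        for tau in (0.25, 0.5, 0.75):
            r1, _ = error_quantile_regression(ErrorSeries(truth, err), tau, n_boot=100)
            r2, _ = error_quantile_regression(ErrorSeries(truth, err + 3.0), tau,
                                              n_boot=100)
            assert r2.params["const"] - r1.params["const"] == pytest.approx(3.0, abs=1e-4)
            assert r2.params["truth"] == pytest.approx(r1.params["truth"], abs=1e-6)

    def test_symmetric_noise_median_slope_zero(self, rng):
        truth = rng.normal(170, 7, 1000)
        err = 1.0 + rng.standard_t(5, size=1000)
        res, se = error_quantile_regression(ErrorSeries(truth, err), 0.5, n_boot=100)
        assert abs(res.params["truth"]) < 3 * se["truth"]

    def test_invalid_tau_rejected(self, rng):
        s = ErrorSeries(rng.normal(size=20), rng.normal(size=20))
        with pytest.raises(ValueError):
            error_quantile_regression(s, 1.5)


class TestZeroCrossing:
    def test_linear_curve_crosses_at_pivot(self):
        from shapeincome.reporting import KernelCurve

        grid = np.linspace(50, 100, 51)
        c = KernelCurve(grid=grid, estimate=grid - 75.0, bandwidth=1.0)
        assert zero_crossing(c) == [pytest.approx(75.0)]

    def test_all_positive_curve_has_no_crossing(self):
        from shapeincome.reporting import KernelCurve

        grid = np.linspace(0, 1, 11)
        c = KernelCurve(grid=grid, estimate=np.ones(11), bandwidth=1.0)
        assert zero_crossing(c) == []

    def test_multiple_crossings_all_returned(self):
        from shapeincome.reporting import KernelCurve

        grid = np.linspace(0.1, 3 * np.pi - 0.1, 300)
        c = KernelCurve(grid=grid, estimate=np.sin(grid), bandwidth=1.0)
        got = zero_crossing(c)
        assert len(got) == 2          # interior crossings of sin at pi and 2*pi
        assert got[0] == pytest.approx(np.pi, abs=1e-3)
        assert got[1] == pytest.approx(2 * np.pi, abs=1e-3)

    def test_default_grid_spans_inner_quantiles(self, rng):
        x = rng.normal(size=5000)
        g = default_grid(x, 101)
        assert len(g) == 101
        assert g[0] == pytest.approx(np.quantile(x, 0.01))
        assert g[-1] == pytest.approx(np.quantile(x, 0.99))
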