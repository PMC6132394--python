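import numpy as np
import pytest
from scipy import stats

from conftest import make_series
from d9assess.errors import InsufficientDataError
from d9assess.synthetic import SeriesGenSpec, lognormal_noise, simulate_series
from d9assess.trend import (
    contrast_test,
    linear_trend,
    loess_fit,
    loess_fit_arrays,
    trend_anova,
    trend_anova_arrays,
)


class TestLoessFit:
    def test_reproduces_straight_line_exactly(self, line_series):
        fit = loess_fit(line_series)
        assert np.allclose(fit.fitted, line_series.values, atol=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_constant_series_fitted_constant_sigma2_zero(self):
        s = make_series(list(range(2000, 2010)), [3.0] * 10)
        fit = loess_fit(s)
        assert np.allclose(fit.fitted, 3.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_full_span_uniform_equals_ols(self):
        rng = np.random.default_rng(7)
        years = np.arange(2000.0, 2010.0)
        values = 4.0 - 0.3 * (years - 2000) + rng.normal(0, 0.5, 10)
        fit = loess_fit_arrays(years, values, window_years=1000.0, kernel="uniform")
        slope, intercept = np.polyfit(years, values, 1)
        assert np.allclose(fit.fitted, slope * years + intercept, rtol=1e-8)

    def test_hat_rows_sum_to_one_and_shift_equivariance(self, noisy_decline_series):
        fit = loess_fit(noisy_decline_series)
        assert np.allclose(fit.hat_rows.sum(axis=1), 1.0)
        shifted = loess_fit_arrays(
            np.asarray(noisy_decline_series.years, float),
            np.asarray(noisy_decline_series.values) + 5.0,
        )
        assert np.allclose(shifted.fitted, fit.fitted + 5.0)

    def test_too_few_points_rejected(self):
        s = make_series([2000, 2001, 2002, 2003], [1, 2, 3, 4])
        with pytest.raises(InsufficientDataError):
            loess_fit(s)

    def test_sparse_window_widens_to_three_points(self):
        # biennial sampling leaves <3 points per 7-year window at the edges
        s = make_series(list(range(2003, 2016, 2)), [5, 4.5, 4, 3.8, 3.2, 3, 2.7])
        fit = loess_fit(s)
        assert np.all(np.isfinite(fit.fitted))
        assert np.allclose(fit.hat_rows.sum(axis=1), 1.0)


class TestTrendAnova:
    def test_linear_decline_detected(self):
        rng = np.random.default_rng(3)
        years = list(range(2000, 2015))
        values = 10 - 0.4 * np.arange(15) + rng.normal(0, 0.15, 15)
        res = trend_anova(make_series(years, list(values)))
        assert res.p_linear < 1e-4
        assert res.p_nonlinear > 0.05
        assert res.overall_trend == "decreasing"

    def test_hump_detected_as_nonlinear_not_linear(self):
        spec = SeriesGenSpec(
            year_start=2000, year_end=2014, c0=1.0, nonlinear_amplitude=1.0,
            noise_cv=0.02, seed=5,
        )
        recs, _ = simulate_series(spec)
        s = make_series([r.year for r in recs], [r.value for r in recs])
        res = trend_anova(s)
        assert res.p_nonlinear < 0.05
        assert res.p_linear > 0.05

    def test_needs_seven_points(self):
        s = make_series(list(range(2000, 2006)), [1, 2, 3, 4, 5, 6])
        with pytest.raises(InsufficientDataError):
            trend_anova(s)

    def test_null_type_one_error_near_nominal(self):
        """Fraction of p_linear <= 0.05 on no-trend series stays near 5%
        (500 replicates here; the full 2000-replicate study runs in the
        acceptance suite)."""
        rng = np.random.default_rng(17)
        years = np.arange(2000.0, 2015.0)
        hits = 0
        reps = 500
        noise = lognormal_noise(rng, 0.2, (reps, 15))
        for i in range(reps):
            if trend_anova_arrays(years, noise[i]).p_linear <= 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08

    def test_slope_ci_covers_generator_slope(self):
        """OLS slope CI covers the generator's mean secant slope in >= 90%
        of mildly nonlinear, low-noise replicates."""
        rng = np.random.default_rng(29)
        n, reps = 15, 200
        spec = SeriesGenSpec(year_start=2000, year_end=2014, c0=5.0,
                             decline_rate=0.02, noise_cv=0.05)
        years = spec.years().astype(float)
        mean = spec.mean_curve()
        true_slope = (mean[-1] - mean[0]) / (years[-1] - years[0])
        covered = 0
        tcrit = stats.t.ppf(0.975, n - 2)
        for _ in range(reps):
            values = mean * lognormal_noise(rng, 0.05, n)
            res = stats.linregress(years, values)
            if abs(res.slope - true_slope) <= tcrit * res.stderr:
                covered += 1
        assert covered / reps >= 0.90


class TestContrastTest:
    def test_identity_contrast_zero_difference(self, noisy_decline_series):
        fit = loess_fit(noisy_decline_series)
        c = contrast_test(fit, 2005, 2005, min_span_years=0)
        assert c.difference == pytest.approx(0.0)
        assert c.p == pytest.approx(1.0)

    def test_short_span_refused(self, noisy_decline_series):
        fit = loess_fit(noisy_decline_series)
        with pytest.raises(ValueError, match="below the minimum"):
            contrast_test(fit, 2010, 2016)

    def test_strong_decline_detected_over_twenty_years(self, noisy_decline_series):
        fit = loess_fit(noisy_decline_series)
        c = contrast_test(fit, 1998, 2017)
        assert c.difference < 0
        assert c.p < 0.05

    def test_two_sided_symmetry(self, noisy_decline_series):
        fit = loess_fit(noisy_decline_series)
        a = contrast_test(fit, 1998, 2017)
        b = contrast_test(fit, 2017, 1998)
        assert a.p == pytest.approx(b.p)
        assert a.difference == pytest.approx(-b.difference)


class TestLinearTrend:
    def test_two_point_line_through_zero(self):
        s = make_series([2000, 2005, 2010], [10.0, 5.0, 0.0])
        res = linear_trend(s)
        assert res.slope == pytest.approx(-1.0)
        assert res.calc_last == pytest.approx(0.0, abs=1e-9)
        assert res.percent_change == pytest.approx(-100.0)
        assert res.last_year_status == "value"

    def test_negative_endpoint_reported_not_detected(self):
        s = make_series([2000, 2002, 2004, 2006, 2010], [10.0, 6.0, 2.0, 0.5, 0.1])
        res = linear_trend(s)
        assert res.calc_last < 0
        assert res.last_year_status == "not_detected"
        assert res.percent_change is None

    def test_calc_vs_measured_factor(self):
        # line ends near 1.0 while the measured final value is 3.6
        years = [2000, 2001, 2002, 2003, 2004]
        values = [1.0, 1.0, 1.0, 1.0, 3.6]
        res = linear_trend(make_series(years, values))
        assert res.calc_vs_measured_factor == pytest.approx(
            3.6 / res.calc_last
        )
        assert res.calc_vs_measured_factor > 1

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            linear_trend(make_series([2000, 2001], [1.0, 2.0]))
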