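"""Detrending, serial-dependence tests, AR prewhitening, lagged correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inflowcast import (AnnualSeries, cross_correlation, detrend_linear,
                        durbin_watson, lagged_pair, ljung_box, prewhiten,
                        star_code, xcorr_matrix)
from inflowcast.prewhiten import ar_fit_cls

YEARS100 = np.arange(1900, 2000)


def ar1(phi, n, rng, sd=1.0):
    x = np.zeros(n)
    e = rng.normal(0.0, sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestDetrend:
    def test_exact_line_leaves_zero(self):
        s = AnnualSeries(np.arange(2000, 2004), [1.0, 2.0, 3.0, 4.0])
        trend, det = detrend_linear(s)
        np.testing.assert_allclose(det.values, 0.0, atol=1e-12)
        assert trend.slope == pytest.approx(1.0)

    def test_constant_series(self):
        _, det = detrend_linear(AnnualSeries(np.arange(2000, 2010), np.full(10, 3.3)))
        np.testing.assert_allclose(det.values, 0.0, atol=1e-12)

    def test_known_noise_recovered(self):
        rng = np.random.default_rng(0)
        eps = rng.standard_normal(50)
        years = np.arange(1960, 2010)
        y = 2.0 * (years - years[0]) + eps
        _, det = detrend_linear(AnnualSeries(years, y))
        # detrended series equals eps minus its own fitted line
        t = years.astype(float)
        slope, intercept = np.polyfit(t, eps, 1)
        np.testing.assert_allclose(det.values, eps - (intercept + slope * t),
                                   atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_linear(AnnualSeries([2000, 2001], [1.0, 2.0]))


class TestSerialDependenceTests:
    def test_alternating_series_strongly_autocorrelated(self):
        x = np.tile([1.0, -1.0], 30)
        _, p = ljung_box(x)
        assert p < 0.01

    def test_ljung_box_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ljung_box(np.ones(50))

    def test_durbin_watson_alternating_closed_form(self):
        n = 40
        x = np.tile([1.0, -1.0], n // 2)
        assert durbin_watson(x) == pytest.approx(4.0 * (n - 1) / n)

    def test_durbin_watson_white_noise_near_two(self):
        x = np.random.default_rng(12).standard_normal(500)
        assert 1.8 <= durbin_watson(x) <= 2.2

    def test_durbin_watson_positive_autocorrelation_low(self):
        x = ar1(0.9, 300, np.random.default_rng(5))
        assert durbin_watson(x) < 1.0

    def test_durbin_watson_degenerate_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.full(10, 2.0))


class TestPrewhiten:
    def test_trend_plus_white_noise_gives_order_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 0.5 * np.arange(100) + rng.standard_normal(100)
            res = prewhiten(AnnualSeries(YEARS100, y))
            hits += res.order == 0
        assert hits >= 18

    def test_ar1_input_gives_positive_order(self):
        hits = 0
        for seed in range(20):
            y = ar1(0.7, 100, np.random.default_rng(seed))
            res = prewhiten(AnnualSeries(YEARS100, y))
            hits += res.order >= 1
        assert hits >= 18

    def test_residual_length_matches_order(self):
        y = ar1(0.6, 60, np.random.default_rng(3))
        res = prewhiten(AnnualSeries(np.arange(1950, 2010), y))
        assert res.residuals.size == 60 - res.order
        assert res.years.size == res.residuals.size

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            prewhiten(AnnualSeries(np.arange(2000, 2008), np.arange(8.0)))

    def test_idempotent_on_own_residuals(self):
        hits = 0
        for seed in range(20):
            y = ar1(0.6, 100, np.random.default_rng(seed))
            first = prewhiten(AnnualSeries(YEARS100, y))
            second = prewhiten(AnnualSeries(first.years, first.residuals))
            hits += second.order == 0
        assert hits >= 18

    def test_cls_fit_matches_lstsq_oracle(self):
        y = ar1(0.5, 80, np.random.default_rng(9))
        coefs, resid = ar_fit_cls(y, 2)
        X = np.column_stack([np.ones(78), y[1:-1], y[:-2]])
        beta = np.linalg.solve(X.T @ X, X.T @ y[2:])
        np.testing.assert_allclose(coefs, beta, atol=1e-8)
        np.testing.assert_allclose(resid, y[2:] - X @ beta, atol=1e-8)


class TestLaggedPair:
    def _series(self, month, years, values=None):
        values = np.arange(len(years), dtype=float) if values is None else values
        return AnnualSeries(np.asarray(years), values, month=month)

    def test_same_year_when_no_wrap(self):
        sal = self._series(1, np.arange(2000, 2015))
        oxy = self._series(2, np.arange(2000, 2015), np.arange(15.0) * 2)
        years, xs, ys = lagged_pair(sal, oxy, 1)
        assert years.tolist() == list(range(2000, 2015))
        np.testing.assert_allclose(ys, xs * 2)

    def test_wrap_pairs_with_next_year(self):
        sal = self._series(12, np.arange(2000, 2015))
        oxy = self._series(2, np.arange(2000, 2016), np.arange(16.0))
        years, xs, ys = lagged_pair(sal, oxy, 2)
        # December of year y pairs with February of year y+1
        assert years.min() == 2000 and years.max() == 2014
        np.testing.assert_allclose(ys, xs + 1)

    def test_disjoint_year_ranges_rejected(self):
        sal = self._series(1, np.arange(2000, 2015))
        oxy = self._series(1, np.arange(2030, 2045))
        with pytest.raises(ValueError, match="overlapping"):
            lagged_pair(sal, oxy, 0)

    def test_wrong_month_arithmetic_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            lagged_pair(self._series(1, np.arange(2000, 2015)),
                        self._series(3, np.arange(2000, 2015)), 1)


class TestCrossCorrelation:
    def test_identical_series(self):
        x = np.random.default_rng(0).standard_normal(20)
        assert cross_correlation(x, x).r == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.random.default_rng(0).standard_normal(20)
        assert cross_correlation(x, -x).r == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 30))
        assert cross_correlation(x, y).r == pytest.approx(cross_correlation(y, x).r)

    def test_r_055_n44_highly_significant(self):
        # construct a pair with exactly r = 0.55 at n = 44
        rng = np.random.default_rng(8)
        x = rng.standard_normal(44)
        z = rng.standard_normal(44)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= z.std()
        r = 0.55
        y = r * x + np.sqrt(1 - r**2) * z
        cell = cross_correlation(x, y)
        assert cell.r == pytest.approx(0.55, abs=1e-12)
        assert cell.p < 0.001
        assert cell.stars == "***"

    def test_zero_variance_masked(self):
        cell = cross_correlation(np.ones(15), np.arange(15.0))
        assert np.isnan(cell.r)


class TestStarCode:
    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.05, ""), (0.049, "*"), (0.01, "*"),
        (0.0099, "**"), (0.001, "**"), (0.0009, "***"), (0.0, "***")])
    def test_breakpoints(self, p, stars):
        assert star_code(p) == stars

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_pure_step_function(self, p):
        expected = ("***" if p < 0.001 else "**" if p < 0.01
                    else "*" if p < 0.05 else "")
        assert star_code(p) == expected


class TestXCorrMatrix:
    def test_single_depth_input(self, make_profile_series, monthly_times):
        rng = np.random.default_rng(0)
        times = monthly_times(1980, 20)
        up = make_profile_series(times, [33.0],
                                 salinity=rng.normal(12, 1, (times.size, 1)))
        down = make_profile_series(times, [60.0],
                                   oxygen=rng.normal(5, 1, (times.size, 1)))
        grid = xcorr_matrix(up, down, salinity_depth=33.0, min_oxygen_depth=50.0)
        df = grid.to_frame()
        assert set(df["depth_m"]) == {60.0}
        assert len(df) == 5 * 3  # five salinity months x three lags

    def test_cells_independent_of_depth_subset(self, default_run):
        """Removing other depths leaves each cell's value unchanged."""
        upm, dnm = default_run
        full = xcorr_matrix(upm, dnm).to_frame()
        from inflowcast import ProfileSeries
        keep = [float(d) for d in dnm.depths if d > 70]
        sub_ps = ProfileSeries(dnm.data.sel(depth=keep), region=dnm.region)
        sub = xcorr_matrix(upm, sub_ps).to_frame()
        merged = sub.merge(full, on=["sal_month", "oxy_month", "lag", "depth_m"],
                           suffixes=("_sub", "_full"))
        assert len(merged) == len(sub)
        np.testing.assert_allclose(merged["r_sub"], merged["r_full"], atol=1e-12)
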