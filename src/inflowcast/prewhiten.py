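"""Detrending, AR prewhitening and lagged cross-correlation.

Interannual series (one value per year for a fixed month and depth) are
linearly detrended, checked for serial dependence with the Ljung-Box and
Durbin-Watson tests, and reduced to the residuals of an autoregressive fit
of increasing order until both tests pass.  Pearson correlations between
the prewhitened upstream-salinity and downstream-oxygen series are then
collected over salinity months Nov-Mar, lags 0-2 months, and all
downstream depths below a cutoff, with two-sided t-test p-values and the
conventional significance star coding.

Pairs whose lag crosses the calendar year boundary are aligned on the
winter season: salinity in Nov/Dec of year y pairs with oxygen early in
year y+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .profiles import MonthlySeries, ProfileSeries, depth_level_series, _ensure_monthly

#: months of upstream salinity scanned by the correlation grid
SALINITY_MONTHS = (11, 12, 1, 2, 3)
LAGS = (0, 1, 2)


@dataclass
class AnnualSeries:
    """Year-indexed values of one (month, depth/layer, variable, region)."""

    years: np.ndarray
    values: np.ndarray
    month: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must align")
        if self.years.size > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.years.size)

    def dropna(self) -> "AnnualSeries":
        ok = np.isfinite(self.values)
        return AnnualSeries(self.years[ok], self.values[ok], self.month, self.label)


def annual_series(ms: MonthlySeries, month: int, label: str = "") -> AnnualSeries:
    """Extract the fixed-month interannual series from a MonthlySeries."""
    sel = ms.data.xs(month, level="month").sort_index()
    return AnnualSeries(sel.index.to_numpy(), sel.to_numpy(), month=month,
                        label=label or str(ms.provenance))


@dataclass
class TrendFit:
    intercept: float
    slope: float  # per year


def detrend_linear(series: AnnualSeries) -> tuple[TrendFit, AnnualSeries]:
    """Remove the OLS line on calendar year; detrended mean is ~0."""
    s = series.dropna()
    if s.n < 3:
        raise ValueError("detrending needs at least 3 years")
    t = s.years.astype(float)
    slope, intercept = np.polyfit(t, s.values, 1)
    resid = s.values - (intercept + slope * t)
    return TrendFit(float(intercept), float(slope)), AnnualSeries(
        s.years, resid, s.month, s.label)


def ljung_box(x: np.ndarray, n_lags: int | None = None, model_df: int = 0
              ) -> tuple[float, float]:
    """Ljung-Box portmanteau Q and its chi-square p-value.

    ``model_df`` degrees of freedom are subtracted when testing residuals
    of a fitted AR model.  Default lag count is min(10, n//5), at least
    ``model_df + 1``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.nanstd(x) == 0:
        raise ValueError("zero-variance series")
    if n_lags is None:
        n_lags = max(min(10, n // 5), model_df + 1)
    if n <= n_lags + 1:
        raise ValueError(f"series too short for {n_lags} Ljung-Box lags")
    res = acorr_ljungbox(x, lags=[n_lags], model_df=model_df)
    return float(res["lb_stat"].iloc[0]), float(res["lb_pvalue"].iloc[0])


def durbin_watson(x: np.ndarray) -> float:
    """Durbin-Watson statistic sum((dx)^2)/sum(x^2), in [0, 4], ~2 for
    white noise."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Durbin-Watson needs n >= 3")
    if np.std(x) == 0:
        raise ValueError("zero-variance series")
    return float(_sm_dw(x))


def ar_fit_cls(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional-least-squares AR(p) fit with intercept.

    Returns (coefficients [c, phi_1..phi_p], residuals of length n - p).
    Order 0 returns the mean-centred series.
    """
    x = np.asarray(x, dtype=float)
    if order == 0:
        return np.array([x.mean()]), x - x.mean()
    n = x.size
    if n <= 2 * order + 1:
        raise ValueError(f"series too short for AR({order})")
    X = np.column_stack([np.ones(n - order)]
                        + [x[order - k - 1: n - k - 1] for k in range(order)])
    y = x[order:]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


@dataclass
class PrewhitenResult:
    """Outcome of detrend + AR-order selection for one annual series."""

    years: np.ndarray            # years of the residual series (first p dropped)
    residuals: np.ndarray
    order: int
    ar_coefs: np.ndarray
    trend: TrendFit
    detrended: np.ndarray
    lb_stat: float
    lb_p: float
    dw: float
    whitened: bool               # False when even the max order failed the tests


def prewhiten(series: AnnualSeries, alpha: float = 0.05, max_order: int = 5,
              dw_bounds: tuple[float, float] = (1.5, 2.5)) -> PrewhitenResult:
    """Detrend, then take residuals of the lowest-order AR fit whose
    residuals pass both the Ljung-Box (p >= alpha) and Durbin-Watson
    (within ``dw_bounds``) checks.

    Order 0 means the detrended series itself was already white.  If no
    order up to ``max_order`` passes, the max-order residuals are returned
    with ``whitened=False``.
    """
    s = series.dropna()
    if s.n < 10:
        raise ValueError("prewhitening needs at least 10 years")
    trend, det = detrend_linear(s)
    last = None
    for p in range(max_order + 1):
        try:
            coefs, resid = ar_fit_cls(det.values, p)
        except ValueError:
            break
        lb_stat, lb_p = ljung_box(resid, model_df=p)
        dw = durbin_watson(resid)
        ok = lb_p >= alpha and dw_bounds[0] <= dw <= dw_bounds[1]
        last = PrewhitenResult(det.years[p:], resid, p, coefs, trend, det.values,
                               lb_stat, lb_p, dw, ok)
        if ok:
            return last
    assert last is not None
    return last


# ---------------------------------------------------------------------------
# lagged pairing and correlation
# ---------------------------------------------------------------------------

def lagged_pair(sal: AnnualSeries, oxy: AnnualSeries, lag: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align a salinity-month series with an oxygen-month series at ``lag``
    months, pairing across the New Year when the lag wraps (salinity in
    Nov/Dec of year y with oxygen in Jan/Feb of year y+1).

    Returns (years of the salinity member, salinity values, oxygen values).
    """
    if sal.month is None or oxy.month is None:
        raise ValueError("both series need a month for season alignment")
    expect = sal.month + lag
    carry = 1 if expect > 12 else 0
    if (expect - 1) % 12 + 1 != oxy.month:
        raise ValueError(f"oxygen month {oxy.month} does not equal salinity month "
                         f"{sal.month} + lag {lag}")
    sal = sal.dropna()
    oxy = oxy.dropna()
    oxy_years_needed = sal.years + carry
    common = np.intersect1d(oxy_years_needed, oxy.years)
    if common.size < 10:
        raise ValueError(f"only {common.size} overlapping years (need >= 10)")
    si = np.searchsorted(sal.years, common - carry)
    oi = np.searchsorted(oxy.years, common)
    return common - carry, sal.values[si], oxy.values[oi]


def star_code(p: float) -> str:
    """Significance stars with breakpoints 0.05 / 0.01 / 0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class XCorrCell:
    """One cell of the correlation grid."""

    sal_month: int
    oxy_month: int
    lag: int
    depth_m: float
    r: float
    p: float
    stars: str
    n: int


def cross_correlation(x: np.ndarray, y: np.ndarray, *, sal_month: int = 0,
                      oxy_month: int = 0, lag: int = 0, depth_m: float = np.nan
                      ) -> XCorrCell:
    """Pearson r on prewhitened residual pairs with a two-sided t-test on
    n - 2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need >= 10 aligned pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return XCorrCell(sal_month, oxy_month, lag, depth_m, np.nan, np.nan, "", x.size)
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return XCorrCell(sal_month, oxy_month, lag, depth_m, r, p, star_code(p), n)


@dataclass
class XCorrMatrix:
    """Correlation grid over (salinity month, lag, downstream depth)."""

    cells: list[XCorrCell] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.sal_month, c.oxy_month, c.lag, c.depth_m, c.r, c.p, c.stars, c.n)
             for c in self.cells],
            columns=["sal_month", "oxy_month", "lag", "depth_m", "r", "p", "stars", "n"])

    def peak(self, min_depth: float = -np.inf) -> XCorrCell:
        """Cell with the largest |r| among depths >= min_depth."""
        eligible = [c for c in self.cells
                    if c.depth_m >= min_depth and np.isfinite(c.r)]
        if not eligible:
            raise ValueError("no finite cells")
        return max(eligible, key=lambda c: abs(c.r))


def xcorr_matrix(upstream: ProfileSeries, downstream: ProfileSeries,
                 salinity_depth: float = 33.0, min_oxygen_depth: float = 50.0,
                 sal_months: tuple[int, ...] = SALINITY_MONTHS,
                 lags: tuple[int, ...] = LAGS, alpha: float = 0.05,
                 max_order: int = 5) -> XCorrMatrix:
    """Full correlation grid between upstream salinity at ``salinity_depth``
    and downstream oxygen at every depth below ``min_oxygen_depth``.

    Every series entering a correlation is detrended and AR-prewhitened
    independently.  Failures in individual cells (too few years, level
    fully masked, unparseable variance) yield NaN cells rather than
    aborting the grid.
    """
    upstream = _ensure_monthly(upstream)
    downstream = _ensure_monthly(downstream)
    sal_ms = depth_level_series(upstream, salinity_depth, "salinity")

    sal_white: dict[int, PrewhitenResult | None] = {}
    for m in sal_months:
        try:
            sal_white[m] = prewhiten(annual_series(sal_ms, m), alpha, max_order)
        except ValueError:
            sal_white[m] = None

    depths = [d for d in downstream.depths if d > min_oxygen_depth]
    oxy_months = sorted({(m + k - 1) % 12 + 1 for m in sal_months for k in lags})
    oxy_white: dict[tuple[int, float], PrewhitenResult | None] = {}
    for d in depths:
        oxy_ms = depth_level_series(downstream, d, "oxygen")
        for m in oxy_months:
            try:
                oxy_white[(m, d)] = prewhiten(annual_series(oxy_ms, m), alpha, max_order)
            except ValueError:
                oxy_white[(m, d)] = None

    cells = []
    for m in sal_months:
        sw = sal_white[m]
        for k in lags:
            om = (m + k - 1) % 12 + 1
            for d in depths:
                ow = oxy_white[(om, d)]
                cell = XCorrCell(m, om, k, float(d), np.nan, np.nan, "", 0)
                if sw is not None and ow is not None:
                    try:
                        _, xs, ys = lagged_pair(
                            AnnualSeries(sw.years, sw.residuals, month=m),
                            AnnualSeries(ow.years, ow.residuals, month=om), k)
                        cell = cross_correlation(xs, ys, sal_month=m, oxy_month=om,
                                                 lag=k, depth_m=float(d))
                    except ValueError:
                        pass
                cells.append(cell)
    return XCorrMatrix(cells)
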