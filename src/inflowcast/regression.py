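"""Simple-linear-regression fits with full diagnostics, and leave-one-out
cross-validation.

:class:`RegressionFit` carries the complete diagnostic set printed in the
report tables (coefficients with SEs, t and p, R2, adjusted R2, residual
standard error, F, residual degrees of freedom) and can also be built
directly from published coefficients to apply an externally fitted
relationship.

LOOCV refits the line n times by closed-form normal equations, recording
per fold the squared error on the held-out point, the training mean
squared error and the training R2; the aggregate format mirrors the
cross-validation blocks of the report tables.  The per-fold error metric
is configurable (mse default, rmse, mae at the fold level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionFit:
    """OLS fit y = intercept + slope*x with diagnostics."""

    intercept: float
    slope: float
    se_intercept: float = np.nan
    se_slope: float = np.nan
    t_intercept: float = np.nan
    t_slope: float = np.nan
    p_intercept: float = np.nan
    p_slope: float = np.nan
    r2: float = np.nan
    adj_r2: float = np.nan
    resid_se: float = np.nan
    fstat: float = np.nan
    f_p: float = np.nan
    df_resid: int = 0
    n: int = 0
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    excluded: list = field(default_factory=list)
    response: str = ""

    def predict(self, x0) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return (self.slope - tcrit * self.se_slope, self.slope + tcrit * self.se_slope)

    def mean_response_se(self, x0: float) -> float:
        """Standard error of the fitted mean response at x0."""
        if self.x is None:
            raise ValueError("fit carries no training data")
        xb = self.x.mean()
        sxx = float(np.sum((self.x - xb) ** 2))
        return float(self.resid_se * np.sqrt(1.0 / self.n + (x0 - xb) ** 2 / sxx))

    @property
    def training_range(self) -> tuple[float, float]:
        if self.x is None:
            raise ValueError("fit carries no training data")
        return float(self.x.min()), float(self.x.max())


def fit_ols(x, y, response: str = "", excluded: list | None = None) -> RegressionFit:
    """OLS with intercept; pairs with NaN in either variable are dropped.

    Needs >= 4 complete pairs and nonzero predictor variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("zero predictor variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
        t_intercept=float(res.tvalues[0]), t_slope=float(res.tvalues[1]),
        p_intercept=float(res.pvalues[0]), p_slope=float(res.pvalues[1]),
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        resid_se=float(np.sqrt(res.mse_resid)),
        fstat=float(res.fvalue), f_p=float(res.f_pvalue),
        df_resid=int(res.df_resid), n=int(x.size), x=x, y=y,
        excluded=list(excluded or []), response=response)


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression coefficients (intercept, slope)."""
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    slope = np.sum((x - xb) * (y - yb)) / sxx
    return yb - slope * xb, slope


@dataclass
class LoocvResult:
    """Aggregated leave-one-out cross-validation of a simple regression."""

    mean_r2: float
    r2_sd: float
    mean_train_error: float
    train_error_interval: float   # half-width of the 2.5-97.5 percentile band
    mean_test_error: float
    test_error_interval: float
    metric: str
    folds: pd.DataFrame           # per-fold r2 / train_error / test_error


def _percentile_halfwidth(v: np.ndarray) -> float:
    lo, hi = np.percentile(v, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def loocv(x, y, metric: str = "mse") -> LoocvResult:
    """n-fold leave-one-out cross-validation of the simple linear fit.

    Per fold the line is refitted on the n-1 remaining points and
    evaluated on the held-out one.  ``metric`` applies at the fold level:
    'mse' (squared error; default), 'rmse', or 'mae'.  The 95% intervals
    are percentile half-widths over folds, robust to the heavy skew of
    single-point test errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError(f"LOOCV needs >= 5 points, got {n}")
    if metric not in ("mse", "rmse", "mae"):
        raise ValueError(f"unknown metric '{metric}'")
    rows = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xt, yt = x[keep], y[keep]
        a, b = _line_fit(xt, yt)
        fitted = a + b * xt
        sse = float(np.sum((yt - fitted) ** 2))
        sst = float(np.sum((yt - yt.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        train_res = np.abs(yt - fitted)
        test_res = abs(y[i] - (a + b * x[i]))
        if metric == "mse":
            tr, te = float(np.mean(train_res ** 2)), float(test_res ** 2)
        elif metric == "rmse":
            tr, te = float(np.sqrt(np.mean(train_res ** 2))), float(test_res)
        else:
            tr, te = float(np.mean(train_res)), float(test_res)
        rows.append((i, r2, tr, te))
    folds = pd.DataFrame(rows, columns=["fold", "r2", "train_error", "test_error"])
    return LoocvResult(
        mean_r2=float(folds["r2"].mean()), r2_sd=float(folds["r2"].std(ddof=1)),
        mean_train_error=float(folds["train_error"].mean()),
        train_error_interval=_percentile_halfwidth(folds["train_error"].to_numpy()),
        mean_test_error=float(folds["test_error"].mean()),
        test_error_interval=_percentile_halfwidth(folds["test_error"].to_numpy()),
        metric=metric, folds=folds)
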