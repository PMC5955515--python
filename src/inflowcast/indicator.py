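"""The winter-salinity early-warning indicator.

The predictor is the maximum of the January-March monthly-mean salinity
at the 33 m level in the upstream (Arkona-like) basin; responses are the
April mean oxygen of the downstream 50-70 m and 70-95 m layers and the
April egg-survival probability (0-1) at the 1009/1011/1013 kg/m3
buoyancy levels.  Fits are ordinary least squares, validated by
leave-one-out cross-validation; forecasts clamp survival into [0, 1] and
warn when the salinity lies beyond the training range plus a guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import (CANONICAL_LEVELS, DensityLevel, DepthLayer, MonthlySeries,
                       ProfileSeries, depth_level_series, isopycnal_series,
                       layer_mean_series, _ensure_monthly)
from .regression import LoocvResult, RegressionFit, fit_ols, loocv
from .survival import DEFAULT_PARAMS, SurvivalCurveParams, survival_series

WINTER_MONTHS = (1, 2, 3)
DEFAULT_LAYERS = (DepthLayer(50.0, 70.0), DepthLayer(70.0, 95.0))


def max_winter_salinity(salinity_33m: MonthlySeries, year: int
                        ) -> tuple[float, int | None]:
    """Maximum of the available Jan/Feb/Mar monthly means for one year.

    Returns (value, contributing month); (nan, None) when all three
    months are missing.
    """
    best, best_month = np.nan, None
    for m in WINTER_MONTHS:
        v = salinity_33m.value(year, m)
        if np.isfinite(v) and (best_month is None or v > best):
            best, best_month = v, m
    return best, best_month


def build_indicator_dataset(upstream: ProfileSeries, downstream: ProfileSeries,
                            salinity_depth: float = 33.0,
                            layers: tuple[DepthLayer, ...] = DEFAULT_LAYERS,
                            levels: tuple[DensityLevel, ...] = CANONICAL_LEVELS,
                            params: SurvivalCurveParams = DEFAULT_PARAMS
                            ) -> pd.DataFrame:
    """Assemble the per-year indicator table.

    One row per overlapping year: ``s_max`` (with its month), April layer
    oxygen means (columns ``oxy_<top>_<bottom>``) and April survival
    probabilities on the 0-1 scale (columns ``surv_<level>``, NaN where
    the level is absent in April).
    """
    upstream = _ensure_monthly(upstream)
    downstream = _ensure_monthly(downstream)
    sal = depth_level_series(upstream, salinity_depth, "salinity")
    layer_series = {ly: layer_mean_series(downstream, ly, "oxygen") for ly in layers}
    surv = {lv: survival_series(isopycnal_series(downstream, lv, "oxygen"), params)
            for lv in levels}

    years = sorted(set(sal.years()) & set(downstream.times.year))
    if len(years) < 10:
        raise ValueError(f"only {len(years)} overlapping years (need >= 10)")
    rows = []
    for y in years:
        smax, month = max_winter_salinity(sal, y)
        row = {"year": int(y), "s_max": smax, "s_max_month": month}
        for ly, ms in layer_series.items():
            row[f"oxy_{ly.top:g}_{ly.bottom:g}"] = ms.value(y, 4)
        for lv, ms in surv.items():
            v = ms.value(y, 4)
            row[f"surv_{lv.target:g}"] = (np.nan if ms.is_absent(y, 4)
                                          else (v / 100.0 if np.isfinite(v) else np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_indicator(dataset: pd.DataFrame, response: str) -> tuple[RegressionFit, LoocvResult]:
    """Fit one response column on ``s_max`` (NaN rows dropped pairwise) and
    cross-validate it."""
    fit = fit_ols(dataset["s_max"], dataset[response], response=response)
    cv = loocv(dataset["s_max"], dataset[response])
    return fit, cv


@dataclass
class Forecast:
    """Point prediction with uncertainty for one response."""

    salinity: float
    response: str
    point: float
    half_width: float | None       # t-based SE of the mean response, 68% level
    interval_level: float | None
    clamped: bool = False          # survival clipped into [0, 1]
    raw_point: float | None = None
    extrapolation_warning: str | None = None


def forecast(fit: RegressionFit, s_max: float, response_kind: str = "oxygen",
             level: float = 0.68, guard_fraction: float = 0.10) -> Forecast:
    """Apply a fitted (or published) relationship at salinity ``s_max``.

    The default uncertainty is the t-based standard error of the mean
    response at ``s_max`` at the 68% level; it is omitted (None) when the
    fit carries no training data, e.g. when built from published
    coefficients alone.  Survival responses are clamped to [0, 1] with the
    raw value retained.  An extrapolation warning (never an error) is
    recorded when ``s_max`` exceeds the training range by more than
    ``guard_fraction`` of its width.
    """
    point = float(fit.predict(s_max))
    half = None
    lvl = None
    warning = None
    if fit.x is not None and fit.n >= 3:
        tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
        half = float(tcrit * fit.mean_response_se(s_max))
        lvl = level
        lo, hi = fit.training_range
        guard = guard_fraction * (hi - lo)
        if s_max > hi + guard or s_max < lo - guard:
            warning = (f"salinity {s_max:g} psu outside training range "
                       f"[{lo:.2f}, {hi:.2f}] + {guard_fraction:.0%} guard")
    raw = point
    clamped = False
    if response_kind == "survival":
        clipped = min(max(point, 0.0), 1.0)
        clamped = clipped != point
        point = clipped
    return Forecast(salinity=float(s_max), response=fit.response or response_kind,
                    point=point, half_width=half, interval_level=lvl,
                    clamped=clamped, raw_point=raw, extrapolation_warning=warning)
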