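"""Seasonal persistence of the egg-habitat oxygen conditions.

For each year and buoyancy (density) level the April oxygen value is
compared with August to establish the predominant direction of the
seasonal development, and the May-August integral (sum of the four
monthly means, ml/l*month) is regressed on the April value.  Years in
which the density level does not exist in April, or disappears during
June-August after being present, are excluded from the regression -- in
practice this affects the densest (1013 kg/m3, young-female) level in
low-salinity stagnation years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import MonthlySeries, level_absence_report
from .regression import RegressionFit, fit_ols

SEASON_MONTHS = (5, 6, 7, 8)  # integral months May..Aug


def build_season_records(iso_by_level: dict[float, MonthlySeries]) -> pd.DataFrame:
    """One record per (year, density level) from monthly isopycnal oxygen.

    Columns: year, level, april, may..aug, august, integral (present only
    when all of May-Aug are), exists_in_april, disappeared_during_season.
    """
    rows = []
    for level, iso in iso_by_level.items():
        flags = level_absence_report(iso)
        for year in iso.years():
            monthly = {m: iso.value(year, m) for m in (4,) + SEASON_MONTHS}
            integral = (float(sum(monthly[m] for m in SEASON_MONTHS))
                        if all(np.isfinite(monthly[m]) for m in SEASON_MONTHS)
                        else np.nan)
            f = flags.loc[year] if year in flags.index else None
            rows.append({
                "year": int(year), "level": float(level),
                "april": monthly[4], "may": monthly[5], "jun": monthly[6],
                "jul": monthly[7], "aug": monthly[8], "integral": integral,
                "exists_in_april": bool(f["exists_in_april"]) if f is not None else False,
                "disappeared_during_season":
                    bool(f["disappeared_during_season"]) if f is not None else False,
            })
    return pd.DataFrame(rows)


def decline_fraction(records: pd.DataFrame) -> tuple[float, int, int]:
    """Fraction of (year, level) cases with August oxygen strictly below
    April.  Ties are not declines.  Returns (fraction, declines, valid)."""
    valid = records.dropna(subset=["april", "aug"])
    n = len(valid)
    if n == 0:
        raise ValueError("no cases with both April and August present")
    declines = int((valid["aug"] < valid["april"]).sum())
    return declines / n, declines, n


def fit_season_regression(records: pd.DataFrame, level: float) -> RegressionFit:
    """OLS of the May-August integral on the April value for one density
    level, applying the absence exclusions."""
    sub = records[records["level"] == level]
    if sub.empty:
        raise ValueError(f"no records for level {level}")
    excluded = [
        (int(r.year), "level absent in April" if not r.exists_in_april
         else "level disappeared during season")
        for r in sub.itertuples()
        if not r.exists_in_april or r.disappeared_during_season]
    usable = sub[sub["exists_in_april"] & ~sub["disappeared_during_season"]]
    usable = usable.dropna(subset=["april", "integral"])
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable records for level {level} "
                         "(need >= 10)")
    return fit_ols(usable["april"], usable["integral"],
                   response=f"integral_may_aug@{level:g}", excluded=excluded)
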