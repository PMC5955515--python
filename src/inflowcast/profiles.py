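"""Hydrographic profile containers, I/O and reductions.

The universal exchange object is :class:`ProfileSeries`, a time x depth grid
of salinity (psu), temperature (degC) and oxygen (ml/l) for one averaging
region, carried as an :class:`xarray.Dataset`.  Missing values are NaN.
All statistics downstream operate on :class:`MonthlySeries`, a
(year, month)-indexed scalar series with units and provenance.

Reductions provided here:

* calendar-monthly means of daily series,
* extraction at a fixed depth level (e.g. the 33 m salinity level),
* unweighted means over a depth layer (e.g. 70-95 m oxygen),
* one-atmosphere EOS-80 seawater density, and
* interpolation of a variable onto an isopycnal (egg neutral-buoyancy)
  surface, with per-month "level absent" flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

VARIABLES = ("salinity", "temperature", "oxygen")

#: header expected by the long-form delimited reader
LONGFORM_COLUMNS = ("date", "depth_m", "salinity_psu", "temperature_c", "oxygen_ml_l")

_LONG_TO_VAR = {
    "salinity_psu": "salinity",
    "temperature_c": "temperature",
    "oxygen_ml_l": "oxygen",
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProfileSeries:
    """Time x depth grid of salinity, temperature and oxygen for one region.

    ``data`` must have monotonically increasing ``time`` (datetime) and
    ``depth`` (metres, positive down) coordinates and float variables among
    ``salinity``/``temperature``/``oxygen`` on (time, depth).
    """

    data: xr.Dataset
    region: str = ""

    def __post_init__(self) -> None:
        ds = self.data
        for coord in ("time", "depth"):
            if coord not in ds.coords:
                raise ValueError(f"ProfileSeries requires a '{coord}' coordinate")
            vals = ds[coord].values
            if vals.size > 1 and not np.all(np.diff(vals.astype("f8") if coord == "depth" else vals) > 0):
                raise ValueError(f"'{coord}' axis must be strictly increasing")
        present = [v for v in VARIABLES if v in ds]
        if not present:
            raise ValueError("ProfileSeries holds none of salinity/temperature/oxygen")
        for v in present:
            if ds[v].dims != ("time", "depth"):
                ds[v] = ds[v].transpose("time", "depth")

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth"].values.astype(float)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    def variables(self) -> list[str]:
        return [v for v in VARIABLES if v in self.data]

    def is_monthly(self) -> bool:
        """True when there is at most one sample per calendar month."""
        t = self.times
        return not pd.MultiIndex.from_arrays([t.year, t.month]).duplicated().any()


@dataclass
class MonthlySeries:
    """Scalar series indexed by (year, month) with units and provenance.

    ``absent`` marks months where the value is undefined because the target
    density level did not exist in the water column (as opposed to plain
    missing data); it propagates through survival and exclusion logic.
    """

    data: pd.Series  # MultiIndex (year, month) -> float
    units: str = ""
    provenance: dict = field(default_factory=dict)
    absent: pd.Series | None = None  # bool, aligned with data

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.MultiIndex) or idx.names != ["year", "month"]:
            raise ValueError("MonthlySeries index must be a (year, month) MultiIndex")
        if idx.duplicated().any():
            raise ValueError("at most one value per (year, month)")
        if self.absent is not None and not self.absent.index.equals(idx):
            raise ValueError("'absent' flags must align with the data index")

    def value(self, year: int, month: int) -> float:
        """Value for one (year, month); NaN when missing."""
        try:
            return float(self.data.loc[(year, month)])
        except KeyError:
            return float("nan")

    def is_absent(self, year: int, month: int) -> bool:
        if self.absent is None:
            return False
        try:
            return bool(self.absent.loc[(year, month)])
        except KeyError:
            return False

    def years(self) -> np.ndarray:
        return np.unique(self.data.index.get_level_values("year"))


@dataclass(frozen=True)
class DensityLevel:
    """Target density surface (kg/m3) and the female age class whose eggs
    are neutrally buoyant there (1009 old, 1011 mid-age, 1013 young)."""

    target: float
    age_class: str = ""

    def __post_init__(self) -> None:
        if not 1000.0 < self.target < 1030.0:
            raise ValueError(f"density target {self.target} outside (1000, 1030) kg/m3")


#: canonical egg neutral-buoyancy levels
CANONICAL_LEVELS = (
    DensityLevel(1009.0, "old"),
    DensityLevel(1011.0, "mid-age"),
    DensityLevel(1013.0, "young"),
)


@dataclass(frozen=True)
class DepthLayer:
    """Depth layer [top, bottom] in metres, positive down."""

    top: float
    bottom: float

    def __post_init__(self) -> None:
        if not 0 <= self.top < self.bottom:
            raise ValueError(f"invalid layer {self.top}:{self.bottom}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profiles(path, region: str = "") -> ProfileSeries:
    """Read a long-form delimited profile table.

    The table must carry the header ``date, depth_m, salinity_psu,
    temperature_c, oxygen_ml_l`` (comma-, tab- or semicolon-separated).
    Unparseable numeric cells are masked (NaN) and counted in the log.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in LONGFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    n_bad = 0
    for col in ("depth_m", "salinity_psu", "temperature_c", "oxygen_ml_l"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_bad:
        logger.info("read_profiles(%s): masked %d unparseable cells", path, n_bad)
    df = df.dropna(subset=["depth_m"])
    times = np.sort(df["date"].unique())
    depths = np.sort(df["depth_m"].unique())
    shape = (times.size, depths.size)
    arrays = {v: np.full(shape, np.nan) for v in VARIABLES}
    ti = pd.Index(times).get_indexer(df["date"])
    di = pd.Index(depths).get_indexer(df["depth_m"])
    for col, var in _LONG_TO_VAR.items():
        arrays[var][ti, di] = df[col].to_numpy()
    ds = xr.Dataset(
        {v: (("time", "depth"), arrays[v]) for v in VARIABLES},
        coords={"time": times, "depth": depths.astype(float)},
    )
    return ProfileSeries(ds, region=region)


def write_profiles(series: ProfileSeries, path) -> None:
    """Write a ProfileSeries as a long-form delimited table (round-trips
    with :func:`read_profiles`)."""
    ds = series.data
    t = np.repeat(series.times.values, series.depths.size)
    d = np.tile(series.depths, series.times.size)
    out = pd.DataFrame({"date": pd.DatetimeIndex(t).strftime("%Y-%m-%d"), "depth_m": d})
    for col, var in _LONG_TO_VAR.items():
        if var in ds:
            out[col] = ds[var].values.ravel()
        else:
            out[col] = np.nan
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def monthly_mean(series: ProfileSeries) -> ProfileSeries:
    """Per-calendar-month arithmetic mean at every depth, skipping NaN.

    Months with no valid observation stay NaN.  Idempotent on already
    monthly input.
    """
    if series.times.size == 0:
        raise ValueError("empty series")
    if series.is_monthly():
        return series
    ds = series.data.resample(time="MS").mean(skipna=True)
    return ProfileSeries(ds, region=series.region)


def _ensure_monthly(series: ProfileSeries) -> ProfileSeries:
    return series if series.is_monthly() else monthly_mean(series)


def _to_monthly_series(values: np.ndarray, times: pd.DatetimeIndex, units: str,
                       provenance: dict, absent: np.ndarray | None = None) -> MonthlySeries:
    idx = pd.MultiIndex.from_arrays([times.year, times.month], names=["year", "month"])
    data = pd.Series(values, index=idx)
    ab = pd.Series(absent, index=idx) if absent is not None else None
    return MonthlySeries(data=data, units=units, provenance=provenance, absent=ab)


_UNITS = {"salinity": "psu", "temperature": "degC", "oxygen": "ml/l"}


def depth_level_series(series: ProfileSeries, depth: float, variable: str) -> MonthlySeries:
    """Monthly series of ``variable`` at the grid depth nearest ``depth``.

    Ties between two equally near grid depths resolve to the shallower one.
    """
    series = _ensure_monthly(series)
    grid = series.depths
    if depth < grid.min() or depth > grid.max():
        raise ValueError(f"requested depth {depth} m outside grid span "
                         f"[{grid.min()}, {grid.max()}] m")
    dist = np.abs(grid - depth)
    k = int(np.flatnonzero(dist == dist.min())[0])  # shallower wins ties
    vals = series.data[variable].values[:, k]
    prov = {"variable": variable, "region": series.region,
            "requested_depth_m": float(depth), "grid_depth_m": float(grid[k])}
    return _to_monthly_series(vals.copy(), series.times, _UNITS[variable], prov)


def layer_mean_series(series: ProfileSeries, layer: DepthLayer, variable: str) -> MonthlySeries:
    """Monthly series of the unweighted mean of ``variable`` over all grid
    depths inside ``layer`` (uniform grids make this thickness-weighted)."""
    series = _ensure_monthly(series)
    grid = series.depths
    sel = (grid >= layer.top) & (grid <= layer.bottom)
    if not sel.any():
        raise ValueError(f"no grid depth inside layer {layer.top}:{layer.bottom} m")
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(series.data[variable].values[:, sel], axis=1)
    prov = {"variable": variable, "region": series.region,
            "layer_m": (layer.top, layer.bottom),
            "grid_depths_m": [float(d) for d in grid[sel]]}
    return _to_monthly_series(vals, series.times, _UNITS[variable], prov)


def _density_poly(S, T):
    """EOS-80 one-atmosphere density polynomial, no input validation."""
    rho_w = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T**2
             + 1.001685e-4 * T**3 - 1.120083e-6 * T**4 + 6.536332e-9 * T**5)
    A = (8.24493e-1 - 4.0899e-3 * T + 7.6438e-5 * T**2
         - 8.2467e-7 * T**3 + 5.3875e-9 * T**4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def density_eos(salinity, temperature):
    """One-atmosphere seawater density rho(S, T, p=0) in kg/m3 (EOS-80).

    Polynomial of Millero & Poisson (1981) as adopted in the UNESCO 1980
    equation of state; valid for practical salinity 0-42 and temperature
    -2-40 degC.  Accepts scalars or arrays; NaN inputs yield NaN.
    """
    S = np.asarray(salinity, dtype=float)
    T = np.asarray(temperature, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((S < 0) | (S > 42)):
            raise ValueError("salinity outside EOS-80 validity range [0, 42]")
        if np.any((T < -2) | (T > 40)):
            raise ValueError("temperature outside EOS-80 validity range [-2, 40] degC")
    rho = _density_poly(S, T)
    return float(rho) if np.isscalar(salinity) and np.isscalar(temperature) else rho


def isopycnal_series(series: ProfileSeries, level: DensityLevel, variable: str) -> MonthlySeries:
    """Monthly series of ``variable`` interpolated onto a density surface.

    Per month the density profile rho(d) is computed from salinity and
    temperature via :func:`density_eos`; the shallowest depth where rho
    crosses ``level.target`` is located by linear interpolation between the
    bracketing grid depths, and the variable is linearly interpolated to
    that depth.  Months where the target density is never reached are NaN
    with the ``absent`` flag set (the buoyancy level does not exist).
    """
    series = _ensure_monthly(series)
    ds = series.data
    if "salinity" not in ds or "temperature" not in ds:
        raise ValueError("isopycnal interpolation needs salinity and temperature")
    S = ds["salinity"].values
    T = ds["temperature"].values
    V = ds[variable].values
    target = level.target
    nt = S.shape[0]
    out = np.full(nt, np.nan)
    absent = np.zeros(nt, dtype=bool)
    for i in range(nt):
        ok = ~(np.isnan(S[i]) | np.isnan(T[i]))
        if not ok.any():
            continue  # wholly masked month: NaN, not "absent"
        rho = density_eos(S[i][ok], T[i][ok])
        v = V[i][ok]
        depth_found = None
        for k in range(rho.size):
            if rho[k] == target:
                out[i] = v[k]
                depth_found = True
                break
            if k + 1 < rho.size and (rho[k] - target) * (rho[k + 1] - target) < 0:
                f = (target - rho[k]) / (rho[k + 1] - rho[k])
                out[i] = v[k] + f * (v[k + 1] - v[k])
                depth_found = True
                break
        if depth_found is None:
            absent[i] = True
    prov = {"variable": variable, "region": series.region,
            "density_level_kg_m3": target, "age_class": level.age_class}
    return _to_monthly_series(out, series.times, _UNITS[variable], prov, absent=absent)


def level_absence_report(iso: MonthlySeries,
                         season_months: tuple[int, ...] = (4, 5, 6, 7, 8)) -> pd.DataFrame:
    """Per-year existence flags for a buoyancy level over the spawning season.

    Returns a DataFrame indexed by year with boolean columns
    ``exists_in_april`` and ``disappeared_during_season`` (level absent in
    any of June/July/August after being present in an earlier season month).
    Missing months count as absent.
    """
    rows = {}
    for year in iso.years():
        present = {}
        for m in season_months:
            v = iso.value(year, m)
            present[m] = np.isfinite(v) and not iso.is_absent(year, m)
        exists_apr = present.get(4, False)
        disappeared = False
        for m in (6, 7, 8):
            if m in present and not present[m]:
                if any(present.get(e, False) for e in season_months if e < m):
                    disappeared = True
        rows[year] = {"exists_in_april": exists_apr,
                      "disappeared_during_season": disappeared}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("year")
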