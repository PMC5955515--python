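"""Synthetic two-basin inflow/stagnation simulator.

A deliberately minimal daily surrogate for a Baltic-like two-basin system:
an upstream, Arkona-like basin receiving episodic winter inflows of saline,
oxygen-rich water, and a downstream, Bornholm-like basin whose deep layers
relax toward the upstream sub-halocline state with a fixed advective delay.
It reproduces the statistical structure the downstream analyses assume --
winter inflow pulses, a ~3-week lagged deep-water response, oxygen renewal
at inflow followed by temperature- and oxygen-dependent decline, a
persistent halocline, and interannual variability spanning inflow and
stagnation years -- without any hydrodynamics.

Two generators are exposed:

* :func:`simulate` -- the mechanistic daily model above;
* :func:`simulate_linear_coupling` -- a calibration generator that embeds a
  *prescribed* linear relation between winter 33 m upstream salinity and
  April downstream deep-layer oxygen into full profile series, so pipeline
  parameter-recovery can be checked against a known true slope.

The calendar is a fixed 365-day year (standard month lengths, no leap
days); dates are emitted as real timestamps with Feb 29 never present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .profiles import ProfileSeries, _density_poly

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
DAYS_PER_YEAR = 365
#: winter inflow window: Nov 1 (0-based day-of-year 304) .. Mar 31 next year
WINTER_START_DOY = 304
WINTER_LENGTH = 151


def noleap_dates(start_year: int, n_years: int) -> pd.DatetimeIndex:
    """Daily timestamps for ``n_years`` fixed 365-day years (Feb 29 dropped)."""
    parts = []
    for y in range(start_year, start_year + n_years):
        d = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        parts.append(d[~((d.month == 2) & (d.day == 29))])
    return pd.DatetimeIndex(np.concatenate([p.values for p in parts]))


@dataclass(frozen=True)
class InflowEvent:
    """One inflow pulse: saline, near-saturation water entering the
    upstream basin's sub-halocline layers."""

    start_day: int              # day index within the simulated period
    duration: int               # days
    salinity_amplitude: float   # psu added to the upstream deep target
    oxygen_at_source: float     # ml/l carried by the inflowing water

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("event duration must be >= 1 day")
        if self.salinity_amplitude < 0:
            raise ValueError("salinity amplitude must be >= 0")
        if not 0 <= self.oxygen_at_source <= 12:
            raise ValueError("oxygen at source must lie in [0, 12] ml/l")

    def active(self, day: int) -> bool:
        return self.start_day <= day < self.start_day + self.duration


@dataclass
class SimulationConfig:
    """Parameters of the two-basin surrogate.

    Defaults give a 45-year hindcast-like run on a 3-m grid to 100 m with
    about one inflow event per winter, a 21-day advective delay, and deep
    oxygen consumption of Q10 type vanishing as oxygen runs out.
    """

    n_years: int = 45
    start_year: int = 1971
    depth_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1.5, 100.0, 3.0))  # 3-m layer midpoints
    halocline_depth_upstream: float = 30.0   # m
    halocline_depth_downstream: float = 60.0  # m
    halocline_width: float = 6.0             # m, sigmoid half-width
    advection_lag: int = 21                  # days, upstream->downstream delay
    mixing_rate: float = 0.1                 # 1/day, downstream deep intrusion
    stagnation_rate: float = 0.002           # 1/day, downstream deep decay without inflow
    intrusion_scale: float = 1.0             # psu salinity excess giving full intrusion
    upstream_relax: float = 0.02             # 1/day, upstream return to baseline
    event_relax: float = 0.15                # 1/day, relaxation during an event
    surface_relax: float = 0.1               # 1/day, surface ventilation
    ventilation_depth: float = 40.0          # m, summer ventilation (thermocline) limit
    winter_ventilation_depth: float = 58.0   # m, winter mixed layer reaches the halocline top
    ventilation_width: float = 3.0           # m, sharp cutoff at the mixing limit
    consumption_rate_ref: float = 0.8        # ml/l/month at T_ref
    temp_reference: float = 5.0              # degC
    temp_coefficient: float = 2.0            # Q10-style multiplier
    oxygen_half_saturation: float = 1.0      # ml/l
    event_rate_per_winter: float = 1.0       # Poisson mean per Nov-Mar season
    event_duration_mean: float = 20.0        # days
    amplitude_mean: float = 3.5              # psu
    amplitude_sd: float = 1.5                # psu
    oxygen_at_source: float = 8.0            # ml/l
    surface_salinity: float = 7.5            # psu
    deep_salinity_upstream: float = 15.0     # psu baseline below the halocline
    surface_oxygen: float = 8.0              # ml/l ventilated target
    temp_surface_mean: float = 8.0           # degC
    temp_deep_mean: float = 5.0              # degC
    temp_surface_amplitude: float = 7.0      # degC seasonal swing at surface
    temp_deep_amplitude: float = 0.5         # degC seasonal swing at depth
    noise_sd: float = 0.1                    # psu and ml/l daily additive noise
    seed: int = 0

    def validate(self) -> None:
        z = np.asarray(self.depth_grid, dtype=float)
        if z.ndim != 1 or z.size < 2 or not np.all(np.diff(z) > 0) or z[0] < 0:
            raise ValueError("depth_grid must be 1-D, positive-down, strictly increasing")
        if self.advection_lag < 0:
            raise ValueError("advection_lag must be >= 0")
        for name in ("mixing_rate", "stagnation_rate", "upstream_relax",
                     "event_relax", "surface_relax",
                     "consumption_rate_ref", "oxygen_half_saturation",
                     "event_rate_per_winter", "event_duration_mean", "noise_sd",
                     "amplitude_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BasinState:
    """Per-depth salinity, temperature and oxygen on one day."""

    salinity: np.ndarray
    temperature: np.ndarray
    oxygen: np.ndarray

    def copy(self) -> "BasinState":
        return BasinState(self.salinity.copy(), self.temperature.copy(), self.oxygen.copy())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _halocline_weight(z: np.ndarray, depth: float, width: float) -> np.ndarray:
    return _sigmoid((z - depth) / width)


def temperature_profile(config: SimulationConfig, doy: int) -> np.ndarray:
    """Deterministic seasonal temperature: warm, strongly seasonal surface
    water over cold (~5 degC), nearly aseasonal deep water; annual maximum
    around late July (day-of-year 210)."""
    z = np.asarray(config.depth_grid, dtype=float)
    w = _sigmoid((z - 25.0) / 10.0)  # 0 at surface, 1 at depth
    mean = config.temp_surface_mean * (1 - w) + config.temp_deep_mean * w
    amp = config.temp_surface_amplitude * (1 - w) + config.temp_deep_amplitude * w
    return mean + amp * np.cos(2 * np.pi * (doy - 210) / DAYS_PER_YEAR)


def sample_inflow_events(config: SimulationConfig, rng: np.random.Generator) -> list[InflowEvent]:
    """Draw inflow events from a per-winter Poisson process.

    Event counts are Poisson(``event_rate_per_winter``) per Nov-Mar season;
    start days are uniform over the 151-day winter window, which puts ~61%
    of events in Nov-Jan, mirroring the observed dominance of that period.
    Amplitudes are normal(mean, sd) clipped to >= 0.2 psu; durations are
    geometric-like around ``event_duration_mean``.
    """
    config.validate()
    events: list[InflowEvent] = []
    n_days = config.n_years * DAYS_PER_YEAR
    for winter in range(config.n_years):
        count = rng.poisson(config.event_rate_per_winter)
        for _ in range(count):
            offset = int(rng.integers(0, WINTER_LENGTH))
            start = winter * DAYS_PER_YEAR + WINTER_START_DOY + offset
            if start >= n_days:
                continue
            duration = max(3, int(round(rng.exponential(config.event_duration_mean))))
            amp = max(0.2, rng.normal(config.amplitude_mean, config.amplitude_sd))
            events.append(InflowEvent(start, duration, amp, config.oxygen_at_source))
    events.sort(key=lambda e: e.start_day)
    return events


def baseline_state(config: SimulationConfig, basin: str, doy: int = 0) -> BasinState:
    """Equilibrium-like initial state: stratified salinity, ventilated
    oxygen, seasonal temperature."""
    z = np.asarray(config.depth_grid, dtype=float)
    hc = (config.halocline_depth_upstream if basin == "upstream"
          else config.halocline_depth_downstream)
    w = _halocline_weight(z, hc, config.halocline_width)
    sal = config.surface_salinity + (config.deep_salinity_upstream - config.surface_salinity) * w
    oxy = np.full_like(z, config.surface_oxygen)
    return BasinState(sal, temperature_profile(config, doy), oxy)


def _consumption(oxygen: np.ndarray, temperature: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    """Daily oxygen consumption r(T, O2): higher at higher temperature,
    vanishing as oxygen approaches zero (Michaelis-Menten in O2)."""
    q = config.temp_coefficient ** ((temperature - config.temp_reference) / 10.0)
    mm = oxygen / (oxygen + config.oxygen_half_saturation)
    return config.consumption_rate_ref / 30.0 * q * mm


def convective_adjust(state: BasinState, max_passes: int = 8) -> None:
    """Enforce non-decreasing density with depth by convective mixing.

    Statically unstable runs of layers are pooled -- salinity, temperature
    and oxygen replaced by the run mean, as in a convectively formed mixed
    layer (e.g. winter cooling below the temperature of maximum density) --
    with one monotone-pooling pass per iteration; since density is nearly
    linear in (S, T) over the pooled range, a single pass normally
    restores stability.
    """
    S, T, O = state.salinity, state.temperature, state.oxygen
    n = S.size
    for _ in range(max_passes):
        rho = _density_poly(S, T)
        if np.all(np.diff(rho) >= -1e-9):
            return
        # monotone pooling on the density profile, carrying S, T and O
        starts = [0]
        counts = [1]
        r_mean = [rho[0]]
        for k in range(1, n):
            starts.append(k)
            counts.append(1)
            r_mean.append(rho[k])
            while len(counts) > 1 and r_mean[-1] < r_mean[-2] - 1e-12:
                c2, c1 = counts.pop(), counts[-1]
                r2 = r_mean.pop()
                starts.pop()
                r_mean[-1] = (r_mean[-1] * c1 + r2 * c2) / (c1 + c2)
                counts[-1] = c1 + c2
        for s0, c in zip(starts, counts):
            if c > 1:
                S[s0:s0 + c] = S[s0:s0 + c].mean()
                T[s0:s0 + c] = T[s0:s0 + c].mean()
                O[s0:s0 + c] = O[s0:s0 + c].mean()


class _StepCache:
    """Static per-depth fields shared by every daily step of one run."""

    def __init__(self, config: SimulationConfig):
        z = np.asarray(config.depth_grid, dtype=float)
        self.z = z
        self.w_up = _halocline_weight(z, config.halocline_depth_upstream,
                                      config.halocline_width)
        self.w_dn = _halocline_weight(z, config.halocline_depth_downstream,
                                      config.halocline_width)
        self.deep_up = z >= config.halocline_depth_upstream
        # Ventilation weight per day-of-year: the wind-stirred/convective
        # mixed layer deepens from the summer thermocline limit to the
        # winter limit (peaking mid-February), capped by the basin's
        # halocline depth.
        season = np.maximum(0.0, np.cos(2 * np.pi * (np.arange(DAYS_PER_YEAR) - 45)
                                        / DAYS_PER_YEAR))
        vent_depth = (config.ventilation_depth
                      + (config.winter_ventilation_depth - config.ventilation_depth)
                      * season)
        self.v_up = np.vstack([
            1 - _halocline_weight(z, min(config.halocline_depth_upstream, vd),
                                  config.ventilation_width) for vd in vent_depth])
        self.v_dn = np.vstack([
            1 - _halocline_weight(z, min(config.halocline_depth_downstream, vd),
                                  config.ventilation_width) for vd in vent_depth])
        self.s_base_up = (config.surface_salinity
                          + (config.deep_salinity_upstream - config.surface_salinity)
                          * self.w_up)
        self.s_base_dn = (config.surface_salinity
                          + (config.deep_salinity_upstream - config.surface_salinity)
                          * self.w_dn)
        # reference value of the upstream sub-halocline mean at baseline;
        # the downstream basin responds to anomalies about it
        self.up_deep_ref = float(self.s_base_up[self.deep_up].mean())
        # one seasonal temperature profile per day-of-year
        self.temp = np.vstack([temperature_profile(config, d)
                               for d in range(DAYS_PER_YEAR)])


def step_day(state_up: BasinState, state_down: BasinState, events: list[InflowEvent],
             config: SimulationConfig, day: int,
             upstream_deep_history: list[tuple[float, float]] | None = None,
             rng: np.random.Generator | None = None,
             cache: _StepCache | None = None) -> tuple[BasinState, BasinState]:
    """Advance both basins by one day (in place; states are also returned).

    ``upstream_deep_history`` is the per-day record of upstream
    sub-halocline mean (salinity, oxygen); the downstream deep target is
    read from it ``advection_lag`` days back.  When omitted, a stationary
    history at the baseline deep state is assumed.
    """
    if cache is None:
        cache = _StepCache(config)
    z = cache.z
    for st in (state_up, state_down):
        if st.salinity.shape != z.shape:
            raise ValueError("state grids do not match config.depth_grid")
    doy = day % DAYS_PER_YEAR
    t_prof = cache.temp[doy]

    w_up, w_dn, deep_up = cache.w_up, cache.w_dn, cache.deep_up

    amp = max((e.salinity_amplitude for e in events if e.active(day)), default=0.0)
    active = amp > 0.0

    # upstream salinity: relax toward baseline (+ event amplitude below the
    # halocline while an inflow is running)
    target = cache.s_base_up + amp * w_up
    rate = config.event_relax if active else config.upstream_relax
    state_up.salinity += rate * (target - state_up.salinity)

    # upstream oxygen: ventilated surface; event pushes deep O2 to source value
    state_up.oxygen += config.surface_relax * cache.v_up[doy] * (config.surface_oxygen - state_up.oxygen)
    if active:
        src = max(e.oxygen_at_source for e in events if e.active(day))
        state_up.oxygen += config.event_relax * w_up * (src - state_up.oxygen)

    # downstream: deep layers relax toward the delayed upstream deep state.
    # Renewal rides on dense gravity currents, which reach the deep basin
    # only when the (delayed) upstream deep water is saltier than the
    # resident bottom water; the intrusion strength ramps up to the full
    # mixing_rate over intrusion_scale psu of excess.  Without an excess,
    # salinity only freshens slowly (stagnation_rate) and deep oxygen
    # receives no renewal at all, so stagnation-phase deep oxygen can
    # only decline -- minor inflows arriving after a major one fail to
    # ventilate, as observed.
    if upstream_deep_history is not None and len(upstream_deep_history) > config.advection_lag:
        s_del, o_del = upstream_deep_history[len(upstream_deep_history) - 1 - config.advection_lag]
    else:
        s_del, o_del = cache.up_deep_ref, config.surface_oxygen
    s_target_dn = cache.s_base_dn + (s_del - cache.up_deep_ref) * w_dn
    excess = max(0.0, float(s_target_dn[-1] - state_down.salinity[-1]))
    intrusion = min(excess / config.intrusion_scale, 1.0)
    deep_rate_s = (config.stagnation_rate
                   + (config.mixing_rate - config.stagnation_rate) * intrusion)
    rate_s = config.surface_relax * (1 - w_dn) + deep_rate_s * w_dn
    state_down.salinity += rate_s * (s_target_dn - state_down.salinity)
    state_down.oxygen += config.surface_relax * cache.v_dn[doy] * (config.surface_oxygen - state_down.oxygen)
    state_down.oxygen += (config.mixing_rate * intrusion * w_dn
                          * (o_del - state_down.oxygen))

    # oxygen consumption everywhere, temperature update, noise, clamping.
    # Noise is vertically coherent (one surface and one deep draw per
    # variable) -- mesoscale variability moves water columns, it does not
    # decorrelate adjacent 3-m layers -- which also keeps the column
    # statically stable.
    for st, w in ((state_up, w_up), (state_down, w_dn)):
        st.temperature = t_prof.copy()
        st.oxygen -= _consumption(np.maximum(st.oxygen, 0.0), st.temperature, config)
        if config.noise_sd > 0 and rng is not None:
            es, eo = rng.normal(0.0, config.noise_sd, (2, 2))
            st.salinity += es[0] * (1 - w) + es[1] * w
            st.oxygen += eo[0] * (1 - w) + eo[1] * w
            st.temperature += rng.normal(0.0, 0.1 * config.noise_sd)
        np.maximum(st.salinity, 0.0, out=st.salinity)
        np.maximum(st.oxygen, 0.0, out=st.oxygen)
        convective_adjust(st)

    if upstream_deep_history is not None:
        upstream_deep_history.append((float(state_up.salinity[deep_up].mean()),
                                      float(state_up.oxygen[deep_up].mean())))
    return state_up, state_down


def simulate(config: SimulationConfig) -> tuple[ProfileSeries, ProfileSeries]:
    """Run the daily two-basin model; returns (upstream, downstream)
    ProfileSeries of length ``n_years * 365`` days.

    Identical config and seed give bit-identical output.
    """
    config.validate()
    if config.n_years < 2:
        raise ValueError("n_years must be >= 2 for any downstream statistics")
    rng = np.random.default_rng(config.seed)
    events = sample_inflow_events(config, rng)
    z = np.asarray(config.depth_grid, dtype=float)
    n_days = config.n_years * DAYS_PER_YEAR

    up = baseline_state(config, "upstream")
    down = baseline_state(config, "downstream")
    deep_up = z >= config.halocline_depth_upstream
    history: list[tuple[float, float]] = [
        (float(up.salinity[deep_up].mean()), float(up.oxygen[deep_up].mean()))]

    out = {b: {v: np.empty((n_days, z.size)) for v in ("salinity", "temperature", "oxygen")}
           for b in ("up", "down")}
    cache = _StepCache(config)
    for day in range(n_days):
        step_day(up, down, events, config, day, history, rng, cache)
        for key, st in (("up", up), ("down", down)):
            out[key]["salinity"][day] = st.salinity
            out[key]["temperature"][day] = st.temperature
            out[key]["oxygen"][day] = st.oxygen

    times = noleap_dates(config.start_year, config.n_years)
    meta = {"generator": "inflowcast.simulate", "seed": config.seed,
            "n_years": config.n_years, "advection_lag_days": config.advection_lag,
            "event_rate_per_winter": config.event_rate_per_winter}
    result = []
    for key, region in (("up", "upstream"), ("down", "downstream")):
        ds = xr.Dataset(
            {v: (("time", "depth"), out[key][v]) for v in ("salinity", "temperature", "oxygen")},
            coords={"time": times, "depth": z}, attrs=meta)
        result.append(ProfileSeries(ds, region=region))
    return result[0], result[1]


# ---------------------------------------------------------------------------
# calibration generator with a known linear coupling
# ---------------------------------------------------------------------------

def simulate_linear_coupling(n_years: int = 45, slope: float = 0.7,
                             intercept: float = -2.0, noise_sd: float = 1.3,
                             seed: int = 0, start_year: int = 1971,
                             s_mean: float = 13.0, s_sd: float = 1.5,
                             depth_grid: np.ndarray | None = None
                             ) -> tuple[ProfileSeries, ProfileSeries, float]:
    """Two-basin *monthly* profile series with a prescribed linear relation
    between the winter salinity indicator and April deep oxygen.

    Per year y the January 33 m upstream salinity S_y is drawn normal
    (``s_mean``, ``s_sd``) and is the Jan-Mar maximum by construction; the
    downstream April oxygen over 50-95 m is ``intercept + slope*S_y`` plus
    normal noise.  Because the true slope is known, end-to-end parameter
    recovery of the reduction + regression pipeline can be verified.
    Returns (upstream, downstream, true_slope).
    """
    rng = np.random.default_rng(seed)
    z = np.arange(1.5, 100.0, 3.0) if depth_grid is None else np.asarray(depth_grid, float)
    months = pd.DatetimeIndex(
        [pd.Timestamp(year=y, month=m, day=1)
         for y in range(start_year, start_year + n_years) for m in range(1, 13)])
    nt = months.size
    w = _sigmoid((z - 60.0) / 6.0)

    sal_up = np.tile(7.5 + 6.5 * _sigmoid((z - 30.0) / 6.0), (nt, 1))
    sal_dn = np.tile(7.5 + 6.5 * w, (nt, 1))
    temp = np.tile(8.0 - 3.0 * w, (nt, 1))
    oxy_up = np.full((nt, z.size), 7.0)
    oxy_dn = np.tile(8.0 - 3.0 * w, (nt, 1))

    s_year = rng.normal(s_mean, s_sd, n_years)
    eps = rng.normal(0.0, noise_sd, n_years)
    k33 = int(np.argmin(np.abs(z - 33.0)))
    deep = (z >= 50.0) & (z <= 95.0)
    for i in range(n_years):
        jan = i * 12
        sal_up[jan, k33] = s_year[i]
        sal_up[jan + 1, k33] = s_year[i] - 0.5   # Feb below the Jan maximum
        sal_up[jan + 2, k33] = s_year[i] - 1.0   # Mar
        oxy_dn[jan + 3, deep] = max(0.0, intercept + slope * s_year[i] + eps[i])

    result = []
    for region, sal, oxy in (("upstream", sal_up, oxy_up), ("downstream", sal_dn, oxy_dn)):
        ds = xr.Dataset({"salinity": (("time", "depth"), sal),
                         "temperature": (("time", "depth"), temp),
                         "oxygen": (("time", "depth"), oxy)},
                        coords={"time": months, "depth": z},
                        attrs={"generator": "inflowcast.simulate_linear_coupling",
                               "seed": seed, "true_slope": slope})
        result.append(ProfileSeries(ds, region=region))
    return result[0], result[1], slope
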