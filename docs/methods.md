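# Methods

This note documents the models and statistical procedures implemented in
`inflowcast`, the assumptions behind them, the parameters that matter, and
what the synthetic data can and cannot show.

## The indicator chain

The package operationalises one causal chain.  Major Baltic inflows carry
saline, oxygen-rich water through the Arkona Basin into the Bornholm Basin
deep water with a delay of a few weeks.  Winter salinity at 33 m in the
Arkona Basin therefore anticipates April oxygen in the Bornholm spawning
layers, and — because the seasonal oxygen budget of those layers is
essentially fixed by April — anticipates egg survival for the whole
spawning season.  The statistical stages are:

1. **Reduction.**  Daily profiles are averaged to calendar-month means per
   depth.  Scalar series are taken at a fixed depth (nearest grid level,
   ties to the shallower one), as unweighted means over a depth layer
   (thickness-weighted on the uniform 3-m grid), or by interpolation onto a
   density surface.
2. **Density and isopycnals.**  Density is the EOS-80 one-atmosphere
   polynomial (Millero & Poisson 1981) evaluated from practical salinity
   and temperature; at these depths (≤ 100 m) the pressure correction and
   the potential/in-situ distinction are ignored.  The egg buoyancy levels
   1009/1011/1013 kg m⁻³ correspond to S ≈ 11/13.5/16 at 5 °C, which the
   implementation reproduces within ±0.5 kg m⁻³.  A variable is carried
   onto a level by locating the *shallowest* crossing of the target density
   (eggs rising from below settle at their first neutral-buoyancy depth)
   with linear interpolation between bracketing grid depths; months whose
   maximum density stays below the target are flagged "level absent".
3. **Prewhitening.**  For each (month, depth) the interannual series is
   linearly detrended, then reduced to the residuals of the lowest-order
   AR(p) fit (conditional least squares, p ≤ 5) whose residuals pass both a
   Ljung-Box test (p ≥ 0.05 at min(10, n/5) lags, model degrees of freedom
   subtracted) and a Durbin-Watson check (DW ∈ [1.5, 2.5]).  Order 0 means
   the detrended series was already white.  The thresholds are conventional
   rather than canonical and are exposed as arguments.
4. **Cross-correlation.**  Pearson r between prewhitened residual pairs,
   two-sided t-test on n−2 degrees of freedom, star coding at
   0.05/0.01/0.001.  Pairs are aligned on the *winter season*: salinity in
   Nov/Dec of year y pairs with oxygen in the first months of year y+1
   when the lag crosses the New Year.  The grid spans salinity months
   Nov–Mar, lags 0–2 months, and all downstream depths below 50 m; failed
   cells (short series, absent levels) stay NaN without aborting the grid.
5. **Egg survival.**  y = 100·(1 − e^(−a·x))^b with a = 0.71 (ml l⁻¹)⁻¹ and
   b = 11.63; strictly increasing, sigmoid, y ∈ [0, 100).  The closed-form
   half-survival point −ln(1 − 2^(−1/b))/a ≈ 4.0 ml l⁻¹.  Survival is
   reported in percent but regressed on the 0–1 probability scale, which is
   the scale on which the published coefficient magnitudes live.
6. **Seasonal persistence.**  The "integral" of May–August oxygen is the
   sum of the four monthly means (ml l⁻¹·month); this matches the magnitude
   of the published regression tables, where an April value near 7 ml l⁻¹
   maps to an integral near 27.  The integral is regressed on the April
   value per level.  Years in which a level is absent in April, or
   disappears in June–August after being present, are excluded; ties
   (August = April) do not count as declines.
7. **Indicator and validation.**  S_max = max of the Jan–Mar monthly means
   at 33 m, paired with same-calendar-year April responses.  OLS with full
   diagnostics; leave-one-out cross-validation refits the line n times by
   closed-form normal equations, recording per fold the training R²,
   training MSE and the squared error on the held-out point.  The error
   metric is squared error by default (so that the mean LOOCV test error is
   commensurable with the squared residual SE — the consistency pattern the
   published tables show) and can be switched to RMSE or MAE; the reported
   "95% interval" is the half-width of the 2.5–97.5 percentile band of
   fold-wise errors, which tolerates the heavy right skew of single-point
   squared errors.
8. **Forecast.**  Point prediction intercept + slope·S_max.  The default
   uncertainty is the t-based standard error of the mean response at S_max
   at the 68% level; when a fit is constructed from published coefficients
   alone (no training data), no interval is reported rather than inventing
   one.  Survival forecasts are clamped to [0, 1] with the raw value
   retained.  Salinity beyond the training range plus 10% of its width
   raises a recorded warning, not an error — the 2014/15 inflow produced
   exactly such out-of-regime values.

## The synthetic two-basin generator

The generator is a deliberately minimal daily surrogate for the two-basin
system, built so that every statistical property the pipeline relies on is
*mechanistically present* rather than painted on:

* **Calendar.**  Fixed 365-day years (no leap days), standard month
  lengths; timestamps are real dates with Feb 29 never emitted.  Monthly
  statistics are insensitive to this simplification.
* **Grid.**  3-m layer midpoints 1.5–98.5 m (33 levels).
* **Temperature.**  Deterministic seasonal sinusoid per depth — 8 ± 7 °C at
  the surface thinning to 5 ± 0.5 °C at depth, maximum in late July — plus
  a small noise term tied to the noise amplitude.  Temperature only matters
  through consumption and density.
* **Inflow events.**  Counts are Poisson per Nov–Mar winter (default mean
  1), start days uniform over that 151-day window (placing ~61% of events
  in Nov–Jan), durations exponential around 20 days (min 3), salinity
  amplitudes normal(3.5, 1.5) psu clipped at 0.2, source oxygen 8 ml l⁻¹.
* **Upstream basin.**  Salinity relaxes to a sigmoidal baseline (7.5 psu
  surface, 15 psu below a 30-m halocline) at 0.02 d⁻¹; during an event the
  sub-halocline target is raised by the event amplitude and the relaxation
  accelerates to 0.15 d⁻¹; deep oxygen is driven toward the source value at
  the same rate.
* **Downstream basin.**  Deep layers (below a 60-m halocline) relax toward
  the upstream sub-halocline mean delayed by 21 days, expressed as an
  *anomaly* about the shared baseline so that the resting state is an exact
  fixed point.  Renewal rides on dense gravity currents: the relaxation
  rate ramps from a slow stagnation value (0.002 d⁻¹, salinity only) to the
  full mixing rate (0.1 d⁻¹) as the delayed water's bottom salinity excess
  grows to 1 psu, and deep *oxygen* is renewed only through this intrusion
  term — during stagnation deep oxygen can only decline.  A consequence
  matching observed behaviour: a minor inflow arriving after a major one
  fails to ventilate.
* **Ventilation.**  Surface oxygen relaxes to 8 ml l⁻¹ at 0.1 d⁻¹ above a
  seasonally varying mixing depth: 40 m in summer (thermocline limit)
  deepening to 58 m — the halocline top — in mid-February.  This is what
  keeps the 1009 kg m⁻³ habitat renewed every winter while the 1013 level
  depends entirely on inflows, and it makes the April→August oxygen
  decline the dominant seasonal pattern.
* **Consumption.**  r = r_ref · Q10^((T−5)/10) · O₂/(O₂ + K) with r_ref =
  0.8 ml l⁻¹ month⁻¹, Q10 = 2, K = 1 ml l⁻¹: faster when warm, vanishing
  as oxygen runs out.
* **Stability.**  After each step a convective adjustment pools statically
  unstable runs of layers (monotone pooling on density, averaging S, T and
  O over the run) — winter cooling below the temperature of maximum
  density genuinely convects, forming the winter mixed layer.
* **Noise.**  Daily additive noise is vertically coherent (one surface and
  one deep draw per variable per basin): mesoscale variability displaces
  water columns rather than decorrelating adjacent 3-m layers, and
  column-coherent noise does not fight the stratification invariant.

Under the default configuration a 45-year run produces: deep-water April
oxygen spanning ~0.1–8 ml l⁻¹ with inflow and stagnation years; the 1013
level absent in roughly a quarter to a half of Aprils and occasionally
disappearing mid-season; April→August declines in ~87% of year-level
cases; and a cross-correlation grid peaking at a one-month lag (21-day
advection plus the ~10-day mixing response).

A second generator, `simulate_linear_coupling`, embeds a *prescribed*
linear relation between the January 33-m salinity and April 50–95 m oxygen
into monthly profile series (salinity draws N(13, 1.5) psu; oxygen noise
SD 1.3 ml l⁻¹; oxygen floored at 0, far from the working range).  Because
its true slope is known, it supports exact end-to-end parameter-recovery
and CI-coverage checks of the reduction + regression pipeline.

### What the generator does not emulate

No hydrodynamics, wind forcing, sea ice, or Baltic Sea Index; no
eutrophication trend in consumption; no baroclinic summer inflows; no
attempt to reproduce the magnitudes of any particular hindcast.  Passing
tests therefore demonstrate that the *statistical machinery* recovers
structure that is mechanistically present in data of this shape — they do
not validate the published regression coefficients, which derive from a
45-year ocean-model hindcast that is out of scope.  Published coefficient
values enter only the worked-forecast checks, where they are inputs, not
targets of estimation.

## Numerical choices and degenerate inputs

* Nearest-depth ties resolve to the shallower level; multiple density
  crossings resolve to the shallowest.
* Monthly means use whatever days a month has; a month is masked only when
  empty.  Masked cells propagate; grid cells whose series fail a
  precondition become NaN cells rather than aborting a grid.
* AR fits are conditional least squares via `numpy.linalg.lstsq`; the
  Ljung-Box lag count never falls below the fitted order + 1.
* Zero-variance series are rejected by the serial-dependence tests and
  produce masked correlation cells.
* LOOCV intervals are percentile half-widths, not ±t·SE, because fold-wise
  squared errors are strongly skewed.
* Report tables round to 4 significant digits; machine-readable outputs
  (TSV, fit artifacts) keep full precision, and the fit artifact stores the
  training data so a reloaded fit reproduces fitted values exactly.

## Problem sizes

The test suite works at the scale the methods are meant for: 40–45-year
series (the length of an operational hindcast), 33 depth levels, 200
replicate seeds for coverage calibration, 20 seeds for lag recovery, 1000
replicates for Ljung-Box calibration.  The complete suite runs in about
two minutes on one CPU.

## Known limitations

* The two-basin surrogate has one advective pathway and one delay; the
  real system has wind-driven return flows and interleaving at neutral
  buoyancy that this model cannot express.
* EOS-80 at 0 dbar is used throughout; TEOS-10 absolute-salinity density
  would shift the isopycnal depths by a few decimetres but is not wired in.
* The Ljung-Box/Durbin-Watson acceptance thresholds in prewhitening are
  conventions; different choices change selected AR orders on marginal
  series.
* Survival forecasting inherits every assumption of the dose–response
  curve: no temperature or salinity effect on egg survival, no predation,
  no egg-quality variation within an age class.
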