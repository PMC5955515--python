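"""The winter-salinity early-warning indicator, end to end.

The Jan-Mar maximum of monthly mean salinity at 33 m in the upstream
basin predicts April oxygen in the downstream 70-95 m egg layer and the
April egg-survival probability on the buoyancy levels.  Fits are
validated by leave-one-out cross-validation; the fitted relation is then
applied to a January salinity observation, and for comparison the
published 70-95 m relationship is applied to the January 2015 value of
14.42 psu.
"""

from inflowcast import (RegressionFit, SimulationConfig, build_indicator_dataset,
                        fit_indicator, forecast, monthly_mean, simulate)

upstream, downstream = simulate(SimulationConfig(n_years=45, seed=3))
dataset = build_indicator_dataset(monthly_mean(upstream), monthly_mean(downstream))
print(f"indicator dataset: {len(dataset)} years, "
      f"s_max {dataset.s_max.min():.1f}-{dataset.s_max.max():.1f} psu")

fit, cv = fit_indicator(dataset, "oxy_70_95")
print(f"\n70-95 m April oxygen ~ winter salinity: slope {fit.slope:.3f} "
      f"(p {fit.p_slope:.1e}), adj R2 {fit.adj_r2:.2f}, "
      f"residual SE {fit.resid_se:.2f}")
print(f"LOOCV: mean test error {cv.mean_test_error:.2f} "
      f"(residual SE^2 = {fit.resid_se ** 2:.2f})")

salinity = 14.42
fc = forecast(fit, salinity, level=0.68)
print(f"\nforecast at S = {salinity} psu: April oxygen "
      f"{fc.point:.2f} +/- {fc.half_width:.2f} ml/l (68% mean-response)")
if fc.extrapolation_warning:
    print(f"  note: {fc.extrapolation_warning}")

published = RegressionFit(intercept=-3.8837, slope=0.7114, response="oxy_70_95")
fc_pub = forecast(published, salinity)
print(f"published 70-95 m relationship at S = {salinity} psu: "
      f"{fc_pub.point:.2f} ml/l")
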