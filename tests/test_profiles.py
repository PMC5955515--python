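"""Profile container, I/O, reductions, density and isopycnal interpolation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from inflowcast import (DensityLevel, DepthLayer, ProfileSeries, density_eos,
                        depth_level_series, isopycnal_series, layer_mean_series,
                        level_absence_report, monthly_mean, read_profiles,
                        write_profiles)
from inflowcast.profiles import MonthlySeries


class TestIO:
    def test_toy_table(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("date,depth_m,salinity_psu,temperature_c,oxygen_ml_l\n"
                     "2000-01-15,33,12.5,4.0,6.0\n"
                     "2000-01-15,45,14.0,5.0,3.0\n")
        ps = read_profiles(p)
        assert ps.times.size == 1 and ps.depths.tolist() == [33.0, 45.0]
        assert ps.data["salinity"].values.tolist() == [[12.5, 14.0]]

    def test_roundtrip(self, tmp_path, make_profile_series):
        rng = np.random.default_rng(0)
        ps = make_profile_series(
            pd.date_range("2001-01-01", periods=10), [10.5, 13.5, 16.5],
            salinity=rng.uniform(7, 17, (10, 3)),
            temperature=rng.uniform(2, 15, (10, 3)),
            oxygen=rng.uniform(0, 9, (10, 3)))
        f = tmp_path / "rt.csv"
        write_profiles(ps, f)
        back = read_profiles(f)
        for v in ("salinity", "temperature", "oxygen"):
            np.testing.assert_allclose(back.data[v].values, ps.data[v].values)
        np.testing.assert_allclose(back.depths, ps.depths)

    def test_unparseable_cell_masked(self, tmp_path):
        p = tmp_path / "na.csv"
        p.write_text("date,depth_m,salinity_psu,temperature_c,oxygen_ml_l\n"
                     "2000-01-15,33,12.5,4.0,NA\n"
                     "2000-01-15,45,14.0,5.0,3.0\n")
        ps = read_profiles(p)
        oxy = ps.data["oxygen"].values
        assert np.isnan(oxy[0, 0]) and oxy[0, 1] == 3.0
        assert ps.data["salinity"].values[0, 0] == 12.5

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("date,depth_m,salinity_psu,temperature_c\n2000-01-15,33,12,4\n")
        with pytest.raises(ValueError, match="oxygen_ml_l"):
            read_profiles(p)

    def test_non_monotone_depth_rejected(self):
        ds = xr.Dataset({"oxygen": (("time", "depth"), np.ones((1, 2)))},
                        coords={"time": pd.DatetimeIndex(["2000-01-01"]),
                                "depth": [40.0, 30.0]})
        with pytest.raises(ValueError, match="depth"):
            ProfileSeries(ds)


class TestMonthlyMean:
    def test_constant_january(self, make_profile_series):
        ps = make_profile_series(pd.date_range("2000-01-01", "2000-01-31"), [10.0],
                                 oxygen=7.0)
        out = monthly_mean(ps)
        assert out.data["oxygen"].values[0, 0] == 7.0

    def test_arithmetic_mean_of_days(self, make_profile_series):
        vals = np.arange(1.0, 32.0)[:, None]
        ps = make_profile_series(pd.date_range("2001-01-01", "2001-01-31"), [10.0],
                                 oxygen=vals)
        out = monthly_mean(ps)
        assert out.data["oxygen"].values[0, 0] == 16.0

    def test_fully_masked_month_stays_masked(self, make_profile_series):
        oxy = np.full((59, 1), 5.0)
        oxy[31:, 0] = np.nan  # February entirely missing
        ps = make_profile_series(pd.date_range("2001-01-01", periods=59), [10.0],
                                 oxygen=oxy)
        out = monthly_mean(ps)
        assert out.data["oxygen"].values[0, 0] == 5.0
        assert np.isnan(out.data["oxygen"].values[1, 0])

    def test_empty_rejected(self, make_profile_series):
        ps = make_profile_series(pd.date_range("2001-01-01", periods=3), [10.0])
        empty = ProfileSeries.__new__(ProfileSeries)
        empty.data = ps.data.isel(time=[])
        empty.region = ""
        with pytest.raises(ValueError, match="empty"):
            monthly_mean(empty)

    def test_constant_series_invariant(self, make_profile_series):
        ps = make_profile_series(pd.date_range("2002-01-01", periods=365),
                                 [5.0, 15.0], salinity=9.25)
        out = monthly_mean(ps)
        assert np.all(out.data["salinity"].values == 9.25)


class TestDepthAndLayerSeries:
    def test_nearest_tie_prefers_shallower(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")], [31.5, 34.5],
                                 salinity=[[11.0, 13.0]])
        ms = depth_level_series(ps, 33.0, "salinity")
        assert ms.provenance["grid_depth_m"] == 31.5
        assert ms.value(2000, 1) == 11.0

    def test_exact_grid_hit(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")], [30.0, 33.0],
                                 salinity=[[10.0, 12.0]])
        assert depth_level_series(ps, 33.0, "salinity").value(2000, 1) == 12.0

    def test_out_of_span_rejected(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")], [10.0, 100.0])
        with pytest.raises(ValueError, match="outside grid span"):
            depth_level_series(ps, 200.0, "oxygen")

    def test_layer_mean_constant(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")],
                                 np.arange(70.5, 95.0, 3.0), oxygen=5.0)
        ms = layer_mean_series(ps, DepthLayer(70, 95), "oxygen")
        assert ms.value(2000, 1) == 5.0

    def test_layer_mean_two_depths(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")], [72.0, 75.0],
                                 oxygen=[[4.0, 6.0]])
        assert layer_mean_series(ps, DepthLayer(70, 95), "oxygen").value(2000, 1) == 5.0

    def test_layer_outside_grid_rejected(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-01-01")], [10.0, 90.0])
        with pytest.raises(ValueError, match="no grid depth"):
            layer_mean_series(ps, DepthLayer(200, 300), "oxygen")

    def test_layer_mean_invariant_to_row_order(self, tmp_path):
        rows = ["date,depth_m,salinity_psu,temperature_c,oxygen_ml_l"]
        rng = np.random.default_rng(1)
        entries = [(f"2000-0{m}-10", d, 10.0, 5.0, rng.uniform(2, 8))
                   for m in (1, 2) for d in (72.0, 78.0, 84.0)]
        fwd = tmp_path / "fwd.csv"
        rev = tmp_path / "rev.csv"
        fwd.write_text("\n".join(rows + [",".join(map(str, e)) for e in entries]))
        rev.write_text("\n".join(rows + [",".join(map(str, e)) for e in entries[::-1]]))
        a = layer_mean_series(read_profiles(fwd), DepthLayer(70, 95), "oxygen")
        b = layer_mean_series(read_profiles(rev), DepthLayer(70, 95), "oxygen")
        pd.testing.assert_series_equal(a.data, b.data)


class TestDensity:
    @pytest.mark.parametrize("salinity,expected", [(11.0, 1009.0), (13.5, 1011.0),
                                                   (16.0, 1013.0)])
    def test_egg_buoyancy_correspondences(self, salinity, expected):
        """Salinities 11/13.5/16 at 5 degC sit on the 1009/1011/1013 kg/m3
        egg neutral-buoyancy surfaces."""
        assert density_eos(salinity, 5.0) == pytest.approx(expected, abs=0.5)

    def test_freshwater_density_maximum(self):
        assert density_eos(0.0, 3.98) == pytest.approx(1000.0, abs=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            density_eos(-1.0, 5.0)
        with pytest.raises(ValueError):
            density_eos(10.0, 45.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.0, 35.9), st.floats(0.0, 20.0))
    def test_strictly_increasing_in_salinity(self, s, t):
        assert density_eos(s + 0.1, t) > density_eos(s, t)


class TestIsopycnal:
    def test_linear_profile_closed_form(self, make_profile_series):
        # rho 1008 @50 m and 1010 @60 m bracket the 1009 target at 55 m;
        # oxygen 6 -> 4 over the same span interpolates to 5.0
        s_1008 = 10.117  # S giving rho=1008 at 5 degC (solved numerically)
        s_1010 = 12.648
        ps = make_profile_series([pd.Timestamp("2000-04-01")], [50.0, 60.0],
                                 salinity=[[s_1008, s_1010]], temperature=5.0,
                                 oxygen=[[6.0, 4.0]])
        ms = isopycnal_series(ps, DensityLevel(1009.0), "oxygen")
        assert ms.value(2000, 4) == pytest.approx(5.0, abs=0.01)

    def test_target_never_reached_flagged_absent(self, make_profile_series):
        ps = make_profile_series([pd.Timestamp("2000-04-01")], [50.0, 60.0],
                                 salinity=[[10.0, 15.0]], temperature=5.0)
        ms = isopycnal_series(ps, DensityLevel(1013.0), "oxygen")
        assert np.isnan(ms.value(2000, 4))
        assert ms.is_absent(2000, 4)

    def test_exact_grid_density_returns_cell_value(self, make_profile_series):
        s_exact = 11.382  # rho(S, 5) == 1009 to ~1e-3
        ps = make_profile_series([pd.Timestamp("2000-04-01")], [50.0, 60.0],
                                 salinity=[[s_exact, 16.0]], temperature=5.0,
                                 oxygen=[[6.5, 2.0]])
        ms = isopycnal_series(ps, DensityLevel(density_eos(s_exact, 5.0)), "oxygen")
        assert ms.value(2000, 4) == 6.5

    def test_matches_closed_form_on_analytic_profile(self, make_profile_series):
        # salinity linear in depth at constant T: compare against direct
        # inversion of the (locally linear) density profile
        depths = np.arange(40.0, 100.0, 3.0)
        sal = 8.0 + 0.12 * (depths - 40.0)
        ps = make_profile_series([pd.Timestamp("2000-04-01")], depths,
                                 salinity=sal[None, :], temperature=5.0,
                                 oxygen=(9.0 - 0.08 * depths)[None, :])
        target = 1010.0
        rho = density_eos(sal, np.full_like(sal, 5.0))
        k = np.searchsorted(rho, target)
        f = (target - rho[k - 1]) / (rho[k] - rho[k - 1])
        expected = (9.0 - 0.08 * depths[k - 1]) + f * (-0.08 * 3.0)
        ms = isopycnal_series(ps, DensityLevel(target), "oxygen")
        assert ms.value(2000, 4) == pytest.approx(expected, abs=1e-12)


class TestLevelAbsence:
    def _iso(self, present_months):
        idx = pd.MultiIndex.from_product([[2000], [4, 5, 6, 7, 8]],
                                         names=["year", "month"])
        vals = [5.0 if m in present_months else np.nan for _, m in idx]
        absent = [m not in present_months for _, m in idx]
        return MonthlySeries(data=pd.Series(vals, index=idx), units="ml/l",
                             absent=pd.Series(absent, index=idx))

    def test_present_all_season(self):
        rep = level_absence_report(self._iso({4, 5, 6, 7, 8}))
        assert rep.loc[2000, "exists_in_april"]
        assert not rep.loc[2000, "disappeared_during_season"]

    def test_disappears_in_july(self):
        rep = level_absence_report(self._iso({4, 5}))
        assert rep.loc[2000, "exists_in_april"]
        assert rep.loc[2000, "disappeared_during_season"]

    def test_absent_in_april(self):
        rep = level_absence_report(self._iso({5, 6, 7, 8}))
        assert not rep.loc[2000, "exists_in_april"]
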