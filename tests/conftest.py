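import numpy as np
import pandas as pd
import pytest
import xarray as xr

from inflowcast import ProfileSeries, SimulationConfig, monthly_mean, simulate


@pytest.fixture(scope="session")
def default_run():
    """One 45-year default-configuration simulation, monthly-reduced;
    shared across tests that only read it."""
    up, down = simulate(SimulationConfig(n_years=45, seed=3))
    return monthly_mean(up), monthly_mean(down)


@pytest.fixture()
def make_profile_series():
    """Factory for small synthetic ProfileSeries grids."""

    def _make(times, depths, salinity=None, temperature=None, oxygen=None,
              region="test"):
        times = pd.DatetimeIndex(times)
        depths = np.asarray(depths, dtype=float)
        shape = (times.size, depths.size)

        def _field(v, fill):
            if v is None:
                return np.full(shape, fill)
            return np.broadcast_to(np.asarray(v, dtype=float), shape).copy()

        ds = xr.Dataset(
            {"salinity": (("time", "depth"), _field(salinity, 8.0)),
             "temperature": (("time", "depth"), _field(temperature, 5.0)),
             "oxygen": (("time", "depth"), _field(oxygen, 6.0))},
            coords={"time": times, "depth": depths})
        return ProfileSeries(ds, region=region)

    return _make


@pytest.fixture()
def monthly_times():
    """Month-start timestamps covering whole years."""

    def _make(start_year, n_years):
        return pd.DatetimeIndex([pd.Timestamp(y, m, 1)
                                 for y in range(start_year, start_year + n_years)
                                 for m in range(1, 13)])

    return _make
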