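import numpy as np
import pytest

from bloomtrace import FieldSeries, Grid, ScenarioConfig, generate_scenario


@pytest.fixture
def small_grid():
    """7x6 grid with a land rim plus one interior land node."""
    lon = np.linspace(13.0, 14.0, 6)
    lat = np.linspace(55.0, 55.5, 7)
    land = np.zeros((7, 6), dtype=bool)
    land[0, :] = land[-1, :] = True
    land[:, 0] = land[:, -1] = True
    land[3, 2] = True
    return Grid(lon=lon, lat=lat, land_mask=land)


@pytest.fixture
def all_wet_grid():
    lon = np.linspace(13.0, 15.0, 9)
    lat = np.linspace(55.0, 56.0, 8)
    return Grid(lon=lon, lat=lat, land_mask=np.zeros((8, 9), dtype=bool))


def constant_series(grid, value, name="f", times=(0.0, 10800.0, 21600.0)):
    times = np.asarray(times, dtype=float)
    vals = np.full((times.size,) + grid.shape, float(value))
    return FieldSeries(grid=grid, times=times, values=vals, name=name)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small but complete scenario shared by integration-style tests."""
    cfg = ScenarioConfig(n_lon=40, n_lat=30, duration=5 * 86400.0,
                         n_records_per_month=200, rng_seed=7)
    return generate_scenario(cfg)
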