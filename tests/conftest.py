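import numpy as np
import pandas as pd
import pytest

from presstrack.io import GriddedAtmosphere, LoggerSeries
from presstrack.world import WorldConfig, default_truth, generate_world, simulate_bird
import xarray as xr


@pytest.fixture(scope="session")
def small_world_cfg() -> WorldConfig:
    """Compact world for fast unit tests (study-scale runs use the defaults)."""
    return WorldConfig(n_lat=9, n_lon=9, span_days=30, seed=7)


@pytest.fixture(scope="session")
def small_world(small_world_cfg):
    return generate_world(small_world_cfg)


@pytest.fixture(scope="session")
def small_track(small_world, small_world_cfg):
    cfg = small_world_cfg
    world = small_world
    truth = default_truth(world, cfg)
    series, timeline = simulate_bird(world, truth, cfg=cfg)
    return world, truth, series, timeline


def flat_atmosphere(
    n_lat=5,
    n_lon=5,
    hours=48,
    p0=1013.25,
    start="2021-06-01",
    lat_north=46.0,
    lon_west=8.0,
    res=0.25,
    elev_min=0.0,
    elev_max=300.0,
    sp=None,
) -> GriddedAtmosphere:
    """Hand-built atmosphere with controllable surface pressure."""
    times = pd.date_range(start, periods=hours, freq="h")
    lats = lat_north - np.arange(n_lat) * res
    lons = lon_west + np.arange(n_lon) * res
    if sp is None:
        sp = np.full((hours, n_lat, n_lon), p0)
    ds = xr.Dataset(
        {
            "sp": (("time", "lat", "lon"), np.asarray(sp, dtype=float)),
            "elev_min": (("lat", "lon"), np.full((n_lat, n_lon), elev_min)),
            "elev_max": (("lat", "lon"), np.full((n_lat, n_lon), elev_max)),
            "u": (("time", "lat", "lon"), np.zeros((hours, n_lat, n_lon))),
            "v": (("time", "lat", "lon"), np.zeros((hours, n_lat, n_lon))),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"sp_ref_elev_m": 0.0},
    )
    return GriddedAtmosphere(ds)


def logger_from_pressure(pressure, start="2021-06-01", dt_s=1800, light=None, bird_id="T1") -> LoggerSeries:
    ts = pd.date_range(start, periods=len(pressure), freq=pd.Timedelta(seconds=dt_s))
    return LoggerSeries(bird_id=bird_id, timestamps=ts, pressure=np.asarray(pressure, float), light=light)
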