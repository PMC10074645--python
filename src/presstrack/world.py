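"""Ground-truthed synthetic world: atmosphere, bird, logger readout.

The generator emulates the statistical structure the pipeline assumes:

* a gridded hourly **atmosphere** whose sea-level pressure is a smooth
  spatial gradient plus a spatially correlated AR(1) weather process
  (temporal persistence is what the pressure-matching step exploits; the
  spatial decorrelation is what makes it informative), with a smooth
  topography giving each cell an elevation range, and a smooth wind field;
* a **bird** occupying a sequence of stationary sites (cell + altitude) and
  flying between them at night along great circles with a
  climb/cruise/descent altitude profile;
* a **logger** that reads the pressure at the bird's altitude (barometric
  transform of the local sea-level pressure) plus Gaussian sensor noise, and
  a light channel driven by the solar zenith angle at the true position.

Everything is reproducible from the seed, and the truth record is exported
so each pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .barometry import altitude_to_pressure
from .geodesy import haversine_km
from .io import ActivityTimeline, GriddedAtmosphere, LoggerSeries
from .solar import solar_zenith

__all__ = [
    "WorldConfig",
    "TruthTrajectory",
    "generate_world",
    "default_truth",
    "simulate_bird",
    "score_recovery",
]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic atmosphere and observation process."""

    n_lat: int = 15
    n_lon: int = 15
    res_deg: float = 0.25
    lat_north: float = 46.0
    lon_west: float = 8.0
    start: str = "2020-09-01"
    span_days: int = 90
    seed: int = 0
    p0_hpa: float = 1013.25
    gradient_hpa_per_cell: float = 0.5  # eastward mean gradient
    ar_coef: float = 0.95
    innovation_sd_hpa: float = 1.0
    spatial_corr_cells: float = 3.0
    elev_max_m: float = 3000.0
    elev_halfwidth_m: float = 200.0
    wind_mean_u_ms: float = 1.0
    wind_mean_v_ms: float = -2.0
    wind_sd_ms: float = 1.5
    sensor_noise_sd_hpa: float = 0.5
    logger_dt_s: int = 1800

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValueError("ar_coef must be in [0, 1)")
        for name in ("innovation_sd_hpa", "wind_sd_ms", "sensor_noise_sd_hpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthTrajectory:
    """Ground truth: ordered stationary sites and the flights between them.

    ``sites`` columns: period_id, i, j, lat, lon, altitude_m, arrival,
    departure.  ``flights`` columns: flight_id, start, end, from/to indices,
    cruise_altitude_m.
    """

    sites: pd.DataFrame
    flights: pd.DataFrame


def _correlated_field_chol(n_lat: int, n_lon: int, corr_cells: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential spatial correlation over cells."""
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    cov = np.exp(-d2 / (2.0 * corr_cells**2))
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def generate_world(cfg: WorldConfig) -> GriddedAtmosphere:
    """Generate the hourly gridded atmosphere; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n_hours = cfg.span_days * 24
    lats = cfg.lat_north - np.arange(cfg.n_lat) * cfg.res_deg
    lons = cfg.lon_west + np.arange(cfg.n_lon) * cfg.res_deg
    times = pd.date_range(cfg.start, periods=n_hours, freq="h")

    k = cfg.n_lat * cfg.n_lon
    chol = _correlated_field_chol(cfg.n_lat, cfg.n_lon, cfg.spatial_corr_cells)
    sd = cfg.innovation_sd_hpa
    phi = cfg.ar_coef
    weather = np.empty((n_hours, k))
    if sd > 0:
        x = (chol @ rng.standard_normal(k)) * sd / np.sqrt(1.0 - phi**2)
        for t in range(n_hours):
            weather[t] = x
            x = phi * x + (chol @ rng.standard_normal(k)) * sd
    else:
        weather[:] = 0.0

    grad = cfg.gradient_hpa_per_cell * np.arange(cfg.n_lon)
    sp = cfg.p0_hpa + grad[None, None, :] + weather.reshape(n_hours, cfg.n_lat, cfg.n_lon)

    topo = gaussian_filter(rng.standard_normal((cfg.n_lat, cfg.n_lon)), sigma=3.0, mode="reflect")
    topo = topo - topo.min()
    if topo.max() > 0:
        topo = topo / topo.max()
    elev_center = topo * cfg.elev_max_m
    elev_min = np.maximum(elev_center - cfg.elev_halfwidth_m, 0.0)
    elev_max = elev_center + cfg.elev_halfwidth_m

    def smooth_field(mean: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((cfg.n_lat, cfg.n_lon)), sigma=3.0, mode="reflect")
        s = f.std()
        return mean + (f / s if s > 0 else f) * cfg.wind_sd_ms

    u = np.broadcast_to(smooth_field(cfg.wind_mean_u_ms), (n_hours, cfg.n_lat, cfg.n_lon)).copy()
    v = np.broadcast_to(smooth_field(cfg.wind_mean_v_ms), (n_hours, cfg.n_lat, cfg.n_lon)).copy()

    ds = xr.Dataset(
        {
            "sp": (("time", "lat", "lon"), sp),
            "elev_min": (("lat", "lon"), elev_min),
            "elev_max": (("lat", "lon"), elev_max),
            "u": (("time", "lat", "lon"), u),
            "v": (("time", "lat", "lon"), v),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"sp_ref_elev_m": 0.0, "res_deg": cfg.res_deg},
    )
    ds["sp"].attrs["units"] = "hPa"
    return GriddedAtmosphere(ds)


def default_truth(world: GriddedAtmosphere, cfg: WorldConfig, seed=None) -> TruthTrajectory:
    """Default migration scenario: 8 stationary periods moving north -> south.

    One breeding site, a coastal stop, one long stopover, four day-stops and
    a non-breeding site, linked by nocturnal flights whose durations follow
    from the site spacing at ground speeds inside 20-80 km/h.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_lat, n_lon = world.shape
    rows = [1, 5, 7, 9, 10, 11, 12, 13]
    cols = [7, 6, 8, 7, 6, 8, 7, 7]
    rows = [min(r, n_lat - 1) for r in rows]
    cols = [min(c, n_lon - 1) for c in cols]
    # clamping on small grids can collapse consecutive sites onto one cell;
    # nudge the column so every hop covers at least one cell
    for k in range(1, 8):
        if rows[k] == rows[k - 1] and cols[k] == cols[k - 1]:
            cols[k] = cols[k] - 1 if cols[k] > 0 else cols[k] + 1
    # breeding / coastal stop / long stopover / four day-stops, scaled to the
    # span (at the default 90 days: 18, 2, 12, 1, 1, 1, 1; the non-breeding
    # site holds the remainder)
    fractions = [0.20, 1 / 45, 2 / 15, 1 / 90, 1 / 90, 1 / 90, 1 / 90]
    stop_days = [max(int(round(f * cfg.span_days)), 1) for f in fractions]
    t0 = world.times[0]
    t_end = world.times[-1]

    sites, flights = [], []
    arrival = t0
    for k in range(8):
        i, j = rows[k], cols[k]
        lat, lon = world.cell_center(i, j)
        alt = float(0.5 * (world.elev_min[i, j] + world.elev_max[i, j]))
        if k < 7:
            dep_day = arrival.normalize() + pd.Timedelta(days=stop_days[k])
            departure = dep_day + pd.Timedelta(hours=20)  # nocturnal take-off
        else:
            departure = t_end
        sites.append(
            {
                "period_id": k + 1,
                "i": i,
                "j": j,
                "lat": lat,
                "lon": lon,
                "altitude_m": alt,
                "arrival": arrival,
                "departure": departure,
            }
        )
        if k < 7:
            lat2, lon2 = world.cell_center(rows[k + 1], cols[k + 1])
            dist = haversine_km(lat, lon, lat2, lon2)
            gs = rng.uniform(30.0, 60.0)
            dur_h = float(np.clip(dist / gs, 1.0, 11.0))
            # round to the logger step so labels align with samples
            step_h = cfg.logger_dt_s / 3600.0
            dur_h = max(round(dur_h / step_h) * step_h, step_h)
            end = departure + pd.Timedelta(hours=dur_h)
            cruise = float(max(alt, 0.0) + rng.uniform(1000.0, 2500.0))
            flights.append(
                {
                    "flight_id": k + 1,
                    "start": departure,
                    "end": end,
                    "from_i": i,
                    "from_j": j,
                    "to_i": rows[k + 1],
                    "to_j": cols[k + 1],
                    "cruise_altitude_m": cruise,
                }
            )
            arrival = end
    return TruthTrajectory(pd.DataFrame(sites), pd.DataFrame(flights))


def simulate_bird(
    world: GriddedAtmosphere,
    truth: TruthTrajectory,
    noise_sd: float | None = None,
    seed: int | None = None,
    cfg: WorldConfig | None = None,
    bird_id: str = "SYN01",
) -> tuple[LoggerSeries, ActivityTimeline]:
    """Logger readout of the truth trajectory (pressure + light channels).

    Stationary samples read the cell's sea-level pressure converted to the
    site altitude; flight samples follow a climb/cruise/descent profile along
    the great circle; Gaussian sensor noise on pressure.  Raises if a site
    altitude falls outside its cell's elevation bounds.
    """
    cfg = cfg or WorldConfig()
    noise_sd = cfg.sensor_noise_sd_hpa if noise_sd is None else noise_sd
    rng = np.random.default_rng(cfg.seed + 10_000 if seed is None else seed)
    for s in truth.sites.itertuples():
        if not (world.elev_min[s.i, s.j] <= s.altitude_m <= world.elev_max[s.i, s.j]):
            raise ValueError(
                f"period {s.period_id}: truth altitude {s.altitude_m:.0f} m outside "
                f"cell elevation bounds"
            )
    dt = pd.Timedelta(seconds=cfg.logger_dt_s)
    t_start = truth.sites["arrival"].iloc[0]
    t_stop = truth.sites["departure"].iloc[-1]
    ts = pd.date_range(t_start, t_stop, freq=dt, inclusive="left")
    t_atm = world.times.asi8.astype(float)
    t_num = ts.asi8.astype(float)

    pressure = np.empty(len(ts))
    lat_true = np.empty(len(ts))
    lon_true = np.empty(len(ts))
    alt_true = np.empty(len(ts))

    for s in truth.sites.itertuples():
        m = (ts >= s.arrival) & (ts < s.departure)
        sp = np.interp(t_num[m], t_atm, world.sp[:, s.i, s.j])
        pressure[m] = altitude_to_pressure(s.altitude_m, sp)
        lat_true[m], lon_true[m] = s.lat, s.lon
        alt_true[m] = s.altitude_m

    for f, s0, s1 in zip(
        truth.flights.itertuples(),
        truth.sites.iloc[:-1].itertuples(),
        truth.sites.iloc[1:].itertuples(),
    ):
        m = (ts >= f.start) & (ts < f.end)
        if not m.any():
            continue
        frac = (t_num[m] - f.start.value) / (f.end.value - f.start.value)
        la = s0.lat + frac * (s1.lat - s0.lat)
        lo = s0.lon + frac * (s1.lon - s0.lon)
        # trapezoidal altitude profile: 20% climb, 60% cruise, 20% descent
        alt = np.where(
            frac < 0.2,
            s0.altitude_m + (f.cruise_altitude_m - s0.altitude_m) * frac / 0.2,
            np.where(
                frac > 0.8,
                s1.altitude_m + (f.cruise_altitude_m - s1.altitude_m) * (1.0 - frac) / 0.2,
                f.cruise_altitude_m,
            ),
        )
        sp_here = np.empty(m.sum())
        for k, (lat_k, lon_k, t_k) in enumerate(zip(la, lo, t_num[m])):
            try:
                i, j = world.cell_index(lat_k, lon_k)
            except ValueError:
                i, j = s0.i, s0.j
            sp_here[k] = np.interp(t_k, t_atm, world.sp[:, i, j])
        pressure[m] = altitude_to_pressure(alt, sp_here)
        lat_true[m], lon_true[m], alt_true[m] = la, lo, alt

    pressure = pressure + rng.normal(0.0, noise_sd, len(ts))
    zen = solar_zenith(ts.to_numpy(), lat_true, lon_true)
    light = 100.0 / (1.0 + np.exp((np.asarray(zen) - 96.0) / 1.5))
    light = np.clip(light + rng.normal(0.0, 1.0, len(ts)), 0.0, None)

    series = LoggerSeries(bird_id=bird_id, timestamps=ts, pressure=pressure, light=light)

    bounds = []
    for k, s in enumerate(truth.sites.itertuples()):
        bounds.append(("stationary", s.arrival, s.departure))
        if k < len(truth.flights):
            f = truth.flights.iloc[k]
            bounds.append(("flight", f["start"], f["end"]))
    timeline = ActivityTimeline.from_bounds(bounds)
    return series, timeline


def score_recovery(result, truth: TruthTrajectory, world: GriddedAtmosphere, q: float = 0.99) -> dict:
    """Score a TrajectoryResults against the truth sites.

    Returns median great-circle error of the most-likely path (km), the
    fraction of periods whose MLP cell is within one cell (Chebyshev index
    distance) of the truth cell, and the fraction of periods whose truth
    cell lies inside the q credible region.
    """
    errors, within, covered = [], [], []
    for t, s in enumerate(truth.sites.itertuples()):
        ci, cj = result.mlp_cells[t]
        lat, lon = world.cell_center(ci, cj)
        errors.append(haversine_km(lat, lon, s.lat, s.lon))
        within.append(max(abs(ci - s.i), abs(cj - s.j)) <= 1)
        covered.append(bool(result.credible_region(t, q)[s.i, s.j]))
    return {
        "median_error_km": float(np.median(errors)),
        "pct_within_1_cell": 100.0 * float(np.mean(within)),
        "pct_truth_in_cr": 100.0 * float(np.mean(covered)),
        "n_periods": len(errors),
    }
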