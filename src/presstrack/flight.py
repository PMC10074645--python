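"""Per-flight performance metrics and regional summaries.

For each migratory flight the pressure recorded on the bird is converted to
an altitude series with the barometric transform against the hourly
reference pressure at the most-likely location (reduced to sea level, so
terrain elevation does not bias flight altitude).  Speed metrics come from
the great-circle displacement between the positions bracketing the flight:
ground speed, wind support (projection of the wind vector on the track
bearing) and airspeed (magnitude of ground minus wind vector).  Flights are
classified into five geographic categories by the great-circle midpoint of
the transition — by default a configurable latitude-band partition spanning
continental Europe, the Mediterranean, the Atlas, the Sahara and the Sahel —
and split into autumn and spring; summaries report n and mean +/- sd per
category and season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barometry import STANDARD, pressure_to_altitude, reduce_to_sea_level
from .geodesy import haversine_km, initial_bearing_deg, midpoint
from .io import GriddedAtmosphere, LoggerSeries
from .movement import KMH_PER_MS

__all__ = [
    "RegionPartition",
    "flight_altitude_series",
    "positive_altitudinal_change",
    "speed_and_wind",
    "classify_and_summarize",
    "flight_season",
]

METRICS = [
    "duration_h",
    "max_altitude_m",
    "mean_altitude_m",
    "positive_altitudinal_change_m",
    "climb_rate_m_per_h",
    "ground_speed_kmh",
    "wind_support_kmh",
    "airspeed_kmh",
    "distance_km",
]


@dataclass(frozen=True)
class RegionPartition:
    """Ordered latitude bands (name, lat_min, lat_max); first match wins.

    The defaults approximate the flyway of a central-European trans-Saharan
    migrant; real analyses should override with proper polygons.
    """

    bands: tuple = (
        ("europe", 43.0, 90.0),
        ("mediterranean", 37.0, 43.0),
        ("atlas", 30.0, 37.0),
        ("sahara", 18.0, 30.0),
        ("sahel", 10.0, 18.0),
    )

    def classify(self, lat: float, lon: float) -> str:
        for name, lo, hi in self.bands:
            if lo <= lat < hi:
                return name
        return "unclassified"


def flight_altitude_series(
    flight_series: LoggerSeries,
    atmosphere: GriddedAtmosphere,
    location: tuple[float, float],
    constants=STANDARD,
) -> np.ndarray:
    """Altitude (m a.s.l.) per flight sample against the hourly reference.

    The reference is the surface pressure of the cell containing
    ``location``, linearly interpolated in time to the logger stamps and
    reduced to sea level, so the recovered altitude tracks the bird and not
    the weather.
    """
    i, j = atmosphere.cell_index(*location)
    t_atm = atmosphere.times.asi8.astype(float)
    sp = atmosphere.sp[:, i, j]
    ref_elev = float(atmosphere.ds.attrs.get("sp_ref_elev_m", 0.0))
    sp_sl = reduce_to_sea_level(sp, ref_elev, constants=constants)
    t_log = flight_series.timestamps.asi8.astype(float)
    if t_log.min() < t_atm.min() or t_log.max() > t_atm.max():
        raise ValueError("flight extends beyond the atmosphere time span")
    p_ref = np.interp(t_log, t_atm, sp_sl)
    return pressure_to_altitude(flight_series.pressure, p_ref, z_ref=0.0, constants=constants)


def positive_altitudinal_change(altitudes: np.ndarray) -> float:
    """Sum of positive altitude increments over the flight, m."""
    alt = np.asarray(altitudes, dtype=float)
    if len(alt) < 2:
        raise ValueError("need at least two altitude samples")
    d = np.diff(alt)
    return float(d[d > 0].sum())


def speed_and_wind(
    from_latlon: tuple[float, float],
    to_latlon: tuple[float, float],
    duration_h: float,
    wind_uv_ms: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Ground speed, wind support, airspeed (km/h) and distance (km)."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    dist = haversine_km(*from_latlon, *to_latlon)
    gs = dist / duration_h
    bearing = np.radians(initial_bearing_deg(*from_latlon, *to_latlon))
    we, wn = wind_uv_ms[0] * KMH_PER_MS, wind_uv_ms[1] * KMH_PER_MS
    wind_support = we * np.sin(bearing) + wn * np.cos(bearing)
    ge, gn = gs * np.sin(bearing), gs * np.cos(bearing)
    airspeed = float(np.hypot(ge - we, gn - wn))
    return {
        "distance_km": float(dist),
        "ground_speed_kmh": float(gs),
        "wind_support_kmh": float(wind_support),
        "airspeed_kmh": airspeed,
    }


def flight_season(start: pd.Timestamp) -> str:
    """Autumn (Jul-Dec departures) vs spring (Jan-Jun)."""
    return "autumn" if pd.Timestamp(start).month >= 7 else "spring"


def classify_and_summarize(
    records: pd.DataFrame,
    partition: RegionPartition | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign category/season and build the per-category summary table.

    ``records`` needs columns ``from_lat, from_lon, to_lat, to_lon, start``
    plus any of the metric columns; returns (records with ``category`` and
    ``season``, summary with n / mean / sd per category x season and an
    overall row).  Single-flight groups report sd = 0 with ``sd_defined`` =
    False.
    """
    partition = partition or RegionPartition()
    rec = records.copy()
    mid = [
        midpoint(r.from_lat, r.from_lon, r.to_lat, r.to_lon)
        for r in rec.itertuples()
    ]
    rec["mid_lat"] = [m[0] for m in mid]
    rec["mid_lon"] = [m[1] for m in mid]
    rec["category"] = [partition.classify(la, lo) for la, lo in mid]
    if "season" not in rec.columns:
        rec["season"] = [flight_season(s) for s in rec["start"]]
    metrics = [m for m in METRICS if m in rec.columns]
    rows = []

    def _summarize(group: pd.DataFrame, category: str, season: str) -> dict:
        row = {"category": category, "season": season, "n": len(group)}
        for m in metrics:
            vals = group[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        row["sd_defined"] = len(group) > 1
        return row

    for (cat, season), g in rec.groupby(["category", "season"], sort=True):
        rows.append(_summarize(g, cat, season))
    rows.append(_summarize(rec, "overall", "all"))
    return rec, pd.DataFrame(rows)
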