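"""Domain containers and file I/O for logger, label and gridded-atmosphere data.

Conventions shared by the whole package:

* all timestamps are UTC;
* pressure is stored in hPa, altitude in m a.s.l., wind in m/s;
* the atmosphere grid is regular, hourly, with latitude rows ordered
  north -> south and cell (i, j) covering the half-open box
  ``[center - res/2, center + res/2)`` in both axes.

File formats:

* logger CSV: ``timestamp_utc,pressure_hpa,light,temperature_c`` (header
  required, ISO-8601 timestamps, light/temperature optional);
* label CSV: ``start_utc,end_utc,kind,id`` with kind in {stationary, flight};
* gridded atmosphere: NetCDF with dims (time, lat, lon) and variables
  ``sp`` (surface pressure, hPa or Pa), ``elev_min``, ``elev_max`` (m),
  ``u``, ``v`` (m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

PRESSURE_RANGE_HPA = (300.0, 1100.0)

__all__ = [
    "LoggerSeries",
    "ActivityTimeline",
    "GriddedAtmosphere",
    "SchemaError",
    "ValidationError",
    "read_logger",
    "write_logger",
    "read_labels",
    "write_labels",
    "read_atmosphere",
]


class SchemaError(ValueError):
    """A file does not have the documented columns/layout."""


class ValidationError(ValueError):
    """Contents violate a domain invariant."""


# ---------------------------------------------------------------------------
# LoggerSeries
# ---------------------------------------------------------------------------


@dataclass
class LoggerSeries:
    """Multi-sensor time series recorded on the bird.

    ``pressure_valid`` flags samples whose pressure lies inside the physically
    plausible range [300, 1100] hPa; out-of-range rows are kept but flagged so
    downstream steps can ignore them without silently changing the series
    length.
    """

    bird_id: str
    timestamps: pd.DatetimeIndex
    pressure: np.ndarray
    light: np.ndarray | None = None
    temperature: np.ndarray | None = None
    pressure_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.timestamps.tz is None:
            self.timestamps = self.timestamps.tz_localize("UTC")
        self.pressure = np.asarray(self.pressure, dtype=float)
        if len(self.timestamps) != len(self.pressure):
            raise ValidationError("timestamps and pressure must have equal length")
        if self.timestamps.has_duplicates:
            first = self.timestamps[self.timestamps.duplicated()][0]
            raise ValidationError(f"duplicate timestamp at {first}")
        if not self.timestamps.is_monotonic_increasing:
            diffs = np.diff(self.timestamps.asi8)
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"timestamps not strictly increasing: first offending row {row} "
                f"({self.timestamps[row]})"
            )
        if len(self.timestamps) >= 3:
            steps = np.diff(self.timestamps.asi8)
            if len(np.unique(steps)) > 1:
                raise ValidationError("sampling interval is not constant")
        if self.pressure_valid is None:
            lo, hi = PRESSURE_RANGE_HPA
            with np.errstate(invalid="ignore"):
                self.pressure_valid = (self.pressure >= lo) & (self.pressure <= hi)
        self.pressure_valid = np.asarray(self.pressure_valid, dtype=bool)
        for name in ("light", "temperature"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != len(self.timestamps):
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt_seconds(self) -> float:
        """Sampling interval in seconds."""
        if len(self.timestamps) < 2:
            raise ValueError("need at least two samples to define an interval")
        return float((self.timestamps[1] - self.timestamps[0]).total_seconds())

    def slice(self, start, end) -> "LoggerSeries":
        """Sub-series with timestamps in ``[start, end)``."""
        start = pd.Timestamp(start).tz_localize("UTC") if pd.Timestamp(start).tz is None else pd.Timestamp(start)
        end = pd.Timestamp(end).tz_localize("UTC") if pd.Timestamp(end).tz is None else pd.Timestamp(end)
        m = (self.timestamps >= start) & (self.timestamps < end)
        return LoggerSeries(
            bird_id=self.bird_id,
            timestamps=self.timestamps[m],
            pressure=self.pressure[m],
            light=None if self.light is None else self.light[m],
            temperature=None if self.temperature is None else self.temperature[m],
            pressure_valid=self.pressure_valid[m],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp_utc": self.timestamps, "pressure_hpa": self.pressure})
        if self.light is not None:
            df["light"] = self.light
        if self.temperature is not None:
            df["temperature_c"] = self.temperature
        return df


def read_logger(path, schema: dict | None = None, bird_id: str | None = None) -> LoggerSeries:
    """Read a logger CSV into a validated :class:`LoggerSeries`.

    ``schema`` maps canonical names (``timestamp``, ``pressure``, ``light``,
    ``temperature``) to the file's column names; by default the documented
    header ``timestamp_utc,pressure_hpa,light,temperature_c`` is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = {
        "timestamp": "timestamp_utc",
        "pressure": "pressure_hpa",
        "light": "light",
        "temperature": "temperature_c",
    }
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("timestamp", "pressure"):
        if mapping[key] not in df.columns:
            raise SchemaError(f"missing required column {mapping[key]!r} in {path.name}")
    ts = pd.to_datetime(df[mapping["timestamp"]], utc=True)
    kwargs = {}
    for key in ("light", "temperature"):
        col = mapping[key]
        if col in df.columns:
            kwargs[key] = df[col].to_numpy(dtype=float)
    return LoggerSeries(
        bird_id=bird_id or path.stem,
        timestamps=pd.DatetimeIndex(ts),
        pressure=df[mapping["pressure"]].to_numpy(dtype=float),
        **kwargs,
    )


def write_logger(series: LoggerSeries, path) -> None:
    df = series.to_frame()
    df["timestamp_utc"] = df["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    # %.17g keeps float64 bit-for-bit across the round trip
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ActivityTimeline
# ---------------------------------------------------------------------------


@dataclass
class ActivityTimeline:
    """Partition of a logger record into stationary periods and flights.

    ``segments`` has columns ``kind`` ("stationary"|"flight"), ``start``,
    ``end`` (UTC) and ``id`` (positive integer, numbered separately per kind
    and increasing in time).  Segments are contiguous: each segment's end is
    the next segment's start.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments.reset_index(drop=True).copy()
        if df.empty:
            raise ValidationError("no segments")
        for col in ("kind", "start", "end", "id"):
            if col not in df.columns:
                raise SchemaError(f"timeline missing column {col!r}")
        for col in ("start", "end"):
            ts = pd.to_datetime(df[col], utc=True)
            df[col] = ts
        bad = ~df["kind"].isin(["stationary", "flight"])
        if bad.any():
            raise ValidationError(f"unknown segment kind {df.loc[bad, 'kind'].iloc[0]!r}")
        if (df["end"] <= df["start"]).any():
            row = df[df["end"] <= df["start"]].iloc[0]
            raise ValidationError(f"segment with non-positive duration at {row['start']}")
        df = df.sort_values("start").reset_index(drop=True)
        gaps = df["start"].iloc[1:].to_numpy() != df["end"].iloc[:-1].to_numpy()
        if gaps.any():
            i = int(np.argmax(gaps))
            a, b = df["end"].iloc[i], df["start"].iloc[i + 1]
            if b < a:
                raise ValidationError(f"overlapping segments at {b}")
            raise ValidationError(f"unlabelled gap between {a} and {b}")
        for kind in ("stationary", "flight"):
            ids = df.loc[df["kind"] == kind, "id"].to_numpy()
            if len(ids) and (np.diff(ids) <= 0).any():
                raise ValidationError(f"{kind} ids not strictly increasing in time")
            if len(ids) and (ids <= 0).any():
                raise ValidationError("segment ids must be positive")
        self.segments = df

    @property
    def stationary(self) -> pd.DataFrame:
        return self.segments[self.segments["kind"] == "stationary"].reset_index(drop=True)

    @property
    def flights(self) -> pd.DataFrame:
        return self.segments[self.segments["kind"] == "flight"].reset_index(drop=True)

    @property
    def start(self) -> pd.Timestamp:
        return self.segments["start"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.segments["end"].iloc[-1]

    @staticmethod
    def from_bounds(bounds: list[tuple]) -> "ActivityTimeline":
        """Build from a list of (kind, start, end) triples, assigning ids."""
        rows = []
        counters = {"stationary": 0, "flight": 0}
        for kind, start, end in bounds:
            counters[kind] += 1
            rows.append({"kind": kind, "start": start, "end": end, "id": counters[kind]})
        return ActivityTimeline(pd.DataFrame(rows))


def read_labels(path, series: LoggerSeries | None = None) -> ActivityTimeline:
    """Read a label CSV into a validated :class:`ActivityTimeline`.

    If ``series`` is given, the labelled span must lie within the series'
    time range.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("start_utc", "end_utc", "kind", "id"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path.name}")
    if df.empty:
        raise ValidationError("no segments")
    tl = ActivityTimeline(
        pd.DataFrame(
            {
                "kind": df["kind"],
                "start": pd.to_datetime(df["start_utc"], utc=True),
                "end": pd.to_datetime(df["end_utc"], utc=True),
                "id": df["id"].astype(int),
            }
        )
    )
    if series is not None and len(series):
        if tl.start < series.timestamps[0] or tl.end > series.timestamps[-1] + pd.Timedelta(
            seconds=series.dt_seconds if len(series) > 1 else 0
        ):
            raise ValidationError("labels extend beyond the logger series")
    return tl


def write_labels(timeline: ActivityTimeline, path) -> None:
    df = timeline.segments.copy()
    out = pd.DataFrame(
        {
            "start_utc": df["start"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "end_utc": df["end"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "kind": df["kind"],
            "id": df["id"],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GriddedAtmosphere
# ---------------------------------------------------------------------------


@dataclass
class GriddedAtmosphere:
    """Hourly gridded surface pressure, elevation bounds and wind.

    Thin wrapper around an :class:`xarray.Dataset` with dims
    ``(time, lat, lon)`` and variables ``sp`` (hPa), ``elev_min``/``elev_max``
    (m a.s.l., per cell), ``u``/``v`` (m/s).  Latitude is ordered
    north -> south.  ``sp`` is referenced to sea level (``sp_ref_elev_m``
    attribute, default 0).
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        ds = self.ds
        for var in ("sp", "elev_min", "elev_max", "u", "v"):
            if var not in ds:
                raise SchemaError(f"atmosphere dataset missing variable {var!r}")
        lat = ds["lat"].values
        lon = ds["lon"].values
        if len(lat) > 1:
            dlat = np.diff(lat)
            if not np.allclose(dlat, dlat[0], atol=1e-9) or dlat[0] >= 0:
                if np.allclose(dlat, dlat[0], atol=1e-9) and dlat[0] > 0:
                    ds = ds.isel(lat=slice(None, None, -1))
                    lat = ds["lat"].values
                else:
                    raise ValidationError("latitude axis must be regular")
        if len(lon) > 1:
            dlon = np.diff(lon)
            if not np.allclose(dlon, dlon[0], atol=1e-9) or dlon[0] <= 0:
                raise ValidationError("longitude axis must be regular and increasing")
        times = pd.DatetimeIndex(ds["time"].values)
        if len(times) > 1:
            steps = np.unique(np.diff(times.asi8))
            if len(steps) != 1 or steps[0] != 3_600_000_000_000:
                raise ValidationError("time axis must be exactly hourly")
        sp = ds["sp"]
        if float(sp.max()) > 2000.0 or str(sp.attrs.get("units", "")).lower() in ("pa", "pascal"):
            ds = ds.assign(sp=sp / 100.0)
            ds["sp"].attrs["units"] = "hPa"
        if float(ds["sp"].min()) <= 0:
            raise ValidationError("surface pressure must be positive")
        if bool((ds["elev_min"] > ds["elev_max"]).any()):
            raise ValidationError("elev_min must be <= elev_max")
        self.ds = ds

    # -- grid geometry ------------------------------------------------------

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def res_deg(self) -> float:
        if len(self.lons) > 1:
            return float(self.lons[1] - self.lons[0])
        if len(self.lats) > 1:
            return float(abs(self.lats[1] - self.lats[0]))
        return float(self.ds.attrs.get("res_deg", 0.25))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    @property
    def times(self) -> pd.DatetimeIndex:
        idx = pd.DatetimeIndex(self.ds["time"].values)
        return idx.tz_localize("UTC") if idx.tz is None else idx

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Unique cell whose half-open box [center-res/2, center+res/2) contains the point."""
        res = self.res_deg
        lat_edges_hi = self.lats + res / 2.0  # lat decreasing north->south
        i = np.nonzero((lat < lat_edges_hi) & (lat >= self.lats - res / 2.0))[0]
        j = np.nonzero((lon >= self.lons - res / 2.0) & (lon < self.lons + res / 2.0))[0]
        if len(i) != 1 or len(j) != 1:
            raise ValueError(f"point ({lat}, {lon}) outside the grid")
        return int(i[0]), int(j[0])

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return float(self.lats[i]), float(self.lons[j])

    # -- field access -------------------------------------------------------

    @property
    def sp(self) -> np.ndarray:
        """Surface pressure, hPa, shape (time, lat, lon)."""
        return self.ds["sp"].values

    @property
    def elev_min(self) -> np.ndarray:
        return self.ds["elev_min"].values

    @property
    def elev_max(self) -> np.ndarray:
        return self.ds["elev_max"].values

    def wind_mean(self, start, end, cells: list[tuple[int, int]]) -> tuple[float, float]:
        """Time-mean wind (u, v) over [start, end], space-mean over ``cells``."""
        t = self.times
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start.tz is None:
            start = start.tz_localize("UTC")
        if end.tz is None:
            end = end.tz_localize("UTC")
        m = (t >= start) & (t <= end)
        if not m.any():
            m = np.abs((t - start).total_seconds()) == np.min(np.abs((t - start).total_seconds()))
        us, vs = [], []
        for i, j in cells:
            us.append(self.ds["u"].values[m, i, j].mean())
            vs.append(self.ds["v"].values[m, i, j].mean())
        return float(np.mean(us)), float(np.mean(vs))

    # -- I/O ----------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds["sp"].attrs["units"] = "hPa"
        # scipy engine writes NetCDF3 classic, which cannot hold datetime64
        # attributes; encode time as hours since the first stamp.
        ds.to_netcdf(path, engine="scipy")

    @staticmethod
    def from_netcdf(path) -> "GriddedAtmosphere":
        ds = xr.open_dataset(path, engine="scipy").load()
        return GriddedAtmosphere(ds)


def read_atmosphere(path) -> GriddedAtmosphere:
    """Read and validate a gridded-atmosphere NetCDF file (units normalized to hPa/m/(m/s))."""
    return GriddedAtmosphere.from_netcdf(path)
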