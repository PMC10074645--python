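"""Within-stationary-period altitudinal behaviour.

Two patterns are screened for in the altitude series of a stationary period:

* **diel roost commuting** — the bird spends nights consistently higher (or
  lower) than its daytime territory.  Samples are split into day and night
  at civil twilight (solar zenith 96 degrees at the period's most-likely
  location); each day/following-night pair yields a delta of medians, and a
  pattern is *detected* when the delta stays inside a configurable band
  (default 50-300 m, matching the roost offsets reported for alpine
  passerines) for a minimum number of consecutive days;
* **excursions** — multi-hour departures from the period's baseline
  (median) altitude beyond a threshold, e.g. valley descents during adverse
  weather.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import CIVIL_TWILIGHT_ZENITH, solar_zenith

__all__ = ["DielPattern", "Excursion", "detect_diel_commuting", "detect_excursions"]


@dataclass
class DielPattern:
    period_id: int
    day_altitude: float
    night_altitude: float
    delta: float
    n_days: int
    detected: bool
    evaluable: bool = True


@dataclass
class Excursion:
    period_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    altitude_shift: float
    duration_h: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def detect_diel_commuting(
    timestamps: pd.DatetimeIndex,
    altitudes: np.ndarray,
    location: tuple[float, float],
    period_id: int = 0,
    min_delta: float = 50.0,
    max_delta: float = 300.0,
    min_days: int = 3,
) -> DielPattern:
    """Detect regular day/night altitude alternation within one period.

    Day = solar zenith < 96 deg at ``location``.  Each daylight run is paired
    with the following night run; the pattern is detected when the night
    minus day median altitude lies within [min_delta, max_delta] for at
    least ``min_days`` consecutive pairs.  Detections are invariant to an
    altitude offset.
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    alt = np.asarray(altitudes, dtype=float)
    z = solar_zenith(ts.to_numpy(), location[0], location[1])
    is_day = np.asarray(z) < CIVIL_TWILIGHT_ZENITH
    day_runs = _runs(is_day)
    night_runs = _runs(~is_day)
    # pair each full daylight run with the night run that follows it
    deltas = []
    for ds, de in day_runs:
        following = [(ns, ne) for ns, ne in night_runs if ns == de]
        if not following:
            continue
        ns, ne = following[0]
        if ne >= len(alt):  # truncated final night
            ne = len(alt)
        if ne - ns < 2 or de - ds < 2:
            continue
        deltas.append(np.median(alt[ns:ne]) - np.median(alt[ds:de]))
    if len(deltas) < min_days:
        return DielPattern(period_id, np.nan, np.nan, np.nan, len(deltas), False, evaluable=False)
    deltas = np.asarray(deltas)
    in_band = (deltas >= min_delta) & (deltas <= max_delta)
    longest = max((e - s for s, e in _runs(in_band)), default=0)
    day_med = float(np.median(alt[is_day])) if is_day.any() else np.nan
    night_med = float(np.median(alt[~is_day])) if (~is_day).any() else np.nan
    return DielPattern(
        period_id=period_id,
        day_altitude=day_med,
        night_altitude=night_med,
        delta=night_med - day_med,
        n_days=len(deltas),
        detected=bool(longest >= min_days),
    )


def detect_excursions(
    timestamps: pd.DatetimeIndex,
    altitudes: np.ndarray,
    period_id: int = 0,
    threshold_m: float = 300.0,
    min_duration_h: float = 6.0,
) -> list[Excursion]:
    """Maximal runs where altitude departs from the period median by >= threshold.

    Two separated departures stay two excursions; the reported shift is the
    median deviation from baseline during the run.
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    alt = np.asarray(altitudes, dtype=float)
    if len(alt) < 2:
        return []
    baseline = np.median(alt)
    away = np.abs(alt - baseline) >= threshold_m
    out = []
    for s, e in _runs(away):
        start, endi = ts[s], ts[min(e, len(ts) - 1)]
        dur = (endi - start).total_seconds() / 3600.0
        if e == len(ts):  # run reaches the series end; extend by one step
            dur += (ts[1] - ts[0]).total_seconds() / 3600.0
        if dur >= min_duration_h:
            out.append(
                Excursion(
                    period_id=period_id,
                    start=start,
                    end=endi,
                    altitude_shift=float(np.median(alt[s:e] - baseline)),
                    duration_h=float(dur),
                )
            )
    return out
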