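"""Automatic flight/stationary segmentation of a pressure series.

Stationary periods show limited pressure variation; migratory flights show a
sustained, fast pressure change as the bird climbs or descends.  The proposal
rule classifies a sample as in-flight when the magnitude of the local
pressure rate (centered first difference over one sampling step) exceeds a
threshold, merges flight runs separated by short gaps, and drops runs shorter
than a minimum duration.  Proposals are a labelling aid: curated label files
always take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ActivityTimeline, LoggerSeries, ValidationError

__all__ = ["SegmentationConfig", "propose_segments", "flight_durations"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the rate-based segmentation rule.

    rate_threshold
        |dP/dt| above which a sample is flagged as in-flight, hPa/h.  The
        default 4 hPa/h corresponds to roughly 35 m/min of climb near sea
        level — well above synoptic weather rates.
    min_flight_duration
        Runs shorter than this (hours) are reclassified stationary.
    merge_gap
        Flight runs separated by less than this (hours) are merged.
    stationary_variation_limit
        Pressure spread (hPa over a 2-h window) regarded as compatible with
        a stationary bird; used only for diagnostics.
    """

    rate_threshold: float = 4.0
    min_flight_duration: float = 0.5
    merge_gap: float = 1.0
    stationary_variation_limit: float = 3.0

    def __post_init__(self) -> None:
        for name in ("rate_threshold", "min_flight_duration", "merge_gap", "stationary_variation_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def propose_segments(series: LoggerSeries, cfg: SegmentationConfig | None = None) -> ActivityTimeline:
    """Propose an :class:`ActivityTimeline` from the pressure series alone."""
    cfg = cfg or SegmentationConfig()
    if len(series) < 3:
        raise ValidationError("series too short to segment (need >= 3 samples)")
    dt_h = series.dt_seconds / 3600.0
    p = series.pressure.astype(float).copy()
    p[~series.pressure_valid] = np.nan

    # centered first difference over one sampling step, hPa/h
    rate = np.full(len(p), np.nan)
    rate[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt_h)
    rate[0] = (p[1] - p[0]) / dt_h
    rate[-1] = (p[-1] - p[-2]) / dt_h
    in_flight = np.abs(rate) > cfg.rate_threshold
    in_flight &= ~np.isnan(rate)

    # merge flight runs separated by gaps shorter than merge_gap
    gap_samples = max(int(round(cfg.merge_gap / dt_h)), 1)
    runs = _runs(in_flight)
    for (s0, e0), (s1, _e1) in zip(runs[:-1], runs[1:]):
        if s1 - e0 < gap_samples:
            in_flight[e0:s1] = True

    # reclassify short flights as stationary
    min_samples = max(int(round(cfg.min_flight_duration / dt_h)), 1)
    for s, e in _runs(in_flight):
        if e - s < min_samples:
            in_flight[s:e] = False

    ts = series.timestamps
    step = pd.Timedelta(seconds=series.dt_seconds)
    bounds = []
    state = bool(in_flight[0])
    seg_start = ts[0]
    for k in range(1, len(ts)):
        if bool(in_flight[k]) != state:
            bounds.append(("flight" if state else "stationary", seg_start, ts[k]))
            seg_start = ts[k]
            state = bool(in_flight[k])
    bounds.append(("flight" if state else "stationary", seg_start, ts[-1] + step))
    return ActivityTimeline.from_bounds(bounds)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def flight_durations(timeline: ActivityTimeline) -> pd.DataFrame:
    """Table of (flight_id, start, end, duration_h) for every flight."""
    fl = timeline.flights
    if fl.empty:
        return pd.DataFrame(columns=["flight_id", "start", "end", "duration_h"])
    dur = (fl["end"] - fl["start"]).dt.total_seconds() / 3600.0
    return pd.DataFrame(
        {"flight_id": fl["id"].to_numpy(), "start": fl["start"], "end": fl["end"], "duration_h": dur.to_numpy()}
    )
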