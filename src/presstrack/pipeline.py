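"""End-to-end orchestration: segment -> maps -> HMM -> metrics -> local movements.

`run_track` is the in-memory core used by both the CLI and the test
harness: given a logger series, a timeline and an atmosphere it builds the
per-period emission maps (pressure, optionally light, combined by cell-wise
product), pools consecutive flight segments between stationary periods,
fits the trajectory HMM and derives flight records.  `run_pipeline` wraps it
with file I/O, config echoing and a run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .flight import (
    RegionPartition,
    classify_and_summarize,
    flight_altitude_series,
    flight_season,
    positive_altitudinal_change,
    speed_and_wind,
)
from .hmm import TrajectoryModel, TrajectoryResults
from .io import ActivityTimeline, GriddedAtmosphere, LoggerSeries, read_atmosphere, read_labels, read_logger
from .light import calibrate_zenith, detect_twilights, light_likelihood_map
from .local import detect_diel_commuting, detect_excursions
from .movement import MovementModel
from .pressure import combine_maps, pressure_likelihood_map

__all__ = ["RunConfig", "run_track", "run_pipeline", "TrackOutput"]


@dataclass
class RunConfig:
    """Run-level configuration; defaults are the package's standard analysis."""

    logger_path: str | None = None
    labels_path: str | None = None
    atmosphere_path: str | None = None
    out_dir: str = "presstrack_out"
    sigma_hpa: float = 1.0
    pooling_weight: float = 0.1
    altitude_margin_m: float = 150.0
    use_light: bool = False
    light_threshold: float = 50.0
    calibration_site: tuple | None = None  # (lat, lon)
    calibration_window: tuple | None = None  # (start, end) UTC
    gamma: float = 1.0 / 3.0
    v_min_kmh: float = 20.0
    max_ground_speed_kmh: float = 150.0
    n_sim: int = 100
    cr_quantile: float = 0.99
    seed: int = 0


@dataclass
class TrackOutput:
    """Everything one track produces in memory."""

    results: TrajectoryResults
    periods: pd.DataFrame
    emissions: list
    flights: pd.DataFrame
    flight_records: pd.DataFrame
    summary: pd.DataFrame


def pool_flights(timeline: ActivityTimeline) -> pd.DataFrame:
    """One pooled flight per pair of consecutive stationary periods.

    Consecutive flight segments between two stationary periods are merged;
    the pooled duration is the summed flight time, the window spans first
    take-off to last landing.
    """
    segs = timeline.segments
    pooled = []
    current = None
    for seg in segs.itertuples():
        if seg.kind == "flight":
            if current is None:
                current = {"start": seg.start, "end": seg.end, "duration_h": 0.0}
            current["end"] = seg.end
            current["duration_h"] += (seg.end - seg.start).total_seconds() / 3600.0
        else:
            if current is not None:
                pooled.append(current)
                current = None
    # a trailing flight with no following stationary period is dropped
    return pd.DataFrame(pooled)


def run_track(
    series: LoggerSeries,
    timeline: ActivityTimeline,
    atmosphere: GriddedAtmosphere,
    cfg: RunConfig | None = None,
) -> TrackOutput:
    """Fit the full trajectory model for one track; see module docstring."""
    cfg = cfg or RunConfig()
    stat = timeline.stationary
    flights = pool_flights(timeline)
    if len(flights) != len(stat) - 1:
        raise ValueError(
            f"timeline must alternate: {len(stat)} stationary periods need "
            f"{len(stat) - 1} pooled flights, found {len(flights)}"
        )

    calibration = None
    twilights = None
    if cfg.use_light:
        if series.light is None:
            raise ValueError("use_light requested but series has no light channel")
        twilights = detect_twilights(series, cfg.light_threshold)
        site = cfg.calibration_site
        window = cfg.calibration_window
        if site is None:
            raise ValueError("light geolocation needs calibration_site")
        if window is None:
            first = stat.iloc[0]
            window = (first["start"], first["end"])
        calibration = calibrate_zenith(twilights.between(*window), site[0], site[1])

    emissions = []
    for seg in stat.itertuples():
        sub = series.slice(seg.start, seg.end)
        pmap = pressure_likelihood_map(
            sub,
            atmosphere,
            period_id=int(seg.id),
            pooling_weight=cfg.pooling_weight,
            sigma=cfg.sigma_hpa,
            altitude_margin=cfg.altitude_margin_m,
        )
        lmap = None
        if cfg.use_light:
            tw = twilights.between(seg.start, seg.end)
            if len(tw) >= 1:
                lmap = light_likelihood_map(tw, calibration, atmosphere, period_id=int(seg.id))
        emissions.append(combine_maps(pmap, lmap))

    movement = MovementModel(gamma=cfg.gamma, v_min_kmh=cfg.v_min_kmh)
    model = TrajectoryModel(
        emissions,
        flights=flights.to_dict("records"),
        atmosphere=atmosphere,
        movement=movement,
        max_ground_speed_kmh=cfg.max_ground_speed_kmh,
    )
    results = model.fit()

    flight_records = build_flight_records(series, timeline, atmosphere, results, flights)
    _, summary = (
        classify_and_summarize(flight_records)
        if not flight_records.empty
        else (flight_records, pd.DataFrame())
    )
    return TrackOutput(
        results=results,
        periods=stat,
        emissions=emissions,
        flights=flights,
        flight_records=flight_records,
        summary=summary,
    )


def build_flight_records(
    series: LoggerSeries,
    timeline: ActivityTimeline,
    atmosphere: GriddedAtmosphere,
    results: TrajectoryResults,
    pooled_flights: pd.DataFrame,
) -> pd.DataFrame:
    """Per pooled flight: altitude, climb and speed metrics at the MLP positions."""
    rows = []
    latlon = results.mlp_latlon
    for k, fl in enumerate(pooled_flights.itertuples()):
        from_lat, from_lon = latlon[k]
        to_lat, to_lon = latlon[k + 1]
        dur = float(fl.duration_h)
        sub = series.slice(fl.start, fl.end)
        row = {
            "flight_id": k + 1,
            "bird_id": series.bird_id,
            "start": fl.start,
            "end": fl.end,
            "duration_h": dur,
            "from_lat": from_lat,
            "from_lon": from_lon,
            "to_lat": to_lat,
            "to_lon": to_lon,
            "season": flight_season(fl.start),
        }
        if len(sub) >= 2:
            alt = flight_altitude_series(sub, atmosphere, latlon[k])
            pac = positive_altitudinal_change(alt)
            row.update(
                max_altitude_m=float(alt.max()),
                mean_altitude_m=float(alt.mean()),
                positive_altitudinal_change_m=pac,
                climb_rate_m_per_h=pac / dur,
            )
        wind = atmosphere.wind_mean(
            fl.start, fl.end, [results.mlp_cells[k], results.mlp_cells[k + 1]]
        )
        row.update(speed_and_wind((from_lat, from_lon), (to_lat, to_lon), dur, wind))
        rows.append(row)
    return pd.DataFrame(rows)


def local_movement_report(
    series: LoggerSeries,
    timeline: ActivityTimeline,
    atmosphere: GriddedAtmosphere,
    results: TrajectoryResults,
    min_days: int = 3,
) -> pd.DataFrame:
    """Diel-commuting and excursion screen for every stationary period."""
    rows = []
    for t, seg in enumerate(timeline.stationary.itertuples()):
        sub = series.slice(seg.start, seg.end)
        if len(sub) < 4:
            continue
        loc = results.mlp_latlon[t]
        i, j = results.mlp_cells[t]
        t_atm = atmosphere.times.asi8.astype(float)
        from .barometry import pressure_to_altitude, reduce_to_sea_level

        ref_elev = float(atmosphere.ds.attrs.get("sp_ref_elev_m", 0.0))
        sp_sl = reduce_to_sea_level(atmosphere.sp[:, i, j], ref_elev)
        p_ref = np.interp(sub.timestamps.asi8.astype(float), t_atm, sp_sl)
        alt = pressure_to_altitude(sub.pressure, p_ref)
        diel = detect_diel_commuting(sub.timestamps, alt, loc, period_id=int(seg.id), min_days=min_days)
        rows.append({"kind": "diel", "period_id": int(seg.id), **diel.__dict__})
        for exc in detect_excursions(sub.timestamps, alt, period_id=int(seg.id)):
            rows.append({"kind": "excursion", **exc.__dict__})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based end-to-end run; writes all interface files plus a run log."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        series = read_logger(cfg.logger_path)
        timeline = read_labels(cfg.labels_path, series)
        atmosphere = read_atmosphere(cfg.atmosphere_path)
        stage = "trajectory fit"
        track = run_track(series, timeline, atmosphere, cfg)
        stage = "write outputs"
        track.results.to_path_frame(track.periods).to_csv(out / "mlp.csv", index=False)
        samples = track.results.sample_paths(cfg.n_sim, seed=cfg.seed)
        shape = track.results.model.grid_shape
        rows = []
        for sid in range(samples.shape[0]):
            for t, flat in enumerate(samples[sid]):
                i, j = np.unravel_index(int(flat), shape)
                lat, lon = atmosphere.cell_center(int(i), int(j))
                rows.append({"sample_id": sid, "period_id": t + 1, "lat": lat, "lon": lon})
        pd.DataFrame(rows).to_csv(out / "samples.csv", index=False)
        if not track.flight_records.empty:
            rec, summary = classify_and_summarize(track.flight_records)
            rec.to_csv(out / "flights.csv", index=False)
            summary.to_csv(out / "summary.csv", index=False)
        local = local_movement_report(series, timeline, atmosphere, track.results)
        local.to_csv(out / "local_movements.csv", index=False)
        for t, emission in enumerate(track.emissions):
            emission.to_netcdf(out / f"emission_period_{t + 1:02d}.nc", atmosphere)
        (out / "run_config.json").write_text(json.dumps(asdict(cfg), default=str, indent=2))
        (out / "run_log.txt").write_text(
            f"presstrack {__version__}\nseed {cfg.seed}\nperiods {len(track.periods)}\n"
        )
    except Exception as err:  # noqa: BLE001 - annotate with stage and re-raise
        raise RuntimeError(f"pipeline failed at stage: {stage}: {err}") from err
    return out
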