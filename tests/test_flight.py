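"""Flight altitude reconstruction, speed/wind metrics, regional summaries."""

import numpy as np
import pandas as pd
import pytest

from presstrack.barometry import altitude_to_pressure
from presstrack.flight import (
    RegionPartition,
    classify_and_summarize,
    flight_altitude_series,
    positive_altitudinal_change,
    speed_and_wind,
)
from conftest import flat_atmosphere, logger_from_pressure


def test_altitude_zero_when_pressure_matches_reference():
    atm = flat_atmosphere(p0=1010.0)
    s = logger_from_pressure(np.full(10, 1010.0), dt_s=1800)
    alt = flight_altitude_series(s, atm, (45.6, 8.4))
    np.testing.assert_allclose(alt, 0.0, atol=1e-9)


def test_reference_rise_shifts_altitude():
    # constant bird pressure while the reference rises 5 hPa: the derived
    # altitude rises by ~42 m near sea level (closed form: 41.7 m for
    # 1008 hPa against 1008.25 -> 1013.25)
    hours = 24
    sp = np.full((hours, 3, 3), 1008.25)
    sp[12:] = 1013.25
    atm = flat_atmosphere(n_lat=3, n_lon=3, hours=hours, sp=sp)
    s = logger_from_pressure(np.full(20, 1008.0), dt_s=3600)
    alt = flight_altitude_series(s, atm, (45.8, 8.2))
    rise = alt[-1] - alt[0]
    assert rise == pytest.approx(41.7, abs=2.0)


def test_synthetic_flight_mean_altitude_within_50m():
    hours = 12
    atm = flat_atmosphere(n_lat=3, n_lon=3, hours=hours, p0=1013.25)
    rng = np.random.default_rng(2)
    n = 10
    p = altitude_to_pressure(2000.0, 1013.25) + rng.normal(0.0, 0.5, n)
    s = logger_from_pressure(p, dt_s=1800)
    alt = flight_altitude_series(s, atm, (45.8, 8.2))
    assert abs(alt.mean() - 2000.0) < 50.0


def test_positive_altitudinal_change_examples():
    assert positive_altitudinal_change([0.0, 500.0, 300.0, 800.0]) == 1000.0
    assert positive_altitudinal_change(np.linspace(3000, 0, 20)) == 0.0
    assert positive_altitudinal_change([0.0, 1000.0]) / 2.5 == pytest.approx(400.0)


def test_speed_and_wind_degenerate_and_orthogonal():
    same = speed_and_wind((45.0, 8.0), (45.0, 8.0), 2.0)
    assert same["distance_km"] == 0.0 and same["ground_speed_kmh"] == 0.0
    # due-east track, due-north wind: no support
    out = speed_and_wind((0.0, 0.0), (0.0, 1.0), 2.0, wind_uv_ms=(0.0, 20.0 / 3.6))
    assert out["wind_support_kmh"] == pytest.approx(0.0, abs=1e-9)


def test_quarter_degree_latitude_is_about_27km():
    out = speed_and_wind((45.0, 8.0), (45.25, 8.0), 1.0)
    assert 27.0 <= out["distance_km"] <= 28.0


def test_speed_times_duration_equals_distance():
    rng = np.random.default_rng(8)
    for _ in range(20):
        a = (rng.uniform(-60, 60), rng.uniform(-180, 180))
        b = (rng.uniform(-60, 60), rng.uniform(-180, 180))
        dur = rng.uniform(0.5, 20.0)
        out = speed_and_wind(a, b, dur)
        assert out["ground_speed_kmh"] * dur == pytest.approx(out["distance_km"], rel=1e-6)


def _records(rows):
    return pd.DataFrame(rows)


def test_classify_one_flight_per_category():
    lat_for = {"europe": 50.0, "mediterranean": 39.0, "atlas": 33.0, "sahara": 25.0, "sahel": 14.0}
    rows = []
    for k, (cat, lat) in enumerate(lat_for.items()):
        rows.append(
            {
                "from_lat": lat + 0.5,
                "from_lon": 5.0,
                "to_lat": lat - 0.5,
                "to_lon": 5.0,
                "start": pd.Timestamp("2020-09-15", tz="UTC"),
                "duration_h": float(k + 1),
            }
        )
    rec, summary = classify_and_summarize(_records(rows))
    assert set(rec["category"]) == set(lat_for)
    per_cat = summary[summary["category"] != "overall"].set_index("category")
    for k, cat in enumerate(lat_for):
        assert per_cat.loc[cat, "duration_h_mean"] == k + 1
        assert per_cat.loc[cat, "duration_h_sd"] == 0.0
        assert not per_cat.loc[cat, "sd_defined"]


def test_duplicated_records_keep_means_and_sd():
    rows = [
        {"from_lat": 50.0, "from_lon": 5.0, "to_lat": 49.0, "to_lon": 5.0,
         "start": pd.Timestamp("2020-09-15", tz="UTC"), "duration_h": d}
        for d in (4.0, 6.0, 8.0)
    ]
    _, s1 = classify_and_summarize(_records(rows))
    _, s2 = classify_and_summarize(_records(rows + rows))
    r1 = s1[s1["category"] == "europe"].iloc[0]
    r2 = s2[s2["category"] == "europe"].iloc[0]
    assert r1["duration_h_mean"] == r2["duration_h_mean"]
    # duplicating halves nothing: mean unchanged, sd shrinks but stays defined
    assert r2["sd_defined"]


def test_barrier_flights_rank_longer_and_faster():
    # constructed world: sea/desert crossings are longer and faster than land hops
    rng = np.random.default_rng(3)
    rows = []
    spec = {
        "europe": (3.0, 40.0),
        "mediterranean": (9.0, 55.0),
        "atlas": (2.5, 38.0),
        "sahara": (10.0, 60.0),
        "sahel": (3.5, 42.0),
    }
    lat_for = {"europe": 50.0, "mediterranean": 39.0, "atlas": 33.0, "sahara": 25.0, "sahel": 14.0}
    for cat, (dur, gs) in spec.items():
        for _ in range(5):
            d = dur + rng.normal(0, 0.2)
            rows.append(
                {
                    "from_lat": lat_for[cat] + 0.3,
                    "from_lon": 5.0,
                    "to_lat": lat_for[cat] - 0.3,
                    "to_lon": 5.0,
                    "start": pd.Timestamp("2020-09-15", tz="UTC"),
                    "duration_h": d,
                    "ground_speed_kmh": gs + rng.normal(0, 1.0),
                }
            )
    _, summary = classify_and_summarize(_records(rows))
    per = summary[summary["category"] != "overall"].set_index("category")
    barrier = per.loc[["mediterranean", "sahara"]]
    land = per.loc[["europe", "atlas", "sahel"]]
    assert barrier["duration_h_mean"].min() > land["duration_h_mean"].max()
    assert barrier["ground_speed_kmh_mean"].min() > land["ground_speed_kmh_mean"].max()


def test_unclassifiable_midpoint_reported():
    rows = [{"from_lat": -20.0, "from_lon": 5.0, "to_lat": -21.0, "to_lon": 5.0,
             "start": pd.Timestamp("2021-04-04", tz="UTC"), "duration_h": 3.0}]
    rec, _ = classify_and_summarize(_records(rows))
    assert rec["category"].iloc[0] == "unclassified"
    assert rec["season"].iloc[0] == "spring"


def test_partition_first_match_order():
    part = RegionPartition()
    assert part.classify(43.0, 0.0) == "europe"  # boundary belongs to the first band
    assert part.classify(42.999, 0.0) == "mediterranean"
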