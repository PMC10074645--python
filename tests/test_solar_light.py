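"""Solar geometry and light-level geolocation."""

import numpy as np
import pandas as pd
import pytest

from presstrack.light import (
    ZenithCalibration,
    calibrate_zenith,
    detect_twilights,
    light_likelihood_map,
)
from presstrack.solar import solar_zenith
from conftest import flat_atmosphere, logger_from_pressure


# -- independent ephemeris oracle ------------------------------------------


def almanac_zenith(time_utc, lat, lon):
    """Low-precision Astronomical Almanac solar position (independent of the package).

    Good to ~0.01 deg between 1950 and 2050; used as the cross-check oracle.
    """
    t = pd.Timestamp(time_utc)
    if t.tz is None:
        t = t.tz_localize("UTC")
    n = (t - pd.Timestamp("2000-01-01 12:00", tz="UTC")).total_seconds() / 86400.0
    L = np.mod(280.460 + 0.9856474 * n, 360.0)
    g = np.radians(np.mod(357.528 + 0.9856003 * n, 360.0))
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    alpha = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam)))
    delta = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    # Greenwich mean sidereal time, degrees
    gmst = np.mod(280.46061837 + 360.98564736629 * n, 360.0)
    ha = np.radians(np.mod(gmst + lon - alpha + 180.0, 360.0) - 180.0)
    latr, dr = np.radians(lat), np.radians(delta)
    cosz = np.sin(latr) * np.sin(dr) + np.cos(latr) * np.cos(dr) * np.cos(ha)
    return np.degrees(np.arccos(np.clip(cosz, -1, 1)))


@pytest.mark.parametrize(
    "time,lat,lon",
    [
        ("2020-09-21 12:00", 0.0, 0.0),
        ("2020-06-21 04:00", 46.5, 8.7),
        ("2021-01-15 17:30", 14.0, 0.5),
        ("2020-12-21 22:00", -35.0, 150.0),
        ("2021-04-04 05:10", 30.0, -5.0),
    ],
)
def test_zenith_agrees_with_independent_ephemeris(time, lat, lon):
    ours = solar_zenith(pd.Timestamp(time, tz="UTC"), lat, lon)
    oracle = almanac_zenith(time, lat, lon)
    assert abs(ours - oracle) < 0.5


def test_equator_equinox_noon_near_zero():
    times = pd.date_range("2020-03-20 11:50", "2020-03-20 12:20", freq="1min", tz="UTC")
    z = solar_zenith(times.to_numpy(), 0.0, 0.0)
    assert z.min() < 0.6


def test_antipodal_longitude_sun_near_nadir():
    t = pd.Timestamp("2020-03-20 12:07", tz="UTC")
    z0 = solar_zenith(t, 0.0, 0.0)
    z180 = solar_zenith(t, 0.0, 180.0)
    assert abs((180.0 - z0) - z180) < 0.6


# -- twilight detection -----------------------------------------------------


def test_square_wave_crossings():
    light = np.tile(np.concatenate([np.zeros(24), np.full(24, 100.0)]), 3)
    s = logger_from_pressure(np.full(len(light), 900.0), light=light, dt_s=1800)
    tw = detect_twilights(s, threshold=5.0)
    kinds = list(tw.events["kind"])
    assert kinds[0] == "sunrise"
    assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))  # alternating
    assert len(kinds) == 5  # three nights -> 3 sunrises, 2 sunsets
    # crossings fall within one sample of the constructed switch times
    first = tw.events["time"].iloc[0]
    switch = s.timestamps[24]
    assert abs((first - switch).total_seconds()) <= 1800


def test_constant_light_no_events():
    s = logger_from_pressure(np.full(48, 900.0), light=np.full(48, 50.0))
    assert len(detect_twilights(s, threshold=5.0)) == 0


def _solar_light_series(lat, lon, days, start="2020-09-01", dt_s=1800, noise_sd=0.5, seed=0):
    ts = pd.date_range(start, periods=int(days * 86400 / dt_s), freq=pd.Timedelta(seconds=dt_s), tz="UTC")
    z = solar_zenith(ts.to_numpy(), lat, lon)
    light = 100.0 / (1.0 + np.exp((np.asarray(z) - 96.0) / 1.5))
    light = np.clip(light + np.random.default_rng(seed).normal(0, noise_sd, len(ts)), 0, None)
    return logger_from_pressure(np.full(len(ts), 900.0), start=str(ts[0]), light=light, dt_s=dt_s)


def test_solar_driven_twilights_within_ten_minutes():
    lat, lon = 46.5, 8.7
    s = _solar_light_series(lat, lon, days=6)
    tw = detect_twilights(s, threshold=50.0)
    errors = []
    for ev in tw.events.itertuples():
        # oracle: zenith at the detected event time should be 96 deg; convert
        # the angular offset to time via the local zenith rate (~fine search)
        t = ev.time
        fine = pd.date_range(t - pd.Timedelta("45min"), t + pd.Timedelta("45min"), freq="15s")
        z = solar_zenith(fine.to_numpy(), lat, lon)
        truth = fine[np.argmin(np.abs(np.asarray(z) - 96.0))]
        errors.append(abs((t - truth).total_seconds()) / 60.0)
    assert len(errors) >= 10
    assert np.median(errors) < 10.0


# -- calibration ------------------------------------------------------------


def test_point_mass_calibration_peaks_at_96():
    cal = ZenithCalibration(np.full(12, 96.0), bandwidth=1.0)
    z = np.linspace(80, 110, 301)
    assert z[np.argmax(cal(z))] == pytest.approx(96.0, abs=0.1)


def test_symmetric_samples_symmetric_density():
    cal = ZenithCalibration(np.array([95.0, 96.0, 97.0]), bandwidth=1.0)
    z = np.linspace(90, 102, 241)
    d = cal(z)
    np.testing.assert_allclose(d, d[::-1], atol=1e-12)


def test_density_integrates_to_one():
    cal = ZenithCalibration(np.array([94.0, 95.5, 96.0, 97.2, 98.0]), bandwidth=1.0)
    z = np.linspace(80.0, 110.0, 6001)
    integral = np.trapezoid(cal(z), z)
    assert integral == pytest.approx(1.0, abs=1e-6)


def test_calibrate_requires_enough_twilights():
    s = _solar_light_series(46.5, 8.7, days=1)
    tw = detect_twilights(s, threshold=50.0)
    with pytest.raises(ValueError, match="calibration twilights"):
        calibrate_zenith(tw, 46.5, 8.7)


# -- likelihood maps --------------------------------------------------------


@pytest.fixture(scope="module")
def light_setup():
    atm = flat_atmosphere(n_lat=9, n_lon=9, hours=24 * 12, lat_north=47.0, lon_west=7.0, res=0.25, start="2020-09-01")
    site_lat, site_lon = atm.cell_center(4, 4)
    s = _solar_light_series(site_lat, site_lon, days=12, start="2020-09-01")
    tw = detect_twilights(s, threshold=50.0)
    cal = calibrate_zenith(tw.between("2020-09-01", "2020-09-07"), site_lat, site_lon)
    return atm, s, tw, cal, (4, 4)


def test_pooled_map_longitude_near_truth(light_setup):
    atm, s, tw, cal, truth_cell = light_setup
    test_tw = tw.between("2020-09-07", "2020-09-12")
    m = light_likelihood_map(test_tw, cal, atm)
    i, j = m.argmax_cell()
    assert abs(j - truth_cell[1]) <= 3  # longitude well constrained
    assert m.values.sum() == pytest.approx(1.0)


def test_pooled_map_invariant_to_twilight_order(light_setup):
    atm, s, tw, cal, _ = light_setup
    test_tw = tw.between("2020-09-07", "2020-09-10")
    m1 = light_likelihood_map(test_tw, cal, atm)
    from presstrack.light import TwilightSet

    shuffled = TwilightSet(
        test_tw.events.sample(frac=1.0, random_state=1).sort_values("time"), test_tw.threshold
    )
    # pooling is a symmetric mean of log-densities: any order gives the same map
    m2 = light_likelihood_map(shuffled, cal, atm)
    np.testing.assert_allclose(m1.values, m2.values)


def test_duplicated_twilight_never_sharpens(light_setup):
    atm, s, tw, cal, _ = light_setup
    from presstrack.light import TwilightSet

    one = tw.between("2020-09-07", "2020-09-08")
    ev = one.events.iloc[[0]]
    m1 = light_likelihood_map(TwilightSet(ev, one.threshold), cal, atm)
    dup = ev.copy()
    dup["time"] = dup["time"] + pd.Timedelta("1us")
    both = TwilightSet(pd.concat([ev, dup]).sort_values("time"), one.threshold)
    m2 = light_likelihood_map(both, cal, atm)
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-6)
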