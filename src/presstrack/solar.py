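"""Solar position (zenith angle) from time and place.

Implements the NOAA solar-calculator geometry (Meeus-style truncated series:
mean solar longitude/anomaly, equation of center, apparent longitude,
obliquity with nutation correction, equation of time).  Geometric zenith,
no atmospheric refraction — civil twilight corresponds to a zenith of ~96
degrees.  Accuracy is a few hundredths of a degree over 1900-2100, far
inside the 0.5-degree tolerance that matters for twilight geolocation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_zenith", "solar_declination_eqtime", "CIVIL_TWILIGHT_ZENITH"]

CIVIL_TWILIGHT_ZENITH = 96.0


def _time_index(times) -> pd.DatetimeIndex:
    t = pd.to_datetime(times, utc=True)
    if isinstance(t, pd.Timestamp):
        t = pd.DatetimeIndex([t])
    return pd.DatetimeIndex(t)


def _julian_century(t: pd.DatetimeIndex) -> np.ndarray:
    # days since J2000.0 (2000-01-01 12:00 UTC)
    j2000 = pd.Timestamp("2000-01-01 12:00:00", tz="UTC")
    days = (t - j2000).total_seconds() / 86400.0
    return np.asarray(days) / 36525.0


def solar_declination_eqtime(times) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (degrees) and equation of time (minutes) at UTC times."""
    jc = _julian_century(_time_index(times))
    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = np.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(app_long)))
    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0r)
        - 0.5 * y**2 * np.sin(4 * l0r)
        - 1.25 * ecc**2 * np.sin(2 * m)
    )
    return decl, eqtime


def solar_zenith(times, lat, lon) -> np.ndarray:
    """Geometric solar zenith angle in degrees.

    ``times`` is a scalar or array of UTC instants; ``lat``/``lon`` are in
    decimal degrees and broadcast against the time axis (pass equal-length
    arrays for per-time positions, or scalars).
    """
    scalar = np.isscalar(lat) and not isinstance(times, (list, tuple, np.ndarray, pd.DatetimeIndex, pd.Series))
    t = _time_index(times)
    decl, eqtime = solar_declination_eqtime(t)
    minutes = (t.hour * 60 + t.minute + t.second / 60.0 + t.microsecond / 6.0e7).to_numpy()
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    tst = np.mod(minutes + eqtime + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0
    ha = np.where(ha < -180.0, ha + 360.0, ha)
    latr = np.radians(lat)
    declr = np.radians(decl)
    cosz = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(np.radians(ha))
    z = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))
    return float(z[0]) if scalar and z.size == 1 else z
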