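"""Great-circle geometry on a spherical Earth (R = 6371 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing_deg",
    "midpoint",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees clockwise from north.

    For coincident points the bearing is defined as 0.
    """
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lam2 - lam1
    y = np.sin(dlon) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlon)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return theta if np.ndim(theta) else float(theta)


def midpoint(lat1, lon1, lat2, lon2):
    """Great-circle midpoint of two points, decimal degrees."""
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lam2 - lam1
    bx = np.cos(phi2) * np.cos(dlon)
    by = np.cos(phi2) * np.sin(dlon)
    phim = np.arctan2(
        np.sin(phi1) + np.sin(phi2),
        np.sqrt((np.cos(phi1) + bx) ** 2 + by**2),
    )
    lamm = lam1 + np.arctan2(by, np.cos(phi1) + bx)
    latm = np.degrees(phim)
    lonm = (np.degrees(lamm) + 540.0) % 360.0 - 180.0
    if np.ndim(latm):
        return latm, lonm
    return float(latm), float(lonm)
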