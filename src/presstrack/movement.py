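"""Airspeed-based movement model for grid transitions.

The cost of a transition between two grid cells during a flight of known
duration is tied to the mechanical power a bird of given size and shape must
produce to fly at the implied airspeed.  The ground vector follows from
great-circle distance and initial bearing divided by the flight duration;
subtracting the wind vector gives the airspeed.  The classical power curve

    P(v) = alpha / v + beta * v^3        (v in m/s)

with ``alpha = 2 (m g)^2 / (rho pi b^2)`` (induced power) and
``beta = rho S_b C_Db / 2`` (parasite power) is strictly convex with its
minimum at ``v_mp = (alpha / (3 beta))^(1/4)``.  Transition weights are
``P(v)^(-gamma)`` with gamma = 1/3 by default — inversely proportional to the
cubic root of the mechanical power — so that energetically cheap airspeeds
are favoured.  A low airspeed floor (20 km/h) keeps short local or
exploratory flights from being penalized as absurdly slow transitions.

Defaults describe a Northern Wheatear-sized passerine (25 g, 0.29 m
wingspan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .barometry import STANDARD
from .geodesy import haversine_km, initial_bearing_deg

__all__ = ["MovementModel", "transition_weight", "transition_matrix"]

KMH_PER_MS = 3.6


@dataclass(frozen=True)
class MovementModel:
    """Bird morphology and the power -> weight mapping.

    mass kg, wingspan m, air density kg/m^3, body drag area S_b*C_Db m^2,
    exponent gamma (weight = P^-gamma), airspeed floor km/h.
    """

    mass: float = 0.025
    wingspan: float = 0.29
    air_density: float = 1.0
    body_drag_area: float = 0.00181
    gamma: float = 1.0 / 3.0
    v_min_kmh: float = 20.0

    @property
    def alpha(self) -> float:
        return 2.0 * (self.mass * STANDARD.gravity) ** 2 / (
            self.air_density * np.pi * self.wingspan**2
        )

    @property
    def beta(self) -> float:
        return 0.5 * self.air_density * self.body_drag_area

    def power(self, v_ms):
        """Mechanical power (W) at airspeed v (m/s)."""
        v = np.asarray(v_ms, dtype=float)
        if np.any(v <= 0):
            raise ValueError("airspeed must be positive")
        p = self.alpha / v + self.beta * v**3
        return p if p.ndim else float(p)

    @property
    def v_mp_ms(self) -> float:
        """Minimum-power airspeed, m/s."""
        return (self.alpha / (3.0 * self.beta)) ** 0.25

    def weight_from_airspeed(self, v_kmh):
        """Transition weight P(v)^(-gamma) after clamping v at the floor."""
        v = np.maximum(np.asarray(v_kmh, dtype=float), self.v_min_kmh)
        w = np.asarray(self.power(v / KMH_PER_MS)) ** (-self.gamma)
        return w if w.ndim else float(w)


def transition_weight(
    from_latlon: tuple[float, float],
    to_latlon: tuple[float, float],
    flight_duration_h: float,
    wind_uv_ms: tuple[float, float] = (0.0, 0.0),
    model: MovementModel | None = None,
) -> float:
    """Positive transition weight for one origin/destination pair."""
    if flight_duration_h <= 0:
        raise ValueError("flight duration must be positive")
    model = model or MovementModel()
    dist = haversine_km(*from_latlon, *to_latlon)
    bearing = np.radians(initial_bearing_deg(*from_latlon, *to_latlon))
    gs = dist / flight_duration_h
    ge, gn = gs * np.sin(bearing), gs * np.cos(bearing)  # km/h, east/north
    we, wn = wind_uv_ms[0] * KMH_PER_MS, wind_uv_ms[1] * KMH_PER_MS
    v = float(np.hypot(ge - we, gn - wn))
    return float(model.weight_from_airspeed(v))


def transition_matrix(
    lats: np.ndarray,
    lons: np.ndarray,
    flight_duration_h: float,
    wind_uv_ms: tuple[float, float] = (0.0, 0.0),
    model: MovementModel | None = None,
    max_ground_speed_kmh: float = 150.0,
) -> np.ndarray:
    """Row-stochastic (K, K) transition matrix over the flattened grid.

    Cells requiring a ground speed above ``max_ground_speed_kmh`` are pruned
    (weight zero); each row is renormalized over the reachable cells.
    """
    if flight_duration_h <= 0:
        raise ValueError("flight duration must be positive")
    model = model or MovementModel()
    lat2d, lon2d = np.meshgrid(lats, lons, indexing="ij")
    la = lat2d.ravel()
    lo = lon2d.ravel()
    dist = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    bearing = np.radians(initial_bearing_deg(la[:, None], lo[:, None], la[None, :], lo[None, :]))
    gs = dist / flight_duration_h
    ge, gn = gs * np.sin(bearing), gs * np.cos(bearing)
    we, wn = wind_uv_ms[0] * KMH_PER_MS, wind_uv_ms[1] * KMH_PER_MS
    v = np.hypot(ge - we, gn - wn)
    w = model.weight_from_airspeed(v)
    w[gs > max_ground_speed_kmh] = 0.0
    rows = w.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("a grid cell has no reachable destination; relax max_ground_speed")
    return w / rows
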