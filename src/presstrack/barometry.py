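"""Barometric altitude <-> pressure transform.

The hypsometric relation used throughout the package assumes a linear
temperature lapse below the tropopause (international standard atmosphere):

    z = z_ref + (T_ref / L) * (1 - (p / p_ref)**(R*L / (g*M)))

where ``p_ref`` is the pressure at the reference altitude ``z_ref`` and
``T_ref`` the air temperature at the reference level.  The exponent
``R*L/(g*M)`` is ~0.190263 for the standard-atmosphere constants.  The
inverse transform is exact, so a round trip altitude -> pressure -> altitude
is limited only by floating-point error (well below 0.5 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BarometricConstants",
    "pressure_to_altitude",
    "altitude_to_pressure",
    "reduce_to_sea_level",
]


@dataclass(frozen=True)
class BarometricConstants:
    """Standard-atmosphere constants for the hypsometric equation.

    Attributes
    ----------
    lapse_rate : float
        Temperature lapse rate L, K/m.
    gas_constant : float
        Universal gas constant R, J/(mol K).
    gravity : float
        Standard gravity g, m/s^2.
    molar_mass : float
        Molar mass of dry air M, kg/mol.
    t_ref : float
        Reference-level temperature, K.
    """

    lapse_rate: float = 0.0065
    gas_constant: float = 8.3144598
    gravity: float = 9.80665
    molar_mass: float = 0.0289644
    t_ref: float = 288.15

    def __post_init__(self) -> None:
        for name in ("lapse_rate", "gas_constant", "gravity", "molar_mass", "t_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def exponent(self) -> float:
        """R*L/(g*M), the pressure-ratio exponent (~0.190263)."""
        return (self.gas_constant * self.lapse_rate) / (self.gravity * self.molar_mass)


STANDARD = BarometricConstants()


def pressure_to_altitude(
    p,
    p_ref,
    z_ref=0.0,
    t_ref: float | None = None,
    constants: BarometricConstants = STANDARD,
):
    """Altitude (m a.s.l.) of pressure level ``p`` given reference ``p_ref`` at ``z_ref``.

    Parameters
    ----------
    p : array_like
        Pressure at the unknown altitude, hPa.
    p_ref : array_like
        Pressure at the reference altitude, hPa.
    z_ref : array_like, optional
        Reference altitude, m a.s.l. (default sea level).
    t_ref : float, optional
        Temperature at the reference level, K.  Defaults to the constants'
        ``t_ref`` (288.15 K).
    """
    p = np.asarray(p, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if np.any(p <= 0) or np.any(p_ref <= 0):
        raise ValueError("pressures must be positive")
    if t_ref is None:
        t_ref = constants.t_ref
    ratio = (p / p_ref) ** constants.exponent
    z = np.asarray(z_ref, dtype=float) + (t_ref / constants.lapse_rate) * (1.0 - ratio)
    return z if z.ndim else float(z)


def altitude_to_pressure(
    z,
    p_ref,
    z_ref=0.0,
    t_ref: float | None = None,
    constants: BarometricConstants = STANDARD,
):
    """Exact inverse of :func:`pressure_to_altitude`."""
    z = np.asarray(z, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if np.any(p_ref <= 0):
        raise ValueError("p_ref must be positive")
    if t_ref is None:
        t_ref = constants.t_ref
    base = 1.0 - constants.lapse_rate * (z - np.asarray(z_ref, dtype=float)) / t_ref
    if np.any(base <= 0):
        raise ValueError("altitude outside the validity range of the linear lapse")
    p = p_ref * base ** (1.0 / constants.exponent)
    return p if p.ndim else float(p)


def reduce_to_sea_level(
    p,
    elevation,
    t_ref: float | None = None,
    constants: BarometricConstants = STANDARD,
):
    """Reduce a surface pressure measured at ``elevation`` (m) to sea level.

    Equivalent to asking: what pressure at z=0 is consistent with pressure
    ``p`` observed at ``elevation`` under the standard lapse?  Elevation 0 is
    the identity.
    """
    elevation = np.asarray(elevation, dtype=float)
    p = np.asarray(p, dtype=float)
    if t_ref is None:
        t_ref = constants.t_ref
    base = 1.0 - constants.lapse_rate * elevation / t_ref
    out = p / base ** (1.0 / constants.exponent)
    return out if out.ndim else float(out)
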