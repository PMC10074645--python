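"""Pressure-match geolocation of stationary periods.

A stationary bird records the local surface-pressure signal shifted by a
constant offset set by its altitude above the reference level.  Matching the
*demeaned* logger series against the demeaned surface-pressure series of each
grid cell therefore scores the temporal weather signature independently of
altitude, while the mean offset itself implies an altitude that must be
compatible with the cell's terrain elevation range.  Both pieces of
information enter the likelihood map: a Gaussian mismatch kernel with
log-linear down-weighting (weight ``w`` < 1 compensates for the strong
temporal autocorrelation of weather, which would otherwise make maps built
from thousands of correlated samples badly overconfident), and a hard
altitude-plausibility mask with a configurable margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .barometry import BarometricConstants, STANDARD, pressure_to_altitude
from .io import GriddedAtmosphere, LoggerSeries

__all__ = [
    "LikelihoodMap",
    "pressure_mismatch",
    "pressure_likelihood_map",
    "NoPlausibleCellError",
]

ALTITUDE_MARGIN_M = 150.0
MIN_HOURLY_SAMPLES = 3


class NoPlausibleCellError(ValueError):
    """Every grid cell was rejected by the altitude-plausibility mask."""


@dataclass
class LikelihoodMap:
    """Nonnegative per-cell map for one stationary period.

    ``values`` has the atmosphere grid's (lat, lon) shape.  When
    ``normalized`` is set, values sum to one.
    """

    period_id: int
    source: str  # "pressure" | "light" | "combined"
    values: np.ndarray
    normalized: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("likelihood values must be nonnegative")
        if self.normalized:
            total = self.values.sum()
            if total <= 0:
                raise ValueError("cannot normalize an all-zero map")
            if abs(total - 1.0) > 1e-9:
                self.values = self.values / total

    def normalize(self) -> "LikelihoodMap":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero map")
        return LikelihoodMap(self.period_id, self.source, self.values / total, True, dict(self.meta))

    def argmax_cell(self) -> tuple[int, int]:
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(i), int(j)

    def plot(self, atmosphere: GriddedAtmosphere, ax=None, **kwargs):
        """Diagnostic map rendering (pcolormesh over the grid); returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = atmosphere.res_deg
        lat_edges = np.append(atmosphere.lats + res / 2, atmosphere.lats[-1] - res / 2)
        lon_edges = np.append(atmosphere.lons - res / 2, atmosphere.lons[-1] + res / 2)
        m = ax.pcolormesh(lon_edges, lat_edges, self.values, **kwargs)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.set_title(f"period {self.period_id} ({self.source})")
        plt.colorbar(m, ax=ax, label="likelihood")
        return ax

    def to_netcdf(self, path, atmosphere: GriddedAtmosphere) -> None:
        da = xr.DataArray(
            self.values,
            coords={"lat": atmosphere.lats, "lon": atmosphere.lons},
            dims=("lat", "lon"),
            name="likelihood",
            attrs={"period_id": self.period_id, "source": self.source},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")


def hourly_means(series: LoggerSeries, times: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Average the logger pressure within each atmosphere hour.

    Returns (indices into ``times``, hourly mean pressures) for the hours with
    at least one valid logger sample.  The hour of a sample is its timestamp
    floored to the hour (atmosphere stamps are on the hour).
    """
    valid = series.pressure_valid
    ts = series.timestamps[valid].floor("h")
    p = series.pressure[valid]
    if len(ts) == 0:
        return np.array([], dtype=int), np.array([])
    df = pd.DataFrame({"hour": ts, "p": p}).groupby("hour", sort=True)["p"].mean()
    pos = times.get_indexer(df.index)
    keep = pos >= 0
    return pos[keep], df.to_numpy()[keep]


def pressure_mismatch(
    period_series: LoggerSeries,
    atmosphere: GriddedAtmosphere,
    cell: tuple[int, int],
    constants: BarometricConstants = STANDARD,
) -> dict:
    """Temporal mismatch and implied altitude of one period at one cell.

    Returns ``{"mse": hPa^2, "implied_altitude": m, "n": int}``.  ``mse`` is
    the mean squared difference between the demeaned hourly logger series and
    the demeaned cell surface-pressure series; ``implied_altitude`` converts
    the mean logger pressure against the cell's mean surface pressure with
    the barometric transform.  Fewer than 3 overlapping hourly samples leaves
    the mismatch undefined (mse = nan).
    """
    idx, p_log = hourly_means(period_series, atmosphere.times)
    i, j = cell
    out = {"mse": np.nan, "implied_altitude": np.nan, "n": int(len(idx))}
    if len(idx) == 0:
        return out
    p_cell = atmosphere.sp[idx, i, j]
    ref_elev = float(atmosphere.ds.attrs.get("sp_ref_elev_m", 0.0))
    out["implied_altitude"] = float(
        pressure_to_altitude(p_log.mean(), p_cell.mean(), z_ref=ref_elev, constants=constants)
    )
    if len(idx) >= MIN_HOURLY_SAMPLES:
        d = (p_log - p_log.mean()) - (p_cell - p_cell.mean())
        out["mse"] = float(np.mean(d**2))
    return out


def pressure_likelihood_map(
    period_series: LoggerSeries,
    atmosphere: GriddedAtmosphere,
    period_id: int = 0,
    pooling_weight: float = 0.1,
    sigma: float = 1.0,
    altitude_margin: float = ALTITUDE_MARGIN_M,
    constants: BarometricConstants = STANDARD,
) -> LikelihoodMap:
    """Likelihood map of one stationary period over the atmosphere grid.

    Per cell: ``exp(-w * n * mse / (2 sigma^2))`` times an altitude mask that
    requires the implied altitude to fall within
    ``[elev_min - margin, elev_max + margin]``.  Periods with fewer than 3
    overlapping hourly samples contribute a mask-only map (temporally
    uninformative).  The map is normalized to sum to one.
    """
    if not (0.0 < pooling_weight <= 1.0):
        raise ValueError("pooling_weight must be in (0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    idx, p_log = hourly_means(period_series, atmosphere.times)
    if len(idx) == 0:
        raise ValueError(f"period {period_id} does not overlap the atmosphere time span")
    sp = atmosphere.sp[idx]  # (n, nlat, nlon)
    n = len(idx)
    ref_elev = float(atmosphere.ds.attrs.get("sp_ref_elev_m", 0.0))
    implied_alt = pressure_to_altitude(
        p_log.mean(), sp.mean(axis=0), z_ref=ref_elev, constants=constants
    )
    mask = (implied_alt >= atmosphere.elev_min - altitude_margin) & (
        implied_alt <= atmosphere.elev_max + altitude_margin
    )
    if not mask.any():
        gap = np.minimum(
            np.abs(implied_alt - (atmosphere.elev_min - altitude_margin)),
            np.abs(implied_alt - (atmosphere.elev_max + altitude_margin)),
        )
        raise NoPlausibleCellError(
            f"period {period_id}: no plausible cell "
            f"(min implied-altitude gap {float(gap.min()):.0f} m)"
        )
    if n >= MIN_HOURLY_SAMPLES:
        d = (p_log[:, None, None] - p_log.mean()) - (sp - sp.mean(axis=0))
        mse = np.mean(d**2, axis=0)
        loglik = -pooling_weight * n * mse / (2.0 * sigma**2)
        loglik -= loglik.max()
        values = np.exp(loglik) * mask
    else:
        values = mask.astype(float)
    return LikelihoodMap(
        period_id,
        "pressure",
        values,
        normalized=True,
        meta={"n_hours": n, "pooling_weight": pooling_weight, "sigma": sigma},
    )


def combine_maps(pressure_map: LikelihoodMap | None, light_map: LikelihoodMap | None) -> LikelihoodMap:
    """Cell-wise product of pressure and light maps (independence), renormalized.

    With one source disabled the combined map degenerates to the other
    exactly.
    """
    if pressure_map is None and light_map is None:
        raise ValueError("need at least one source map")
    if pressure_map is None:
        out = light_map.normalize()
        return LikelihoodMap(out.period_id, "combined", out.values, True, dict(out.meta))
    if light_map is None:
        out = pressure_map.normalize()
        return LikelihoodMap(out.period_id, "combined", out.values, True, dict(out.meta))
    if pressure_map.values.shape != light_map.values.shape:
        raise ValueError("map shapes differ")
    prod = pressure_map.values * light_map.values
    if prod.sum() <= 0:
        raise ValueError(f"period {pressure_map.period_id}: pressure and light maps have disjoint support")
    return LikelihoodMap(pressure_map.period_id, "combined", prod, normalized=True)
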