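"""Light-level geolocation: twilight detection, zenith calibration, likelihood maps.

The light channel carries positional information only through the *times* of
sunrise and sunset.  At a known calibration site (the breeding territory
during the equipment and retrieval windows) the solar zenith angle at each
detected twilight is computed; the spread of those angles — shading, sensor
threshold, habitat — is summarized by a kernel density estimate.  For an
unknown period, each twilight scores every grid cell by the calibrated
density evaluated at the zenith angle the sun would have had at that cell at
the twilight time.  The per-twilight maps of one stationary period are
aggregated by log-linear pooling with weight 1/k (the geometric mean), which
keeps a period's map from sharpening artificially as more correlated
twilights accumulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from .io import GriddedAtmosphere, LoggerSeries
from .pressure import LikelihoodMap
from .solar import solar_zenith

__all__ = [
    "TwilightSet",
    "ZenithCalibration",
    "detect_twilights",
    "calibrate_zenith",
    "light_likelihood_map",
]

MIN_CALIBRATION_TWILIGHTS = 10


@dataclass
class TwilightSet:
    """Detected sunrise/sunset events: DataFrame with columns time (UTC), kind."""

    events: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        ev = self.events.reset_index(drop=True)
        if not ev.empty:
            if not ev["time"].is_monotonic_increasing:
                raise ValueError("twilight times must be strictly increasing")
            if ev["time"].duplicated().any():
                raise ValueError("duplicate twilight times")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def between(self, start, end) -> "TwilightSet":
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start.tz is None:
            start = start.tz_localize("UTC")
        if end.tz is None:
            end = end.tz_localize("UTC")
        m = (self.events["time"] >= start) & (self.events["time"] < end)
        return TwilightSet(self.events[m], self.threshold)


def detect_twilights(series: LoggerSeries, threshold: float) -> TwilightSet:
    """Threshold-crossing twilight detection with linear interpolation.

    An upward crossing of ``threshold`` is a sunrise, a downward crossing a
    sunset.  Days where light never crosses the threshold yield no events.
    """
    if series.light is None:
        raise ValueError("series has no light channel")
    light = np.asarray(series.light, dtype=float)
    ts = series.timestamps
    above = light > threshold
    flips = np.flatnonzero(above[1:] != above[:-1])
    rows = []
    for k in flips:
        l0, l1 = light[k], light[k + 1]
        frac = 0.5 if l1 == l0 else (threshold - l0) / (l1 - l0)
        t = ts[k] + frac * (ts[k + 1] - ts[k])
        rows.append({"time": t, "kind": "sunrise" if above[k + 1] else "sunset"})
    events = pd.DataFrame(rows, columns=["time", "kind"])
    return TwilightSet(events, threshold)


class ZenithCalibration:
    """KDE over the zenith angles observed at calibration twilights.

    Gaussian kernel; bandwidth by Silverman's rule unless ``bandwidth``
    (degrees) is given.  The density integrates to one over the real line.
    """

    def __init__(self, samples: np.ndarray, bandwidth: float | None = None):
        samples = np.asarray(samples, dtype=float)
        if len(samples) < 2:
            raise ValueError("need at least two calibration zenith angles")
        self.samples = samples
        sd = samples.std(ddof=1)
        if sd > 0:
            bw_method = "silverman" if bandwidth is None else bandwidth / sd
            self._kde = gaussian_kde(samples, bw_method=bw_method)
            self.bandwidth = float(np.sqrt(self._kde.covariance[0, 0]))
        else:
            # degenerate cluster: single Gaussian at the common angle
            self._kde = None
            self.bandwidth = bandwidth if bandwidth is not None else 0.5

    def __call__(self, zenith) -> np.ndarray:
        z = np.asarray(zenith, dtype=float)
        if self._kde is not None:
            out = self._kde(z.ravel()).reshape(z.shape)
        else:
            out = norm.pdf(z, loc=self.samples[0], scale=self.bandwidth)
        return out if out.ndim else float(out)


def calibrate_zenith(
    twilights: TwilightSet,
    site_lat: float,
    site_lon: float,
    bandwidth: float | None = None,
) -> ZenithCalibration:
    """Fit the zenith-angle distribution at a known site from calibration twilights."""
    if len(twilights) < MIN_CALIBRATION_TWILIGHTS:
        raise ValueError(
            f"need >= {MIN_CALIBRATION_TWILIGHTS} calibration twilights, got {len(twilights)}"
        )
    z = solar_zenith(twilights.events["time"].to_numpy(), site_lat, site_lon)
    return ZenithCalibration(np.atleast_1d(z), bandwidth=bandwidth)


def light_likelihood_map(
    twilights: TwilightSet,
    calibration: ZenithCalibration,
    atmosphere: GriddedAtmosphere,
    period_id: int = 0,
) -> LikelihoodMap:
    """Log-linearly pooled light likelihood map of one stationary period.

    Per twilight the cell likelihood is the calibration density at the solar
    zenith of the cell center at the event time; the k per-twilight maps are
    pooled as ``exp((1/k) * sum(log density))`` and normalized.  If the pooled
    map has no support the map degenerates to uniform with a warning.
    """
    if len(twilights) < 1:
        raise ValueError("need at least one twilight")
    lat2d, lon2d = np.meshgrid(atmosphere.lats, atmosphere.lons, indexing="ij")
    k = len(twilights)
    logsum = np.zeros(lat2d.shape)
    with np.errstate(divide="ignore"):
        for t in twilights.events["time"]:
            z = solar_zenith(np.full(lat2d.size, t, dtype="object"), lat2d.ravel(), lon2d.ravel())
            dens = calibration(np.asarray(z).reshape(lat2d.shape))
            logsum += np.log(dens)
    pooled = logsum / k
    if not np.isfinite(pooled).any():
        warnings.warn(f"period {period_id}: light map has zero density everywhere; using uniform")
        values = np.ones(lat2d.shape)
    else:
        pooled = pooled - pooled[np.isfinite(pooled)].max()
        values = np.where(np.isfinite(pooled), np.exp(pooled), 0.0)
        if values.sum() <= 0:
            warnings.warn(f"period {period_id}: light map has zero mass; using uniform")
            values = np.ones(lat2d.shape)
    return LikelihoodMap(period_id, "light", values, normalized=True, meta={"n_twilights": k})
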