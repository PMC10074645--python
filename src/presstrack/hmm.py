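"""Grid-state HMM over stationary periods: model and results objects.

States are grid cells; one HMM step per stationary period; the emission of a
period is its (combined) likelihood map; the transition kernel between two
consecutive periods comes from the airspeed movement model with the pooled
duration of the intervening flights and the mean wind.  Inference is exact:
scaled forward-backward for the per-period marginal maps, Viterbi for the
most-likely trajectory, and backward sampling from the exact posterior for
trajectory simulations.

The public surface follows the model/results pattern:

>>> model = TrajectoryModel(emissions, transitions=mats)
>>> res = model.fit()
>>> res.marginals, res.mlp_cells, res.sample_paths(100, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GriddedAtmosphere
from .movement import MovementModel, transition_matrix
from .pressure import LikelihoodMap

__all__ = [
    "TrajectoryModel",
    "TrajectoryResults",
    "forward_backward",
    "most_likely_path",
    "sample_paths",
    "credible_region",
]


def _as_flat_emissions(emissions) -> tuple[list[np.ndarray], tuple]:
    mats = []
    shape = None
    for k, e in enumerate(emissions):
        arr = e.values if isinstance(e, LikelihoodMap) else np.asarray(e, dtype=float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError("all emission maps must share one shape")
        if (arr < 0).any():
            raise ValueError("emissions must be nonnegative")
        if arr.sum() <= 0:
            raise ValueError(f"period {k}: emission map is all zero")
        mats.append(arr.ravel())
    if not mats:
        raise ValueError("need at least one period")
    return mats, shape


def forward_backward(emissions, transitions) -> list[np.ndarray]:
    """Exact per-period posterior marginals (scaled forward-backward).

    ``emissions``: sequence of T nonnegative arrays (any common shape);
    ``transitions``: sequence of T-1 row-stochastic (K, K) matrices.
    Returns T marginal arrays in the emission shape, each summing to one.
    """
    ems, shape = _as_flat_emissions(emissions)
    T = len(ems)
    if len(transitions) != T - 1:
        raise ValueError("need exactly T-1 transition matrices")
    alphas = _forward(ems, transitions)
    beta = np.ones_like(ems[-1])
    marginals = [None] * T
    marginals[T - 1] = alphas[T - 1] / alphas[T - 1].sum()
    for t in range(T - 2, -1, -1):
        trans = np.asarray(transitions[t], dtype=float)
        beta = trans @ (ems[t + 1] * beta)
        s = beta.sum()
        if s <= 0:
            raise ValueError(f"period {t}: zero posterior mass (disjoint supports)")
        beta = beta / s
        g = alphas[t] * beta
        marginals[t] = g / g.sum()
    return [m.reshape(shape) for m in marginals]


def _forward(ems: list[np.ndarray], transitions) -> list[np.ndarray]:
    alphas = []
    alpha = ems[0] / ems[0].sum()
    alphas.append(alpha)
    for t in range(1, len(ems)):
        trans = np.asarray(transitions[t - 1], dtype=float)
        alpha = (alpha @ trans) * ems[t]
        s = alpha.sum()
        if s <= 0:
            raise ValueError(f"period {t}: zero forward mass (check emission/transition supports)")
        alpha = alpha / s
        alphas.append(alpha)
    return alphas


def most_likely_path(emissions, transitions) -> np.ndarray:
    """Viterbi argmax path as flat state indices (ties -> lowest index)."""
    ems, _shape = _as_flat_emissions(emissions)
    T = len(ems)
    if len(transitions) != T - 1:
        raise ValueError("need exactly T-1 transition matrices")
    with np.errstate(divide="ignore"):
        delta = np.log(ems[0] / ems[0].sum())
        back = []
        for t in range(1, T):
            logtrans = np.log(np.asarray(transitions[t - 1], dtype=float))
            cand = delta[:, None] + logtrans
            back.append(np.argmax(cand, axis=0))
            delta = cand[back[-1], np.arange(cand.shape[1])] + np.log(ems[t])
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t][path[t + 1]]
    return path


def sample_paths(emissions, transitions, n_sim: int = 100, seed=None) -> np.ndarray:
    """Backward sampling of ``n_sim`` paths from the exact posterior.

    Returns an (n_sim, T) array of flat state indices, reproducible under a
    fixed ``seed``.
    """
    ems, _shape = _as_flat_emissions(emissions)
    T = len(ems)
    rng = np.random.default_rng(seed)
    alphas = _forward(ems, transitions)
    out = np.empty((n_sim, T), dtype=int)
    pT = alphas[-1] / alphas[-1].sum()
    out[:, T - 1] = rng.choice(len(pT), size=n_sim, p=pT)
    for t in range(T - 2, -1, -1):
        trans = np.asarray(transitions[t], dtype=float)
        for s in np.unique(out[:, t + 1]):
            rows = out[:, t + 1] == s
            p = alphas[t] * trans[:, s]
            p = p / p.sum()
            out[rows, t] = rng.choice(len(p), size=int(rows.sum()), p=p)
    return out


def credible_region(marginal: np.ndarray, q: float = 0.99) -> np.ndarray:
    """Smallest set of highest-probability cells with cumulative mass >= q.

    Returns a boolean mask in the marginal's shape.
    """
    m = np.asarray(marginal, dtype=float)
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    flat = m.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, q * flat.sum() - 1e-12)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(m.shape)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class TrajectoryModel:
    """HMM trajectory model over the atmosphere grid.

    Parameters
    ----------
    emissions : sequence of LikelihoodMap or array
        One per stationary period, in temporal order.
    transitions : sequence of (K, K) array, optional
        Pre-built transition matrices.  If omitted, they are built from
        ``flights`` (list of dicts with keys ``duration_h``, ``start``,
        ``end``), ``atmosphere`` and ``movement``; consecutive flight
        segments between two stationary periods must already be pooled into
        one entry with their summed duration.
    atmosphere : GriddedAtmosphere, optional
        Supplies the grid geometry and the wind for transition building.
    movement : MovementModel, optional
    max_ground_speed_kmh : float
        Transitions implying a faster ground speed are pruned.
    """

    def __init__(
        self,
        emissions,
        transitions=None,
        flights=None,
        atmosphere: GriddedAtmosphere | None = None,
        movement: MovementModel | None = None,
        max_ground_speed_kmh: float = 150.0,
    ):
        self.emission_maps = list(emissions)
        self._ems, self.grid_shape = _as_flat_emissions(self.emission_maps)
        self.movement = movement or MovementModel()
        self.atmosphere = atmosphere
        self.max_ground_speed_kmh = max_ground_speed_kmh
        if transitions is not None:
            self.transitions = [np.asarray(t, dtype=float) for t in transitions]
        else:
            if flights is None or atmosphere is None:
                raise ValueError("either transitions or (flights and atmosphere) required")
            if len(flights) != len(self.emission_maps) - 1:
                raise ValueError("need one pooled flight per pair of consecutive periods")
            self.transitions = self._build_transitions(flights)
        if len(self.transitions) != len(self.emission_maps) - 1:
            raise ValueError("need exactly T-1 transition matrices")

    def _build_transitions(self, flights) -> list[np.ndarray]:
        atm = self.atmosphere
        mats = []
        for k, fl in enumerate(flights):
            dur = float(fl["duration_h"])
            cells = []
            for m in (self.emission_maps[k], self.emission_maps[k + 1]):
                arr = m.values if isinstance(m, LikelihoodMap) else np.asarray(m)
                i, j = np.unravel_index(int(np.argmax(arr)), self.grid_shape)
                cells.append((int(i), int(j)))
            wind = (0.0, 0.0)
            if "start" in fl and "end" in fl:
                wind = atm.wind_mean(fl["start"], fl["end"], cells)
            mats.append(
                transition_matrix(
                    atm.lats,
                    atm.lons,
                    dur,
                    wind_uv_ms=wind,
                    model=self.movement,
                    max_ground_speed_kmh=self.max_ground_speed_kmh,
                )
            )
        return mats

    def fit(self) -> "TrajectoryResults":
        """Run exact inference; returns a :class:`TrajectoryResults`."""
        marginals = forward_backward(self.emission_maps, self.transitions)
        mlp = most_likely_path(self.emission_maps, self.transitions)
        return TrajectoryResults(model=self, marginals=marginals, mlp_flat=mlp)


@dataclass
class TrajectoryResults:
    """Marginal maps, most-likely path, samplers and credible regions."""

    model: TrajectoryModel
    marginals: list[np.ndarray]
    mlp_flat: np.ndarray
    _sample_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_periods(self) -> int:
        return len(self.marginals)

    @property
    def mlp_cells(self) -> list[tuple[int, int]]:
        shape = self.model.grid_shape
        if len(shape) == 1:
            return [(int(s),) for s in self.mlp_flat]
        return [tuple(int(x) for x in np.unravel_index(s, shape)) for s in self.mlp_flat]

    @property
    def mlp_latlon(self) -> list[tuple[float, float]]:
        atm = self.model.atmosphere
        if atm is None:
            raise ValueError("no atmosphere attached; cell centers unknown")
        return [atm.cell_center(i, j) for i, j in self.mlp_cells]

    def sample_paths(self, n_sim: int = 100, seed=None) -> np.ndarray:
        return sample_paths(self.model.emission_maps, self.model.transitions, n_sim, seed)

    def credible_region(self, period: int, q: float = 0.99) -> np.ndarray:
        return credible_region(self.marginals[period], q)

    def summary(self, q: float = 0.99) -> pd.DataFrame:
        """Per-period table: MLP cell (and lat/lon), peak marginal mass, CR size."""
        rows = []
        atm = self.model.atmosphere
        for t, (m, cell) in enumerate(zip(self.marginals, self.mlp_cells)):
            row = {
                "period": t,
                "mlp_cell": cell,
                "marginal_max": float(m.max()),
                "mlp_marginal": float(m[cell] if len(cell) > 1 else m[cell[0]]),
                f"cr{int(q * 100)}_cells": int(self.credible_region(t, q).sum()),
            }
            if atm is not None and len(cell) == 2:
                row["lat"], row["lon"] = atm.cell_center(*cell)
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_marginal(self, period: int, ax=None, **kwargs):
        """Diagnostic plot of one period's marginal map with the MLP cell marked."""
        atm = self.model.atmosphere
        if atm is None:
            raise ValueError("plotting needs an attached atmosphere grid")
        m = LikelihoodMap(period, "combined", self.marginals[period])
        ax = m.plot(atm, ax=ax, **kwargs)
        lat, lon = atm.cell_center(*self.mlp_cells[period])
        ax.plot(lon, lat, "r+", markersize=12)
        return ax

    def to_path_frame(self, periods: pd.DataFrame | None = None) -> pd.DataFrame:
        """MLP as a tidy CSV-ready frame (period_id, lat, lon)."""
        atm = self.model.atmosphere
        rows = []
        for t, cell in enumerate(self.mlp_cells):
            lat, lon = (atm.cell_center(*cell) if atm is not None else (np.nan, np.nan))
            row = {"period_id": t + 1, "lat": lat, "lon": lon}
            if periods is not None and t < len(periods):
                row["start_utc"] = periods.iloc[t]["start"]
                row["end_utc"] = periods.iloc[t]["end"]
            rows.append(row)
        return pd.DataFrame(rows)
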