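"""Fixed-grid functional data: ERP-like epochs on a common time grid.

Provides the in-memory containers for sets of curves sampled on a
uniform grid (by default 226 points on [-0.05, 0.4] s, i.e. 500 Hz over
a 0.45 s epoch), plus the elementary operations the clustering pipeline
needs: baseline correction, pointwise averaging over electrode sets,
Fraiman-Muniz depth with outlier trimming, Brownian-bridge sampling and
projection (L2 inner products) of curves onto bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TimeGrid",
    "FunctionalSet",
    "BridgeSample",
    "baseline_correct",
    "average_channels",
    "fm_depth",
    "trim_outliers",
    "sample_bridge",
    "sample_bridges",
    "project",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid ``t0, t0+dt, ..., t1`` in seconds."""

    t0: float = -0.05
    t1: float = 0.4
    n_points: int = 226

    def __post_init__(self):
        if not self.t0 < self.t1:
            raise ValueError("t0 must be smaller than t1")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def dt(self) -> float:
        return (self.t1 - self.t0) / (self.n_points - 1)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t0, self.t1, self.n_points)


@dataclass(frozen=True)
class FunctionalSet:
    """A set of curves sharing one :class:`TimeGrid`.

    ``values`` has one row per curve and one column per grid point.
    ``label`` typically carries the three-symbol stimulus string the
    curves respond to, ``subject`` the participant identifier.
    """

    grid: TimeGrid
    values: np.ndarray
    label: str | None = None
    subject: str | None = None

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[0] < 1:
            raise ValueError("values must be a 2-d array with at least one row")
        if vals.shape[1] != self.grid.n_points:
            raise ValueError(
                f"values has {vals.shape[1]} columns but the grid has "
                f"{self.grid.n_points} points"
            )

    @property
    def n_curves(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class BridgeSample:
    """One Brownian-bridge realisation on a grid; endpoints are exactly 0."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid.n_points,):
            raise ValueError("bridge values must be a vector on the grid")
        if vals[0] != 0.0 or vals[-1] != 0.0:
            raise ValueError("bridge endpoints must be exactly 0")


def baseline_correct(
    curves: FunctionalSet, window: tuple[float, float] = (-0.05, 0.0)
) -> FunctionalSet:
    """Subtract from each curve its mean over the half-open ``[t_a, t_b)``.

    The default window is the 50 ms immediately preceding stimulus onset.
    """
    t_a, t_b = window
    t = curves.grid.times
    mask = (t >= t_a) & (t < t_b)
    if not mask.any():
        raise ValueError(f"baseline window [{t_a}, {t_b}) contains no grid points")
    means = curves.values[:, mask].mean(axis=1, keepdims=True)
    return replace(curves, values=curves.values - means)


def average_channels(sets: list[FunctionalSet]) -> FunctionalSet:
    """Pointwise mean across electrode channels, row by row.

    Implements the electrode-set average ``Y_n = (1/|E|) sum_e Y_n^e``:
    the inputs must be row-aligned (the i-th row of every set is the
    same epoch recorded on a different channel).
    """
    if not sets:
        raise ValueError("need at least one functional set")
    first = sets[0]
    for s in sets[1:]:
        if s.grid != first.grid or s.values.shape != first.values.shape:
            raise ValueError("all sets must share grid and shape")
    mean = np.mean([s.values for s in sets], axis=0)
    return replace(first, values=mean)


def fm_depth(curves: FunctionalSet) -> np.ndarray:
    """Fraiman-Muniz functional depth of each curve within its set.

    At every grid time ``t`` the univariate depth of curve ``i`` is
    ``D_i(t) = 1 - |1/2 - F_t(Y_i(t))|`` where ``F_t`` is the
    right-continuous empirical CDF of the curve values at ``t`` (ties
    counted with <=).  The functional depth is the discrete integral
    (mean over grid points) of ``D_i(t)``.  Central curves score high;
    an extreme artifact curve attains the minimum.
    """
    vals = curves.values
    n = vals.shape[0]
    if n < 2:
        raise ValueError("depth needs at least 2 curves")
    # right-continuous ECDF value of each entry within its column
    ecdf = rankdata(vals, method="max", axis=0) / n
    pointwise = 1.0 - np.abs(0.5 - ecdf)
    return pointwise.mean(axis=1)


def trim_outliers(curves: FunctionalSet, fraction: float = 0.10) -> FunctionalSet:
    """Remove the ``floor(fraction * n)`` most outlying curves.

    Outlyingness is measured by :func:`fm_depth` (lowest depth removed
    first).  Ties are broken by original row order: among equally deep
    curves the earlier row is kept.  Row order of the survivors is
    preserved.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = curves.n_curves
    k = int(np.floor(fraction * n))
    if k == 0:
        return curves
    depth = fm_depth(curves)
    # sort by depth ascending, ties by index descending -> the first k
    # positions are the rows to drop
    order = np.lexsort((-np.arange(n), depth))
    drop = np.zeros(n, dtype=bool)
    drop[order[:k]] = True
    return replace(curves, values=curves.values[~drop])


def sample_bridges(
    grid: TimeGrid, n_bridges: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw ``n_bridges`` independent Brownian bridges on ``grid``.

    Returns an ``(n_bridges, n_points)`` array.  Each bridge is built
    from cumulative Gaussian increments of variance ``dt`` pinned to 0
    at both ends by subtracting the linear interpolant of the terminal
    value; on the grid this is exact in distribution, with covariance
    ``Cov(B(s), B(t)) = (min(s,t) - t0)(t1 - max(s,t)) / (t1 - t0)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = grid.n_points
    inc = rng.standard_normal((n_bridges, n - 1)) * np.sqrt(grid.dt)
    walk = np.concatenate([np.zeros((n_bridges, 1)), np.cumsum(inc, axis=1)], axis=1)
    frac = (grid.times - grid.t0) / (grid.t1 - grid.t0)
    bridges = walk - walk[:, -1:] * frac
    bridges[:, 0] = 0.0
    bridges[:, -1] = 0.0
    return bridges


def sample_bridge(grid: TimeGrid, seed: int | None = None) -> BridgeSample:
    """One Brownian-bridge realisation (see :func:`sample_bridges`)."""
    return BridgeSample(grid, sample_bridges(grid, 1, seed)[0])


def project(curves: FunctionalSet, bridge: BridgeSample) -> np.ndarray:
    """Project every curve onto a bridge: the inner product ``<Y, B>``.

    The integral over ``[t0, t1]`` is approximated by the Riemann sum
    ``sum_k Y(t_k) B(t_k) dt`` (the bridge vanishes at both endpoints,
    so left and right sums coincide).  Returns one real per curve.
    """
    if curves.grid != bridge.grid:
        raise ValueError("curves and bridge must share the same grid")
    return curves.values @ bridge.values * curves.grid.dt
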