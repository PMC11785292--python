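"""Projective dissimilarity between sets of curves.

Two sets of curves are compared by projecting both onto M independent
Brownian bridges and, for each bridge, running a two-sample
Kolmogorov-Smirnov test on the two samples of projections at level
``alpha``.  The empirical dissimilarity is the fraction of bridges on
which the test rejects:

    dhat = (1/M) sum_j 1{ ||F_A,Bj - F_B,Bj||_inf > delta(|A|, |B|) }

where ``delta`` is the two-sided two-sample Smirnov critical value.
Two sets drawn from the same law give a small dhat; sets with different
laws give dhat near 1 for large samples.  The dendrogram cut threshold
``gamma`` is calibrated as a binomial quantile: the ``nu``-quantile of
Binomial(M, beta) divided by M, i.e. an upper bound on the fraction of
false rejections one would see if the per-bridge tests were independent
level-``beta`` tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import binom

from ._ward_null import ks_sorted_batch
from .functional import FunctionalSet, sample_bridges

__all__ = [
    "TestConfig",
    "DissimilarityMatrix",
    "ks_statistic",
    "ks_threshold",
    "gamma_threshold",
    "empirical_dissimilarity",
    "pairwise_matrix",
]


@dataclass(frozen=True)
class TestConfig:
    """Parameters of the projective two-sample procedure.

    n_projections : number of Brownian bridges M per pair (default 5000).
    alpha : level of each per-bridge KS test.
    beta : binomial success parameter used to calibrate gamma.
    nu : binomial quantile level used to calibrate gamma.
    seed : root seed; per-pair bridge streams are derived from it.
    threshold_rule : "smirnov" for the standard two-sided bound
        sqrt(ln(2/alpha)/2 * (n+m)/(nm)); "loose" for the variant
        without the factor 1/2 (sensitivity analysis only).
    shared_bridges : if True, one bridge ensemble is drawn per matrix
        and reused for every pair (each set is projected once); if
        False (default) every pair gets fresh independent bridges.
    """

    n_projections: int = 5000
    alpha: float = 0.05
    beta: float = 0.05
    nu: float = 0.95
    seed: int | None = None
    threshold_rule: str = "smirnov"
    shared_bridges: bool = False

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        for name in ("alpha", "beta", "nu"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.threshold_rule not in ("smirnov", "loose"):
            raise ValueError("threshold_rule must be 'smirnov' or 'loose'")


TestConfig.__test__ = False  # not a pytest class despite the name


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A symmetric matrix of dissimilarities over labelled items."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if not np.allclose(vals, vals.T):
            raise ValueError("dissimilarity matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy linkage input)."""
        return squareform(self.values, checks=False)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def _ks_batch(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """Columnwise two-sample KS statistics.

    ``za`` is (n_a, M), ``zb`` is (n_b, M); column j holds the two
    projection samples for bridge j.  Returns the M statistics
    ``sup_t |F_a(t) - F_b(t)|`` over the pooled points, with
    right-continuous ECDFs (at tied values the difference is evaluated
    after all tied observations).
    """
    na, nb = za.shape[0], zb.shape[0]
    pooled = np.concatenate([za, zb], axis=0)
    weights = np.concatenate([np.full(na, 1.0 / na), np.full(nb, -1.0 / nb)])
    order = np.argsort(pooled, axis=0, kind="stable")
    vals = np.take_along_axis(pooled, order, axis=0)
    cum = np.cumsum(weights[order], axis=0)
    last_of_run = np.ones(cum.shape, dtype=bool)
    last_of_run[:-1] = vals[:-1] != vals[1:]
    return np.max(np.abs(np.where(last_of_run, cum, 0.0)), axis=0)


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic ``sup |F_a - F_b|``."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(_ks_batch(a[:, None], b[:, None])[0])


def ks_threshold(n: int, m: int, alpha: float, rule: str = "smirnov") -> float:
    """Two-sided two-sample Smirnov critical value at level ``alpha``.

    ``sqrt(ln(2/alpha)/2 * (n+m)/(n*m))``; for n = m this reduces to
    ``sqrt(ln(2/alpha)/n)``.  The "loose" rule drops the factor 1/2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    scale = 0.5 if rule == "smirnov" else 1.0
    return float(np.sqrt(np.log(2.0 / alpha) * scale * (n + m) / (n * m)))


def gamma_threshold(cfg: TestConfig) -> float:
    """Dendrogram cut height gamma = q / M.

    ``q`` is the smallest integer k with ``BinomialCDF(k; M, beta) >= nu``
    (the left-continuous binomial quantile).  At the defaults
    (M=5000, beta=0.05, nu=0.95) this gives 276/5000.
    """
    q = int(binom.ppf(cfg.nu, cfg.n_projections, cfg.beta))
    return q / cfg.n_projections


def _dissimilarity_from_projections(
    za: np.ndarray, zb: np.ndarray, delta: float
) -> float:
    return float(np.mean(_ks_batch(za, zb) > delta))


def empirical_dissimilarity(
    a: FunctionalSet,
    b: FunctionalSet,
    cfg: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical projective dissimilarity between two sets of curves.

    Draws ``cfg.n_projections`` Brownian bridges (the same bridge is
    applied to both sets within a projection), projects every curve of
    each set onto each bridge and returns the fraction of bridges whose
    two-sample KS statistic exceeds the Smirnov threshold for the two
    set sizes.  Warns when the threshold is >= 1, in which case no
    projection can ever reject (samples too small at this level).
    """
    if a.grid != b.grid:
        raise ValueError("both sets must share the same grid")
    delta = ks_threshold(a.n_curves, b.n_curves, cfg.alpha, cfg.threshold_rule)
    if delta >= 1.0:
        warnings.warn(
            f"KS threshold {delta:.3f} >= 1 at sizes ({a.n_curves}, {b.n_curves}): "
            "the projective test is powerless at these sample sizes",
            UserWarning,
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bridges = sample_bridges(a.grid, cfg.n_projections, rng)
    dt = a.grid.dt
    za = a.values @ bridges.T * dt
    zb = b.values @ bridges.T * dt
    return _dissimilarity_from_projections(za, zb, delta)


def _pair_rng(root_seed: int | None, i: int, j: int) -> np.random.Generator:
    """Fresh generator for the pair (i, j), deterministic in the root seed."""
    if root_seed is None:
        return np.random.default_rng()
    entropy = [int(root_seed) & 0x7FFFFFFF, i, j]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def pairwise_matrix(
    sets: Mapping[str, FunctionalSet], cfg: TestConfig = TestConfig()
) -> DissimilarityMatrix:
    """Dissimilarity matrix over all unordered pairs of labelled sets.

    Labels are sorted; the diagonal is 0.  With ``cfg.shared_bridges``
    False (default) every pair uses an independent bridge ensemble whose
    seed is derived deterministically from ``cfg.seed`` and the pair
    indices; with True a single ensemble is drawn once and every set is
    projected onto it exactly once.
    """
    labels = sorted(sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 sets")
    grid = sets[labels[0]].grid
    for lab in labels:
        if sets[lab].grid != grid:
            raise ValueError("all sets must share the same grid")
    n = len(labels)
    out = np.zeros((n, n))
    if cfg.shared_bridges:
        rng = _pair_rng(cfg.seed, 0, 0)
        bridges = sample_bridges(grid, cfg.n_projections, rng)
        dt = grid.dt
        # per set: project once onto the shared ensemble, pre-sort per bridge
        proj = {
            lab: np.ascontiguousarray(np.sort(sets[lab].values @ bridges.T * dt, axis=0).T)
            for lab in labels
        }
        for i in range(n):
            for j in range(i + 1, n):
                na = sets[labels[i]].n_curves
                nb = sets[labels[j]].n_curves
                delta = ks_threshold(na, nb, cfg.alpha, cfg.threshold_rule)
                if delta >= 1.0:
                    warnings.warn(
                        f"KS threshold >= 1 for pair ({labels[i]}, {labels[j]})",
                        UserWarning,
                        stacklevel=2,
                    )
                ks = ks_sorted_batch(proj[labels[i]], proj[labels[j]])
                out[i, j] = out[j, i] = float(np.mean(ks > delta))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                rng = _pair_rng(cfg.seed, i + 1, j + 1)
                d = empirical_dissimilarity(sets[labels[i]], sets[labels[j]], cfg, rng)
                out[i, j] = out[j, i] = d
    return DissimilarityMatrix(tuple(labels), out)
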