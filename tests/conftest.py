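import numpy as np
import pytest

from sambaclust import (
    CohortConfig,
    FunctionalSet,
    TimeGrid,
    simulate_cohort,
    strong_beat_partition,
)


@pytest.fixture(scope="session")
def pstar():
    return strong_beat_partition()


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def small_grid():
    """A coarse grid for cheap covariance / quadrature checks."""
    return TimeGrid(t0=-0.05, t1=0.4, n_points=24)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort (7 subjects)."""
    cfg = CohortConfig(n_subjects=7, n_steps=2500, seed=2024)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


def gp_curves(grid: TimeGrid, n: int, rng: np.random.Generator,
              length: float = 0.015, scale: float = 1.0,
              mean: np.ndarray | None = None) -> FunctionalSet:
    """Draw n curves from a smooth stationary Gaussian process."""
    t = grid.times
    k = scale**2 * np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * length**2))
    vals, vecs = np.linalg.eigh(k)
    keep = vals > 1e-12 * vals.max()
    factor = (vecs[:, keep] * np.sqrt(vals[keep])).T
    curves = rng.standard_normal((n, factor.shape[0])) @ factor
    if mean is not None:
        curves = curves + mean
    return FunctionalSet(grid, curves)
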