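"""Synthetic cohort generator: stimulus chains plus ERP-like epochs.

Generates, for each of ``n_subjects`` participants, a stimulus sequence
from the samba chain and one curve per epoch (index n >= 2), where the
curve's mean shape depends only on the block of the reference partition
P* that contains the epoch's three-symbol window.  This reproduces
exactly the structural assumption the clustering pipeline tests -- that
the law of an epoch is a function of the strong-beat position -- so the
pipeline can be exercised end to end without any recordings.

Curve model (amplitudes in arbitrary microvolt-like units)::

    Y_n(t) = a_v * template_{P*(u_n)}(t) + noise_n(t)

with ``a_v`` a per-subject amplitude factor, the templates sums of
Gaussian bumps with class-specific latencies and amplitudes (an N1/P2
morphology), and ``noise_n`` a stationary squared-exponential Gaussian
process.  With probability ``artifact_rate`` an epoch is replaced by a
large-amplitude smooth drift, emulating eye-movement artifacts, to
exercise depth trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .functional import FunctionalSet, TimeGrid
from .partition import Partition
from .stimulus import label_windows, simulate_chain, strong_beat_partition

__all__ = ["CohortConfig", "default_templates", "simulate_subject", "simulate_cohort"]


def default_templates(grid: TimeGrid) -> np.ndarray:
    """Class-conditional mean curves, one per block of P*.

    Each template is a sum of Gaussian bumps mimicking an auditory ERP
    (an early negative deflection followed by a later positive one),
    with latencies and amplitudes that differ clearly across the four
    strong-beat classes.  Rows follow the canonical P* block order
    (no strong beat, strong beat first / second / third).
    """
    t = grid.times

    def bump(center, width):
        return np.exp(-((t - center) ** 2) / (2.0 * width**2))

    return np.stack(
        [
            -3.0 * bump(0.10, 0.03) + 2.0 * bump(0.22, 0.05),
            -6.0 * bump(0.09, 0.03) + 5.0 * bump(0.20, 0.05),
            -4.5 * bump(0.13, 0.035) + 3.0 * bump(0.26, 0.05),
            2.0 * bump(0.08, 0.03) - 3.5 * bump(0.18, 0.04) + 1.5 * bump(0.30, 0.05),
        ]
    )


@dataclass(frozen=True)
class CohortConfig:
    """Conditions for the synthetic cohort.

    n_subjects : cohort size (19, the number of study participants).
    n_steps : stimulus-chain transitions per subject.  5000 makes the
        rarest of the 12 strings (chain frequency 0.01) appear about 50
        times, so every string-set supports the two-sample test.
    grid : epoch time grid (0.45 s at 500 Hz).
    class_templates : optional (4, n_points) array of mean curves per
        P* block; defaults to :func:`default_templates`.
    noise_scale : marginal standard deviation of the Gaussian-process
        noise.  1.0 against template amplitudes of 2-6 gives clearly
        separated classes.
    noise_smoothness : correlation length (s) of the squared-exponential
        noise kernel; 0.015 s roughly matches the smoothness of 1-30 Hz
        band-passed EEG sampled at 500 Hz.
    subject_jitter : half-width of the uniform per-subject amplitude
        factor ``a_v ~ Uniform(1 - j, 1 + j)``.
    artifact_rate : probability an epoch is replaced by an artifact.
    artifact_scale : amplitude of artifact drifts (10x the signal).
    seed : root seed; per-subject streams are derived from it.
    """

    n_subjects: int = 19
    n_steps: int = 5000
    grid: TimeGrid = field(default_factory=TimeGrid)
    class_templates: np.ndarray | None = None
    noise_scale: float = 1.0
    noise_smoothness: float = 0.015
    subject_jitter: float = 0.15
    artifact_rate: float = 0.02
    artifact_scale: float = 50.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")

    def templates(self) -> np.ndarray:
        if self.class_templates is not None:
            tpl = np.asarray(self.class_templates, dtype=float)
            if tpl.shape != (4, self.grid.n_points):
                raise ValueError("class_templates must have shape (4, n_points)")
            return tpl
        return default_templates(self.grid)


@lru_cache(maxsize=8)
def _noise_factor(grid: TimeGrid, scale: float, length: float) -> np.ndarray:
    """Low-rank factor A with A.T @ A ~= the squared-exponential kernel.

    Gaussian noise is then ``randn(n, r) @ A``.  The kernel's spectrum
    decays fast, so eigenpairs below a 1e-12 relative threshold are
    dropped.
    """
    t = grid.times
    k = scale**2 * np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * length**2))
    vals, vecs = np.linalg.eigh(k)
    keep = vals > 1e-12 * max(vals.max(), 1e-300)
    return (vecs[:, keep] * np.sqrt(vals[keep])).T


def _subject_rng(seed: int | None, subject_index: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, subject_index])
    )


def simulate_subject(
    cfg: CohortConfig,
    subject_id: str = "s00",
    rng: np.random.Generator | None = None,
) -> dict[str, FunctionalSet]:
    """One participant: a chain plus one curve per epoch, grouped by string.

    Returns a mapping from each three-symbol string to the
    :class:`FunctionalSet` of the epochs labelled by it.
    """
    if rng is None:
        rng = _subject_rng(cfg.seed, 0)
    templates = cfg.templates()
    pstar = strong_beat_partition()
    grid = cfg.grid
    n_pts = grid.n_points

    seq = simulate_chain(cfg.n_steps, seed=int(rng.integers(2**31)))
    windows = label_windows(seq)

    amp = 1.0 + cfg.subject_jitter * rng.uniform(-1.0, 1.0)

    n_epochs = len(windows)
    if cfg.noise_scale > 0:
        factor = _noise_factor(grid, cfg.noise_scale, cfg.noise_smoothness)
        noise = rng.standard_normal((n_epochs, factor.shape[0])) @ factor
    else:
        noise = np.zeros((n_epochs, n_pts))

    order = sorted(windows)  # epoch indices in time order
    block_of = {u: pstar.block_of(u) for u in set(windows.values())}
    block_idx = np.fromiter(
        (block_of[windows[n]] for n in order), dtype=np.intp, count=n_epochs
    )
    curves = amp * templates[block_idx] + noise

    is_artifact = rng.uniform(size=n_epochs) < cfg.artifact_rate
    if is_artifact.any():
        t01 = (grid.times - grid.t0) / (grid.t1 - grid.t0)
        for row in np.flatnonzero(is_artifact):
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            a = cfg.artifact_scale * (0.5 + rng.uniform())
            curves[row] = sign * a * (0.3 + np.sin(np.pi * t01 * rng.uniform(0.5, 1.5)))

    out: dict[str, FunctionalSet] = {}
    rows_by_string: dict[str, list[int]] = {}
    for row, n in enumerate(order):
        rows_by_string.setdefault(windows[n], []).append(row)
    for u, rows in rows_by_string.items():
        out[u] = FunctionalSet(grid, curves[rows], label=u, subject=subject_id)
    return out


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[dict[str, dict[str, FunctionalSet]], Partition]:
    """Independent subjects sharing class templates, plus the ground truth.

    Returns ``(cohort, pstar)`` where ``cohort`` maps subject id to the
    per-string functional sets and ``pstar`` is the generating partition.
    """
    cohort = {}
    for i in range(cfg.n_subjects):
        sid = f"s{i:02d}"
        cohort[sid] = simulate_subject(cfg, sid, _subject_rng(cfg.seed, i))
    return cohort, strong_beat_partition()
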