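"""Monte-Carlo significance of a partition against a reference.

The null hypothesis is that a consensus partition arises purely at
random: a random symmetric dissimilarity matrix with i.i.d. Uniform(0,1)
upper-triangle entries is Ward-clustered and cut at ``k`` clusters, and
the adjusted Rand index (ARI) of the resulting partition with the
reference partition is recorded.  The estimated p-value is the fraction
of null partitions whose ARI with the reference is at least the ARI of
the observed partition (ties count as exceedances).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._ward_null import ari_labels, null_ari_chunk
from .partition import Partition

__all__ = [
    "NullResult",
    "adjusted_rand_index",
    "sample_null_aris",
    "partition_pvalue",
    "matched_item_count",
]

#: slack for the ">=" exceedance count: null and observed ARIs are
#: computed by different code paths, so exact float equality of
#: mathematically equal rationals is not guaranteed
_ARI_TIE_TOL = 1e-12


@dataclass(frozen=True)
class NullResult:
    """Outcome of the Monte-Carlo partition null."""

    observed_ari: float
    n_reps: int
    n_exceed: int
    p_hat: float
    seed: int | None
    k: int
    ward_variant: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Chance-corrected pair-counting similarity in [-1, 1], equal to 1
    exactly when the partitions coincide.  Singleton blocks contribute
    zero pairs (the pair count ``c(j) = C(j, 2)`` vanishes for j < 2).
    """
    if p1.items != p2.items:
        raise ValueError("partitions must share the same ground set")
    order = sorted(p1.items)
    l1 = p1.to_labels(order)
    l2 = p2.to_labels(order)
    return float(ari_labels(l1, l2, p1.n_blocks, p2.n_blocks))


def sample_null_aris(
    reference: Partition,
    k: int,
    n_reps: int,
    seed: int | None = None,
    ward_variant: str = "d2",
    chunk: int = 100_000,
) -> np.ndarray:
    """ARIs of Ward k-cuts of random uniform matrices vs a reference.

    Each replicate draws a symmetric matrix over the reference's ground
    set with i.i.d. Uniform(0, 1) upper-triangle entries (the diagonal
    is irrelevant to linkage), Ward-clusters it (``ward_variant`` "d2"
    or "d"), cuts the tree at ``k`` clusters and records the ARI with
    ``reference``.  Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if ward_variant not in ("d", "d2"):
        raise ValueError("ward_variant must be 'd' or 'd2'")
    n_items = len(reference.items)
    if not 1 <= k <= n_items:
        raise ValueError(f"k must be in [1, {n_items}]")
    ref_labels = reference.to_labels(sorted(reference.items))
    n_pairs = n_items * (n_items - 1) // 2
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    done = 0
    while done < n_reps:
        c = min(chunk, n_reps - done)
        u = rng.uniform(size=(c, n_pairs))
        if ward_variant == "d2":
            u = u**2  # Lance-Williams recurrence on squares == Ward.D2 cut
        out[done : done + c] = null_ari_chunk(u, ref_labels, k, reference.n_blocks)
        done += c
    return out


def partition_pvalue(
    observed: Partition,
    reference: Partition,
    k: int = 4,
    n_reps: int = 1_000_000,
    seed: int | None = None,
    ward_variant: str = "d2",
) -> NullResult:
    """Estimated probability of a null partition at least as close to
    the reference as the observed one.

    ``p_hat = (1/n_reps) * #{i : ARI(null_i, reference) >=
    ARI(reference, observed)}``.
    """
    obs = adjusted_rand_index(reference, observed)
    nulls = sample_null_aris(reference, k, n_reps, seed, ward_variant)
    n_exceed = int(np.sum(nulls >= obs - _ARI_TIE_TOL))
    return NullResult(
        observed_ari=obs,
        n_reps=n_reps,
        n_exceed=n_exceed,
        p_hat=n_exceed / n_reps,
        seed=seed,
        k=k,
        ward_variant=ward_variant,
    )


def matched_item_count(observed: Partition, reference: Partition) -> int:
    """Items classified as expected under the best one-to-one matching.

    Clusters of ``observed`` are matched one-to-one to blocks of
    ``reference`` so as to maximise the total overlap (Hungarian
    assignment); the returned count is the number of items lying in a
    matched pair of clusters.
    """
    if observed.items != reference.items:
        raise ValueError("partitions must share the same ground set")
    overlap = np.zeros((observed.n_blocks, reference.n_blocks), dtype=int)
    for i, b_obs in enumerate(observed.blocks):
        for j, b_ref in enumerate(reference.blocks):
            overlap[i, j] = len(set(b_obs) & set(b_ref))
    rows, cols = linear_sum_assignment(-overlap)
    return int(overlap[rows, cols].sum())
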