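"""Hierarchical clustering of the string-labelled sets and consensus.

Per subject the 12 dissimilarities are agglomerated with complete
linkage and the tree is cut at the fixed height ``gamma``; under
complete linkage this yields the coarsest partition in which every
within-cluster pairwise dissimilarity is below the cut.  Per-subject
partitions are then combined across participants through the
co-clustering consensus matrix and a Ward-linkage pass, with the usual
internal criteria (Calinski-Harabasz, mean silhouette, Dunn index)
reported for candidate cluster counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .dissimilarity import DissimilarityMatrix
from .partition import Partition

__all__ = [
    "Dendrogram",
    "complete_linkage",
    "cut_at_threshold",
    "cut_k",
    "consensus_dissimilarity",
    "ward_partition",
    "cluster_count_criteria",
]


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative merge history over labelled leaves.

    ``merges`` is a scipy linkage matrix: row ``s`` merges the clusters
    with ids ``merges[s, 0]`` and ``merges[s, 1]`` (ids < n are leaves
    in ``labels`` order, id ``n + s`` is the cluster formed at step
    ``s``) at height ``merges[s, 2]``.
    """

    labels: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        z = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", z)
        n = len(self.labels)
        if z.shape != (n - 1, 4):
            raise ValueError("merges must be an (n-1, 4) linkage matrix")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "merges": [
                [int(a), int(b), float(h), int(c)] for a, b, h, c in self.merges
            ],
        }


def complete_linkage(matrix: DissimilarityMatrix) -> Dendrogram:
    """Agglomerate with the maximum pairwise distance between clusters."""
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 items")
    z = linkage(matrix.condensed(), method="complete")
    return Dendrogram(matrix.labels, z)


def cut_k(dend: Dendrogram, k: int) -> Partition:
    """Partition with exactly ``k`` clusters from the dendrogram."""
    if not 1 <= k <= dend.n_leaves:
        raise ValueError(f"k must be in [1, {dend.n_leaves}]")
    labels = fcluster(dend.merges, k, criterion="maxclust")
    return Partition.from_labels(dend.labels, labels)


def cut_at_threshold(dend: Dendrogram, gamma: float) -> Partition:
    """Keep all merges strictly below height ``gamma``.

    Under complete linkage this is the coarsest dendrogram partition in
    which every within-cluster pairwise dissimilarity is < gamma.
    ``gamma = 0`` yields all singletons; a gamma above the last merge
    height yields a single cluster.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    below = int(np.sum(dend.heights < gamma))
    return cut_k(dend, dend.n_leaves - below)


def consensus_dissimilarity(partitions: Sequence[Partition]) -> DissimilarityMatrix:
    """Co-clustering consensus dissimilarity ``1 - eta`` across subjects.

    For items ``u, u'`` let ``S`` be the number of the ``|V|`` input
    partitions that place them in the same cluster.  The consensus
    co-clustering index is the fraction of ordered pairs of distinct
    subjects agreeing on co-clustering,
    ``eta(u, u') = S(S-1) / (|V|(|V|-1))``, and the returned
    dissimilarity is ``1 - eta`` (0 on the diagonal, symmetric, in
    [0, 1]).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    items = sorted(partitions[0].items)
    for p in partitions[1:]:
        if p.items != partitions[0].items:
            raise ValueError("all partitions must share the same ground set")
    v = len(partitions)
    lab = np.stack([p.to_labels(items) for p in partitions])  # (V, n)
    co = (lab[:, :, None] == lab[:, None, :]).sum(axis=0).astype(float)  # S
    eta = co * (co - 1.0) / (v * (v - 1.0))
    return DissimilarityMatrix(tuple(items), 1.0 - eta)


def ward_partition(
    matrix: DissimilarityMatrix, k: int, variant: str = "d2"
) -> tuple[Partition, Dendrogram]:
    """Ward agglomeration of a dissimilarity matrix, cut at ``k`` clusters.

    ``variant="d2"`` (default) treats the entries as distances and runs
    the Lance-Williams Ward recurrence on their squares (the Ward.D2
    convention, scipy's ``ward``).  ``variant="d"`` runs the recurrence
    on the raw entries (the Ward.D convention); the merge order is
    obtained by feeding the square roots of the entries to the same
    routine and the reported heights are squared back.
    """
    n = len(matrix.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    cond = matrix.condensed()
    if variant == "d2":
        z = linkage(cond, method="ward")
    elif variant == "d":
        z = linkage(np.sqrt(cond), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    else:
        raise ValueError("variant must be 'd' or 'd2'")
    dend = Dendrogram(matrix.labels, z)
    return cut_k(dend, k), dend


def _within_across(matrix: np.ndarray, labels: np.ndarray):
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices_from(matrix, k=1)
    d = matrix[iu]
    within = d[same[iu]]
    across = d[~same[iu]]
    return within, across


def cluster_count_criteria(
    matrix: DissimilarityMatrix, dend: Dendrogram, k_max: int = 5
) -> pd.DataFrame:
    """Internal cluster-count criteria for dendrogram cuts k = 2..k_max.

    Returns a table with one row per k:

    * ``ch`` -- a distance-based Calinski-Harabasz pseudo-F built from
      the squared-dissimilarity decomposition: with
      ``W = sum_c (1/n_c) sum_{i<j in c} d_ij^2`` and
      ``T = (1/n) sum_{i<j} d_ij^2``, ``ch = ((T-W)/(k-1)) / (W/(n-k))``.
    * ``si`` -- mean silhouette width on the dissimilarities.
    * ``di`` -- Dunn index, minimum across-cluster distance divided by
      maximum within-cluster diameter.
    """
    n = len(matrix.labels)
    if not 2 <= k_max <= n - 1:
        raise ValueError(f"k_max must be in [2, {n - 1}]")
    d = matrix.values
    d2 = d**2
    total = d2[np.triu_indices(n, k=1)].sum() / n
    rows = []
    for k in range(2, k_max + 1):
        part = cut_k(dend, k)
        labels = part.to_labels(matrix.labels)
        within_ss = 0.0
        for c in range(part.n_blocks):
            idx = np.flatnonzero(labels == c)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                within_ss += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
        if part.n_blocks < 2:  # degenerate cut (all merges at equal height)
            rows.append({"k": k, "ch": np.nan, "si": np.nan, "di": np.nan})
            continue
        ch = ((total - within_ss) / (part.n_blocks - 1)) / (
            within_ss / (n - part.n_blocks)
        ) if within_ss > 0 else np.inf
        si = float(silhouette_score(d, labels, metric="precomputed"))
        within, across = _within_across(d, labels)
        max_diam = within.max() if within.size else 0.0
        di = float(across.min() / max_diam) if max_diam > 0 else np.inf
        rows.append({"k": k, "ch": ch, "si": si, "di": di})
    return pd.DataFrame(rows)


def brute_force_best_two_partition(matrix: DissimilarityMatrix) -> Partition:
    """Exhaustive 2-partition minimising total within-cluster dissimilarity.

    Exponential in the number of items; intended as an independent check
    for small inputs.
    """
    labels = matrix.labels
    n = len(labels)
    d = matrix.values
    best, best_cost = None, np.inf
    idx = list(range(n))
    for size in range(1, n // 2 + 1):
        for left in combinations(idx, size):
            mask = np.zeros(n, dtype=bool)
            mask[list(left)] = True
            cost = d[np.ix_(mask, mask)].sum() + d[np.ix_(~mask, ~mask)].sum()
            if cost < best_cost:
                best_cost = cost
                best = mask.copy()
    return Partition(
        [
            [labels[i] for i in range(n) if best[i]],
            [labels[i] for i in range(n) if not best[i]],
        ]
    )
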