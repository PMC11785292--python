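"""End-to-end orchestration: subject clustering, consensus, significance.

The full procedure, given per-subject collections of string-labelled
curve sets:

1. per subject: trim the 10% most outlying curves of each set, build
   the pairwise projective dissimilarity matrix, complete-linkage
   cluster and cut at gamma;
2. across subjects: co-clustering consensus matrix, Ward dendrogram,
   partitions for a range of cluster counts plus the internal criteria;
3. Monte-Carlo p-value of each consensus partition against the
   strong-beat reference partition.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .clustering import (
    cluster_count_criteria,
    complete_linkage,
    consensus_dissimilarity,
    cut_at_threshold,
    ward_partition,
)
from .dissimilarity import TestConfig, gamma_threshold, pairwise_matrix
from .functional import FunctionalSet, trim_outliers
from .partition import Partition
from .significance import partition_pvalue
from .stimulus import strong_beat_partition

__all__ = ["cluster_subject", "consensus_partitions", "run_pipeline"]


def cluster_subject(
    sets: Mapping[str, FunctionalSet],
    cfg: TestConfig = TestConfig(),
    gamma: float | None = None,
    trim_fraction: float = 0.10,
) -> Partition:
    """Partition one subject's string-labelled sets of curves."""
    trimmed = {u: trim_outliers(s, trim_fraction) for u, s in sets.items()}
    matrix = pairwise_matrix(trimmed, cfg)
    dend = complete_linkage(matrix)
    if gamma is None:
        gamma = gamma_threshold(cfg)
    return cut_at_threshold(dend, gamma)


def consensus_partitions(
    subject_partitions: list[Partition], k_values=(3, 4, 5), ward_variant: str = "d2"
):
    """Consensus matrix, Ward dendrogram and partitions for each k."""
    matrix = consensus_dissimilarity(subject_partitions)
    parts = {}
    dend = None
    for k in k_values:
        parts[k], dend = ward_partition(matrix, k, ward_variant)
    return matrix, dend, parts


def run_pipeline(
    cohort: Mapping[str, Mapping[str, FunctionalSet]],
    cfg: TestConfig = TestConfig(),
    gamma: float | None = None,
    k_values=(3, 4, 5),
    ward_variant: str = "d2",
    null_reps: int = 100_000,
    seed: int | None = None,
    reference: Partition | None = None,
) -> dict:
    """Run the full procedure on a cohort; returns a JSON-able summary.

    ``null_reps = 0`` skips the significance stage.  The reference
    partition defaults to the strong-beat partition P*.
    """
    if reference is None:
        reference = strong_beat_partition()
    subject_parts = {
        sid: cluster_subject(sets, cfg, gamma) for sid, sets in cohort.items()
    }
    matrix, dend, parts = consensus_partitions(
        list(subject_parts.values()), k_values, ward_variant
    )
    k_max = min(5, len(matrix.labels) - 1)
    criteria = cluster_count_criteria(matrix, dend, k_max=k_max)

    summary: dict = {
        "gamma": gamma if gamma is not None else gamma_threshold(cfg),
        "ward_variant": ward_variant,
        "subject_partitions": {s: p.to_dict() for s, p in subject_parts.items()},
        "consensus_partitions": {str(k): p.to_dict() for k, p in parts.items()},
        "criteria": criteria.to_dict(orient="records"),
    }
    if null_reps > 0:
        pvals = {}
        for k, part in parts.items():
            res = partition_pvalue(
                part, reference, k=k, n_reps=null_reps, seed=seed,
                ward_variant=ward_variant,
            )
            pvals[str(k)] = {
                "observed_ari": res.observed_ari,
                "p_hat": res.p_hat,
                "n_reps": res.n_reps,
            }
        summary["p_values"] = pvals
    # round-trippable floats only
    summary["criteria"] = [
        {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
         for k, v in row.items()}
        for row in summary["criteria"]
    ]
    return summary
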