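from itertools import combinations

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from sambaclust import (
    DissimilarityMatrix,
    Partition,
    cluster_count_criteria,
    complete_linkage,
    consensus_dissimilarity,
    cut_at_threshold,
    cut_k,
    ward_partition,
)
from sambaclust.clustering import brute_force_best_two_partition


def dm(labels, values):
    return DissimilarityMatrix(tuple(labels), np.asarray(values, float))


def three_item_matrix():
    return dm("abc", [[0.0, 0.01, 0.9], [0.01, 0.0, 0.9], [0.9, 0.9, 0.0]])


def planted_blocks(sizes, within=0.1, across=0.9, seed=0, jitter=0.0):
    """Symmetric matrix with planted blocks (optionally jittered)."""
    rng = np.random.default_rng(seed)
    labels = []
    block_of = {}
    for b, size in enumerate(sizes):
        for i in range(size):
            lab = f"b{b}i{i}"
            block_of[lab] = b
            labels.append(lab)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if block_of[labels[i]] == block_of[labels[j]] else across
            v = base + jitter * rng.uniform(-1, 1)
            vals[i, j] = vals[j, i] = v
    return dm(labels, vals), Partition(
        [[lab for lab in labels if block_of[lab] == b] for b in range(len(sizes))]
    )


class TestCompleteLinkage:
    def test_hand_traced_merges(self):
        dend = complete_linkage(three_item_matrix())
        assert np.allclose(dend.heights, [0.01, 0.9])

    def test_two_items_single_merge(self):
        dend = complete_linkage(dm("xy", [[0.0, 0.42], [0.42, 0.0]]))
        assert dend.heights.tolist() == [0.42]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_heights_equal_brute_force_max_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        v = rng.uniform(size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = [f"i{k}" for k in range(n)]
        dend = complete_linkage(dm(labels, v))
        # replay the merge history, checking each height against the
        # brute-force max pairwise distance between the merged clusters
        clusters = {i: {i} for i in range(n)}
        for step, (a, b, h, _) in enumerate(dend.merges):
            ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
            expected = max(v[i, j] for i in ca for j in cb)
            assert np.isclose(h, expected)
            clusters[n + step] = ca | cb


class TestCutAtThreshold:
    def test_gamma_between_heights(self):
        dend = complete_linkage(three_item_matrix())
        part = cut_at_threshold(dend, 276 / 5000)
        assert part == Partition([["a", "b"], ["c"]])

    def test_gamma_zero_gives_singletons(self):
        dend = complete_linkage(three_item_matrix())
        assert cut_at_threshold(dend, 0.0).n_blocks == 3

    def test_large_gamma_gives_one_cluster(self):
        dend = complete_linkage(three_item_matrix())
        assert cut_at_threshold(dend, 1.1).n_blocks == 1

    @pytest.mark.parametrize("seed", [3, 4])
    def test_within_cluster_pairs_below_gamma_and_coarsest(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        v = rng.uniform(size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = [f"i{k}" for k in range(n)]
        matrix = dm(labels, v)
        dend = complete_linkage(matrix)
        gamma = 0.5
        part = cut_at_threshold(dend, gamma)
        for block in part.blocks:
            for u, w in combinations(block, 2):
                assert matrix[(u, w)] < gamma
        # coarsest: one fewer cluster must violate the gamma constraint
        if part.n_blocks > 1:
            coarser = cut_k(dend, part.n_blocks - 1)
            bad = any(
                matrix[(u, w)] >= gamma
                for block in coarser.blocks
                for u, w in combinations(block, 2)
            )
            assert bad


class TestConsensus:
    def test_identical_partitions_give_binary_matrix(self):
        p = Partition([["a", "b"], ["c"]])
        m = consensus_dissimilarity([p, p, p])
        assert m[("a", "b")] == 0.0
        assert m[("a", "c")] == 1.0 and m[("b", "c")] == 1.0

    def test_single_agreement_of_two_is_worthless(self):
        # co-clustered by exactly 1 of 2 partitions: S(S-1) = 0 -> d = 1
        p1 = Partition([["a", "b"], ["c"]])
        p2 = Partition([["a"], ["b"], ["c"]])
        m = consensus_dissimilarity([p1, p2])
        assert m[("a", "b")] == 1.0

    def test_ten_of_nineteen(self):
        together = Partition([["a", "b"], ["c"]])
        apart = Partition([["a"], ["b", "c"]])
        parts = [together] * 10 + [apart] * 9
        m = consensus_dissimilarity(parts)
        assert np.isclose(m[("a", "b")], 1 - 90 / 342)

    def test_output_is_valid_dissimilarity(self):
        rng = np.random.default_rng(0)
        items = list("abcdef")
        parts = [
            Partition.from_labels(items, rng.integers(0, 3, len(items)))
            for _ in range(7)
        ]
        m = consensus_dissimilarity(parts)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert (m.values >= 0).all() and (m.values <= 1).all()

    def test_mismatched_ground_sets_raise(self):
        with pytest.raises(ValueError):
            consensus_dissimilarity(
                [Partition([["a", "b"]]), Partition([["a", "c"]])]
            )


class TestWard:
    def test_degenerate_cuts(self):
        matrix, _ = planted_blocks([2, 2], seed=1, jitter=0.05)
        singletons, _ = ward_partition(matrix, 4)
        assert singletons.n_blocks == 4
        one, _ = ward_partition(matrix, 1)
        assert one.n_blocks == 1

    @pytest.mark.parametrize("variant", ["d", "d2"])
    def test_recovers_planted_blocks(self, variant):
        matrix, truth = planted_blocks([3, 4], seed=2, jitter=0.05)
        part, _ = ward_partition(matrix, 2, variant)
        assert part == truth
        assert part == brute_force_best_two_partition(matrix)

    def test_k_out_of_range(self):
        matrix, _ = planted_blocks([2, 2])
        with pytest.raises(ValueError):
            ward_partition(matrix, 0)
        with pytest.raises(ValueError):
            ward_partition(matrix, 5)

    def test_ward_d_matches_recurrence_on_raw_entries(self):
        """Ward.D merge order equals scipy's Ward.D2 run on sqrt entries."""
        rng = np.random.default_rng(3)
        n = 9
        v = rng.uniform(size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = [f"i{k}" for k in range(n)]
        part_d, dend_d = ward_partition(dm(labels, v), 3, "d")
        z = linkage(np.sqrt(v[np.triu_indices(n, 1)]), method="ward")
        ref = Partition.from_labels(labels, fcluster(z, 3, criterion="maxclust"))
        assert part_d == ref
        assert np.allclose(dend_d.heights, z[:, 2] ** 2)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        matrix, _ = planted_blocks([3, 3, 2], seed=5, jitter=0.08)
        perm = rng.permutation(len(matrix.labels))
        permuted = DissimilarityMatrix(
            tuple(matrix.labels[i] for i in perm),
            matrix.values[np.ix_(perm, perm)],
        )
        p1, _ = ward_partition(matrix, 3)
        p2, _ = ward_partition(permuted, 3)
        assert p1 == p2


class TestCriteria:
    def test_criteria_peak_at_true_k(self):
        matrix, _ = planted_blocks([4, 4, 4], within=0.1, across=0.9, jitter=0.03, seed=6)
        _, dend = ward_partition(matrix, 1)
        table = cluster_count_criteria(matrix, dend, k_max=5)
        for col in ("ch", "si", "di"):
            assert int(table.loc[table[col].idxmax(), "k"]) == 3

    def test_dunn_matches_brute_force(self):
        matrix, _ = planted_blocks([3, 3], within=0.2, across=0.8, jitter=0.1, seed=7)
        _, dend = ward_partition(matrix, 1)
        table = cluster_count_criteria(matrix, dend, k_max=3)
        for _, row in table.iterrows():
            part = cut_k(dend, int(row["k"]))
            labels = part.to_labels(matrix.labels)
            within = [
                matrix.values[i, j]
                for i, j in combinations(range(len(labels)), 2)
                if labels[i] == labels[j]
            ]
            across = [
                matrix.values[i, j]
                for i, j in combinations(range(len(labels)), 2)
                if labels[i] != labels[j]
            ]
            assert np.isclose(row["di"], min(across) / max(within))

    def test_k_max_validation(self):
        matrix, _ = planted_blocks([2, 2])
        _, dend = ward_partition(matrix, 1)
        with pytest.raises(ValueError):
            cluster_count_criteria(matrix, dend, k_max=1)
        with pytest.raises(ValueError):
            cluster_count_criteria(matrix, dend, k_max=4)
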