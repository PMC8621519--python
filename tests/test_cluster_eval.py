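import numpy as np
import pytest
from scipy.cluster.hierarchy import cut_tree
from scipy.stats import spearmanr

from binsim.binary_distances import DistanceMatrix, distance_matrix
from binsim.cluster_eval import (Dendrogram, Partition, adjusted_rand,
                                 bakers_gamma, cophenetic_correlation,
                                 correct_clustering_hca,
                                 correct_clustering_kmeans,
                                 correct_first_cluster,
                                 discrimination_distance_hca,
                                 discrimination_distance_kmeans, hca, kmeans)


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(tuple(ids), values, "euclidean")


def _sep_two_pairs():
    """Two 2-sample groups: within distance 1, between 10."""
    d = np.full((4, 4), 10.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 1.0
    dm = _dm(d, ["a1", "a2", "b1", "b2"])
    gt = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return hca(dm), gt


def _contaminated_five_groups():
    """Five replicate pairs; sample g1a first merges into g2's samples,
    spoiling groups g1 and g2 (hand-traced UPGMA)."""
    ids = ["g1a", "g1b", "g2a", "g2b", "g3a", "g3b", "g4a", "g4b", "g5a", "g5b"]
    gt = {s: s[:2] for s in ids}
    d = np.full((10, 10), 10.0)
    np.fill_diagonal(d, 0)
    for i in (4, 6, 8):  # intact pairs at distance 1
        d[i, i + 1] = d[i + 1, i] = 1.0
    d[0, 1] = d[1, 0] = 5.0       # g1 pair far apart
    d[0, 2] = d[2, 0] = 0.5       # g1a hugs g2a
    d[2, 3] = d[3, 2] = 1.0
    d[0, 3] = d[3, 0] = 1.5
    return hca(_dm(d, ids)), gt


class TestHCA:
    def test_two_samples_single_merge(self):
        dend = hca(_dm([[0.0, 3.0], [3.0, 0.0]]))
        assert dend.Z.shape == (1, 4) and dend.Z[0, 2] == 3.0

    def test_three_equidistant(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        dend = hca(_dm(d))
        np.testing.assert_allclose(dend.Z[:, 2], [2.0, 2.0])

    def test_ultrametric_fixed_point(self):
        dend, _ = _sep_two_pairs()
        coph = dend.cophenetic_matrix()
        assert coph.loc["a1", "a2"] == 1.0
        assert coph.loc["a1", "b1"] == 10.0

    def test_newick_contains_all_leaves(self):
        dend, _ = _sep_two_pairs()
        nwk = dend.to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in ("a1", "a2", "b1", "b2"))


class TestCorrectClusteringHCA:
    def test_separable_is_100(self):
        dend, gt = _sep_two_pairs()
        assert correct_clustering_hca(dend, gt) == 100.0

    def test_contamination_spoils_two_groups(self):
        dend, gt = _contaminated_five_groups()
        assert correct_clustering_hca(dend, gt) == 60.0

    def test_single_group_root_is_pure(self):
        dend, _ = _sep_two_pairs()
        gt = {s: "only" for s in dend.leaf_ids}
        assert correct_clustering_hca(dend, gt) == 100.0


class TestDiscriminationDistanceHCA:
    def test_symmetric_hand_case(self):
        # both pure nodes at height 1 absorbed at root height 4 -> (4-1)/4
        dend, gt = _sep_two_pairs()
        # UPGMA root height: average of the 4 between-pair distances = 10
        # rescale expectations from actual heights
        got = discrimination_distance_hca(dend, gt)
        assert got == pytest.approx((10 - 1) / 10)

    def test_zero_when_nothing_correct(self):
        dend, gt = _sep_two_pairs()
        bad = {"a1": "A", "a2": "B", "b1": "A", "b2": "B"}
        assert discrimination_distance_hca(dend, bad) == 0.0

    def test_constructed_heights(self):
        # pure node at height 1, absorbed at the root (height 4)
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 4.0, 3.0]])
        dend = Dendrogram(("x", "y", "z"), Z)
        gt = {"x": "G", "y": "G", "z": "H"}
        # G: (4-1)/4 = 0.75; H (leaf, height 0): (4-0)/4 = 1
        assert discrimination_distance_hca(dend, gt) == pytest.approx((0.75 + 1) / 2)


class TestCorrectFirstCluster:
    def test_separable_is_100(self):
        dend, gt = _sep_two_pairs()
        assert correct_first_cluster(dend, gt) == 100.0

    def test_two_samples_different_groups(self):
        dend = hca(_dm([[0.0, 3.0], [3.0, 0.0]], ["a", "b"]))
        assert correct_first_cluster(dend, {"a": "A", "b": "B"}) == 0.0

    def test_stray_sample_counts(self):
        dend, gt = _contaminated_five_groups()
        # g1a merges first with g2a (both wrong), then g2b joins a mixed node
        # (wrong), g1b joins a mixed node (wrong): 6 of 10 correct
        assert correct_first_cluster(dend, gt) == 60.0


class TestKMeans:
    def test_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        part = kmeans(X, 2, seed=1)
        labels = [part.assignment[s] for s in part.sample_ids]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_zero_inertia(self):
        X = np.array([[0.0], [5.0], [9.0]])
        assert kmeans(X, 3, seed=0).inertia == pytest.approx(0.0)

    def test_min_inertia_over_restarts(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        multi = kmeans(X, 3, n_init=15, seed=0)
        singles = [kmeans(X, 3, n_init=1, seed=s).inertia for s in range(5)]
        assert multi.inertia <= min(singles) + 1e-9

    def test_rejects_distance_matrix(self):
        dm = _dm([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(TypeError):
            kmeans(dm, 2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        a, b = kmeans(X, 3, seed=9), kmeans(X, 3, seed=9)
        assert a.assignment == b.assignment


class TestKMeansMetrics:
    def test_perfect_partition(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1},
                      centroids=np.array([[0.0], [5.0]]))
        gt = {"a": "A", "b": "A", "c": "B", "d": "B"}
        assert correct_clustering_kmeans(p, gt) == 100.0
        assert discrimination_distance_kmeans(p, gt) == pytest.approx(1.0)

    def test_merged_groups_incorrect(self):
        p = Partition({"a": 0, "b": 0, "c": 0, "d": 1})
        gt = {"a": "A", "b": "A", "c": "B", "d": "B"}
        assert correct_clustering_kmeans(p, gt) == 0.0

    def test_collinear_centroid_hand_case(self):
        # centroids at 0, 1, 10: ratios 1/10, 1/10, 9/10 -> mean 11/30
        p = Partition({"a": 0, "b": 1, "c": 2},
                      centroids=np.array([[0.0], [1.0], [10.0]]))
        gt = {"a": "A", "b": "B", "c": "C"}
        assert discrimination_distance_kmeans(p, gt) == pytest.approx(11 / 30)

    def test_adjusted_rand_hand_case(self):
        p = Partition({"a": 1, "b": 2, "c": 1, "d": 2})
        gt = {"a": 1, "b": 1, "c": 2, "d": 2}
        assert adjusted_rand(p, gt) == pytest.approx(-0.5)

    def test_adjusted_rand_identical_and_degenerate(self):
        p = Partition({"a": 0, "b": 0, "c": 1})
        assert adjusted_rand(p, {"a": "x", "b": "x", "c": "y"}) == 1.0
        single = Partition({"a": 0, "b": 0})
        assert adjusted_rand(single, {"a": "g", "b": "g"}) == 1.0


class TestDendrogramComparison:
    def test_self_correlations_are_one(self):
        dend, _ = _sep_two_pairs()
        assert cophenetic_correlation(dend, dend) == pytest.approx(1.0)
        assert bakers_gamma(dend, dend) == pytest.approx(1.0)

    def test_scale_and_monotone_invariance(self):
        dend, _ = _sep_two_pairs()
        doubled = Dendrogram(dend.leaf_ids,
                             np.column_stack([dend.Z[:, :2], 2 * dend.Z[:, 2],
                                              dend.Z[:, 3]]))
        assert cophenetic_correlation(dend, doubled) == pytest.approx(1.0)
        cubed = Dendrogram(dend.leaf_ids,
                           np.column_stack([dend.Z[:, :2], dend.Z[:, 2] ** 3,
                                            dend.Z[:, 3]]))
        assert bakers_gamma(dend, cubed) == pytest.approx(1.0)

    def test_swapped_pair_matches_bruteforce(self):
        # trees over the same 4 leaves with different nestings
        ids = ("a", "b", "c", "d")
        Z1 = np.array([[0, 1, 1.0, 2], [2, 3, 2.0, 2], [4, 5, 4.0, 4]])
        Z2 = np.array([[0, 2, 1.0, 2], [1, 3, 2.0, 2], [4, 5, 4.0, 4]])
        d1, d2 = Dendrogram(ids, Z1), Dendrogram(ids, Z2)

        def cut_levels(Z):
            # independent oracle: scan k = n..2 with scipy cut_tree
            n = Z.shape[0] + 1
            cuts = cut_tree(Z)
            out = {}
            for i in range(n):
                for j in range(i + 1, n):
                    ks = [n - col for col in range(cuts.shape[1])
                          if cuts[i, col] == cuts[j, col]]
                    out[(i, j)] = max(ks)
            return out

        l1, l2 = cut_levels(Z1), cut_levels(Z2)
        pairs = sorted(l1)
        expected = spearmanr([l1[p] for p in pairs],
                             [l2[p] for p in pairs]).statistic
        assert bakers_gamma(d1, d2) == pytest.approx(expected)
        assert bakers_gamma(d1, d2) < 1

        coph1 = d1.cophenetic_matrix().to_numpy()
        coph2 = d2.cophenetic_matrix().to_numpy()
        v1 = coph1[np.triu_indices(4, 1)]
        v2 = coph2[np.triu_indices(4, 1)]
        assert cophenetic_correlation(d1, d2) == pytest.approx(
            np.corrcoef(v1, v2)[0, 1])
        assert cophenetic_correlation(d1, d2) < 1

    def test_leaf_order_independence(self):
        dend, _ = _sep_two_pairs()
        # same tree with leaves listed in a different order
        perm = [2, 3, 0, 1]
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        ids = [dend.leaf_ids[i] for i in perm]
        other = hca(_dm(d[np.ix_(perm, perm)], ids))
        assert cophenetic_correlation(dend, other) == pytest.approx(1.0)
        assert bakers_gamma(dend, other) == pytest.approx(1.0)

    def test_constant_vector_errors(self):
        dend = hca(_dm([[0.0, 3.0], [3.0, 0.0]], ["a", "b"]))
        with pytest.raises(ValueError):
            cophenetic_correlation(dend, dend)


class TestEndToEndSeparation:
    def test_perfectly_separated_data_maxes_all_metrics(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(10 * c, 0.05, (3, 6)) for c in range(3)])
        ids = [f"c{c}r{r}" for c in range(3) for r in range(3)]
        gt = {f"c{c}r{r}": c for c in range(3) for r in range(3)}
        dm = distance_matrix(X, "euclidean")
        dm = DistanceMatrix(tuple(ids), dm.values, "euclidean")
        dend = hca(dm)
        assert correct_clustering_hca(dend, gt) == 100.0
        assert correct_first_cluster(dend, gt) == 100.0
        assert discrimination_distance_hca(dend, gt) > 0
        import pandas as pd
        part = kmeans(pd.DataFrame(X, index=ids), 3, seed=0)
        assert correct_clustering_kmeans(part, gt) == 100.0
        assert adjusted_rand(part, gt) == 1.0
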