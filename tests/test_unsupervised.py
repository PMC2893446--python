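import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omiclink.datamodel import FeatureMatrix
from omiclink.unsupervised import (
    DistanceMatrix,
    HierarchicalClustering,
    KMeansClustering,
    SeriationTransformer,
    cut_dendrogram,
    hierarchical_cluster,
    kmeans,
    pairwise_distance,
    seriate,
)

from oracles import mst_edge_weights, naive_agglomerate


class TestPairwiseDistance:
    def test_euclidean_closed_form(self):
        D = pairwise_distance(np.array([[0, 0, 0], [1, 1, 1.0]]))
        assert D.values[0, 1] == pytest.approx(np.sqrt(3))

    def test_pearson_perfect_correlation_is_zero(self):
        D = pairwise_distance(np.array([[1, 2, 3], [2, 4, 6.0]]), "pearson")
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_pearson_anticorrelation_is_two(self):
        D = pairwise_distance(np.array([[1, 2, 3], [3, 2, 1.0]]), "pearson")
        assert D.values[0, 1] == pytest.approx(2.0)

    def test_spearman_monotone_equals_zero_distance(self):
        # monotone but nonlinear: rank-perfect, pearson-imperfect
        D = pairwise_distance(np.array([[1, 2, 3, 4], [1, 8, 27, 64.0]]), "spearman")
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_zero_variance_item_reported_missing(self):
        D = pairwise_distance(np.array([[1, 1, 1], [1, 2, 3.0]]), "pearson")
        assert np.isnan(D.values[0, 1])
        with pytest.raises(ValueError, match="missing"):
            D.condensed()

    def test_pairwise_complete_euclidean_rescales(self):
        X = np.array([[0.0, 0.0, np.nan], [1.0, 1.0, 5.0]])
        D = pairwise_distance(X, "euclidean")
        # 2 of 3 coords observed: sum rescaled by 3/2
        assert D.values[0, 1] == pytest.approx(np.sqrt(3 / 2 * 2.0))

    def test_column_axis_uses_sample_ids(self, study):
        D = pairwise_distance(study.expression, axis="columns")
        assert D.item_ids == study.expression.col_ids

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(2, 7), st.integers(2, 5),
           st.sampled_from(["euclidean", "manhattan", "pearson", "spearman"]),
           st.integers(0, 10 ** 6))
    def test_symmetry_and_zero_diagonal(self, n, p, metric, seed):
        X = np.random.default_rng(seed).normal(size=(n, p))
        D = pairwise_distance(X, metric).values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)


class TestHierarchical:
    def points(self, vals):
        return np.asarray(vals, dtype=float).reshape(-1, 1)

    def test_single_linkage_forced_heights(self):
        D = pairwise_distance(self.points([0, 1, 10]))
        dend = hierarchical_cluster(D, "single")
        assert [h for _, _, h in dend.merges] == pytest.approx([1.0, 9.0])

    def test_complete_linkage_forced_heights(self):
        D = pairwise_distance(self.points([0, 1, 10]))
        dend = hierarchical_cluster(D, "complete")
        assert [h for _, _, h in dend.merges] == pytest.approx([1.0, 10.0])

    def test_ward_requires_euclidean(self):
        D = pairwise_distance(np.random.default_rng(0).normal(size=(4, 3)), "manhattan")
        with pytest.raises(ValueError, match="euclidean"):
            hierarchical_cluster(D, "ward")

    def test_heights_nondecreasing(self, rng):
        D = pairwise_distance(rng.normal(size=(12, 4)))
        for linkage in ("single", "complete", "average", "ward"):
            h = hierarchical_cluster(D, linkage).heights
            assert (np.diff(h) >= -1e-12).all()

    def test_matches_naive_agglomeration(self, rng):
        """Merge heights and cluster compositions equal the O(n^3) oracle."""
        for linkage in ("single", "complete", "average", "ward"):
            X = rng.normal(size=(8, 3))
            D = pairwise_distance(X)
            dend = hierarchical_cluster(D, linkage)
            expected = naive_agglomerate(D.values, linkage, points=X)
            got_heights = [h for _, _, h in dend.merges]
            assert got_heights == pytest.approx([h for _, h in expected])
            assert _merge_sets(dend) == [s for s, _ in expected]

    def test_single_linkage_equals_sorted_mst(self, rng):
        D = pairwise_distance(rng.normal(size=(10, 3)))
        heights = np.array([h for _, _, h in hierarchical_cluster(D, "single").merges])
        np.testing.assert_allclose(np.sort(heights), mst_edge_weights(D.values))


def _merge_sets(dend):
    """Leaf set created by each merge, in merge order."""
    n = dend.n
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _) in enumerate(dend.merges):
        members[n + k] = members[a] | members[b]
        out.append(members[n + k])
    return out


class TestCut:
    def dend(self):
        D = pairwise_distance(np.array([[0.0], [1.0], [10.0]]))
        return hierarchical_cluster(D, "single")

    def test_k1_single_cluster(self):
        assert cut_dendrogram(self.dend(), 1).labels.tolist() == [1, 1, 1]

    def test_kn_singletons(self):
        assert sorted(cut_dendrogram(self.dend(), 3).labels.tolist()) == [1, 2, 3]

    def test_forced_two_groups(self):
        p = cut_dendrogram(self.dend(), 2)
        assert p.labels[0] == p.labels[1] != p.labels[2]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must be"):
            cut_dendrogram(self.dend(), 4)


class TestKMeans:
    def test_forced_optimum(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        part, centers, wss = kmeans(X, 2, seed=0)
        assert part.labels.tolist() == [1, 1, 2, 2]
        assert sorted(c[0] for c in centers) == pytest.approx([0.5, 10.5])
        assert wss == pytest.approx(1.0)

    def test_k_equals_n_zero_wss(self, rng):
        X = rng.normal(size=(5, 2))
        _, _, wss = kmeans(X, 5, seed=1)
        assert wss == pytest.approx(0.0, abs=1e-9)

    def test_beats_random_assignments(self, rng):
        """Seeded k-means objective is no worse than 1000 random labelings."""
        X = rng.normal(size=(20, 3))
        _, _, wss = kmeans(X, 3, seed=7)
        for _ in range(1000):
            labels = rng.integers(0, 3, size=20)
            obj = sum(((X[labels == l] - X[labels == l].mean(0)) ** 2).sum()
                      for l in np.unique(labels))
            assert wss <= obj + 1e-9

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(np.zeros((3, 2)), 4)

    def test_missing_rows_imputed(self):
        X = np.array([[0.0, np.nan], [0.0, 0.1], [9.0, 9.0], [9.0, 8.9]])
        part, _, _ = kmeans(X, 2, seed=0)
        assert part.labels[0] == part.labels[1] != part.labels[2]

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 4))
        a = KMeansClustering(n_clusters=4, random_state=11).fit(X)
        b = KMeansClustering(n_clusters=4, random_state=11).fit(X)
        assert a.labels_.tolist() == b.labels_.tolist()
        assert a.inertia_ == b.inertia_


class TestSeriation:
    def test_pca_recovers_1d_structure(self):
        X = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        perm = seriate(data=X, method="pca").permutation.tolist()
        assert perm in ([1, 2, 0], [0, 2, 1])

    def test_mds_recovers_line(self):
        pts = np.array([[0.0], [5.0], [1.0]])
        D = pairwise_distance(pts)
        perm = seriate(distances=D, method="mds").permutation.tolist()
        assert perm in ([0, 2, 1], [1, 2, 0])

    def test_degenerate_input_gives_identity(self):
        X = np.ones((4, 3))
        assert seriate(data=X, method="pca").permutation.tolist() == [0, 1, 2, 3]

    def test_pca_equivariant_under_row_reversal(self, rng):
        X = rng.normal(size=(9, 4))
        fwd = seriate(data=X, method="pca").permutation
        rev = seriate(data=X[::-1], method="pca").permutation
        mapped = [8 - i for i in rev]
        assert mapped == list(fwd) or mapped == list(fwd)[::-1]

    def test_leaf_order_is_optimal_among_flips(self, rng):
        """Adjacent-leaf distance sum equals the minimum over all
        tree-consistent leaf orders (2^(n-1) flips)."""
        from oracles import adjacent_distance_sum, tree_orders
        X = rng.normal(size=(6, 3))
        D = pairwise_distance(X)
        dend = hierarchical_cluster(D, "average")
        ser = seriate(distances=D, dendrogram=dend, method="leaf_order")
        achieved = adjacent_distance_sum(ser.permutation, D.values)
        best = min(adjacent_distance_sum(o, D.values)
                   for o in tree_orders(dend.Z, 6))
        assert achieved == pytest.approx(best)

    def test_transformer_reorders_matrix(self, rng):
        X = rng.normal(size=(6, 3))
        tr = SeriationTransformer(method="leaf_order").fit(X)
        out = tr.transform(X)
        np.testing.assert_array_equal(out, X[tr.order_])

    def test_permutation_must_be_bijection(self):
        from omiclink.unsupervised import Seriation
        with pytest.raises(ValueError, match="bijection"):
            Seriation("rows", [0, 0, 1], "pca")


def test_estimator_pipeline_compatibility(study):
    """Estimators expose get_params/set_params and fit chains."""
    est = HierarchicalClustering(n_clusters=2, metric="pearson", linkage="average")
    assert est.get_params()["metric"] == "pearson"
    est.set_params(metric="euclidean").fit(study.expression.values[:40])
    assert len(est.labels_) == 40
    assert est.partition_.labels.min() == 1
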