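import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from redrug import aggregate as agg
from redrug.aggregate import (
    DiseaseClustering,
    agg_biclique,
    agg_cluster_max,
    agg_cumulative_max,
    agg_drug_clusters_mean,
    agg_global_max,
    agg_global_mean,
    agg_mean_outliers,
    agg_union_clusters,
    agg_union_diseases,
    biclique_core,
    cluster_diseases_kmeans,
    cluster_diseases_louvain,
    pca_diagnostic,
    reduce_clusters,
    standardize,
    top_r,
)


def brute_best_biclique(Shat, diseases):
    """Exhaustive oracle: all non-empty subsets × all prefix lengths."""
    best = -np.inf
    n = Shat.shape[1]
    for size in range(1, len(diseases) + 1):
        for combo in itertools.combinations(diseases, size):
            sums = Shat[list(combo)].sum(axis=0)
            order = np.lexsort((np.arange(n), -sums))
            ss = sums[order]
            for i in range(1, n + 1):
                best = max(best, i * ss[i - 1] * len(combo))
    return best


class TestStandardize:
    def test_row_closed_form(self):
        std = standardize(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(std.Shat[0], [-1.22474487, 0.0, 1.22474487], atol=1e-6)

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="zero score spread"):
            std = standardize(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(std.Shat[0], 0.0)

    def test_rows_have_mean_zero_std_one(self, rng):
        std = standardize(rng.uniform(size=(6, 40)))
        np.testing.assert_allclose(std.Shat.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(std.Shat.std(axis=1, ddof=0), 1.0, atol=1e-9)


class TestTopR:
    def test_orders_by_score(self):
        r = top_r(np.array([0.1, 0.9, 0.5]), 2)
        np.testing.assert_array_equal(r.drug_order, [1, 2])

    def test_ties_break_by_index(self):
        r = top_r(np.zeros(5), 5)
        np.testing.assert_array_equal(r.drug_order, np.arange(5))

    def test_r_equals_n_is_permutation(self, rng):
        scores = rng.standard_normal(9)
        r = top_r(scores, 9)
        assert sorted(r.drug_order.tolist()) == list(range(9))

    def test_r_beyond_n_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            r = top_r(np.array([1.0, 2.0]), 5)
        assert len(r) == 2


class TestFlatStrategies:
    def test_global_mean_example(self):
        Shat = np.array([[2.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
        r = agg_global_mean(Shat, 3)
        np.testing.assert_array_equal(r.drug_order, [0, 1, 2])
        np.testing.assert_allclose(r.scores, [1.0, 0.5, -1.0])

    def test_global_max_example(self):
        r = agg_global_max(np.array([[2.0, 0.0], [0.0, 3.0]]), 2)
        np.testing.assert_array_equal(r.drug_order, [1, 0])

    def test_max_dominates_mean_per_drug(self, rng):
        Shat = rng.standard_normal((5, 12))
        assert np.all(Shat.max(axis=0) >= Shat.mean(axis=0))

    def test_mean_against_loop_oracle(self, rng):
        Shat = rng.standard_normal((5, 20))
        looped = np.array([np.mean([Shat[d, c] for d in range(5)]) for c in range(20)])
        np.testing.assert_array_equal(
            agg_global_mean(Shat, 20).drug_order, top_r(looped, 20).drug_order
        )

    def test_outliers_drops_worst_entries(self):
        Shat = np.array([[3.0, 0.0], [-10.0, 0.1]])
        r = agg_mean_outliers(Shat, 1, 2)
        assert r.scores[r.drug_order.tolist().index(0)] == pytest.approx(3.0)

    def test_outliers_oracle(self, rng):
        Shat = rng.standard_normal((6, 15))
        l = 2
        oracle = np.array([np.sort(Shat[:, c])[l:].mean() for c in range(15)])
        np.testing.assert_array_equal(
            agg_mean_outliers(Shat, l, 15).drug_order, top_r(oracle, 15).drug_order
        )

    def test_single_disease_mean_equals_own_ranking(self, rng):
        Shat = rng.standard_normal((1, 10))
        np.testing.assert_array_equal(
            agg_global_mean(Shat, 5).drug_order, top_r(Shat[0], 5).drug_order
        )


class TestUnionDiseases:
    def test_hand_enumerated_merge(self):
        # rows rank: [d0>d1>d2] and [d0>d2>d1]; x=1 union={d0} so x=2
        Shat = np.array([[3.0, 2.0, 1.0], [3.0, 1.0, 2.0]])
        r = agg_union_diseases(Shat, 2)
        assert r.params["x"] == 2
        np.testing.assert_array_equal(r.drug_order, [0, 1])

    def test_single_disease_is_plain_top_r(self, rng):
        Shat = rng.standard_normal((1, 20))
        r = agg_union_diseases(Shat, 5)
        np.testing.assert_array_equal(r.drug_order, top_r(Shat[0], 5).drug_order)
        assert r.params["x"] == 5

    def test_r_one_picks_first_rows_best(self, rng):
        Shat = rng.standard_normal((4, 10))
        r = agg_union_diseases(Shat, 1)
        assert r.params["x"] == 1
        assert r.drug_order[0] == int(np.argmax(Shat[0]))


class TestClustering:
    def test_kmeans_separates_identical_row_groups(self):
        Shat = np.vstack([np.tile([5.0, 0.0, 0.0], (3, 1)), np.tile([0.0, 5.0, 0.0], (3, 1))])
        cl = cluster_diseases_kmeans(Shat, 2, seed=0)
        assert len(set(cl.labels[:3])) == 1
        assert len(set(cl.labels[3:])) == 1
        assert cl.labels[0] != cl.labels[3]

    def test_kmeans_k1_single_cluster(self, rng):
        cl = cluster_diseases_kmeans(rng.standard_normal((5, 8)), 1, seed=0)
        assert set(cl.labels.tolist()) == {0}

    def test_kmeans_recovers_planted_clusters(self, small_matrix):
        from sklearn.metrics import adjusted_rand_score

        std = standardize(small_matrix.scores)
        cl = cluster_diseases_kmeans(std, 3, seed=0)
        assert adjusted_rand_score(small_matrix.disease_labels, cl.labels) >= 0.9

    def test_kmeans_k_above_D_fatal(self, rng):
        with pytest.raises(ValueError):
            cluster_diseases_kmeans(rng.standard_normal((3, 5)), 4)

    def test_louvain_block_diagonal(self):
        Shat = np.zeros((4, 8))
        Shat[:2, :4] = 1.0
        Shat[2:, 4:] = 1.0
        cl = cluster_diseases_louvain(Shat, seed=0)
        assert cl.labels[0] == cl.labels[1]
        assert cl.labels[2] == cl.labels[3]
        assert cl.labels[0] != cl.labels[2]

    def test_louvain_all_negative_single_cluster(self):
        with pytest.warns(UserWarning, match="no positive"):
            cl = cluster_diseases_louvain(-np.ones((3, 5)), seed=0)
        assert cl.k == 1

    def test_louvain_labels_contiguous(self, small_matrix):
        std = standardize(small_matrix.scores)
        cl = cluster_diseases_louvain(std, seed=0)
        labs = set(cl.labels.tolist())
        assert labs == set(range(len(labs)))
        assert len(labs) <= std.n_diseases


class TestClusterReduction:
    def test_single_cluster_equals_column_means(self, rng):
        Shat = rng.standard_normal((4, 9))
        cl = DiseaseClustering(np.zeros(4, dtype=np.int64), "kmeans", 1)
        np.testing.assert_allclose(reduce_clusters(Shat, cl)[0], Shat.mean(axis=0))

    def test_singleton_clusters_identity(self, rng):
        Shat = rng.standard_normal((4, 9))
        cl = DiseaseClustering(np.arange(4), "kmeans", 4)
        np.testing.assert_allclose(reduce_clusters(Shat, cl), Shat)

    def test_loop_oracle(self, rng):
        Shat = rng.standard_normal((6, 11))
        labels = np.array([0, 1, 0, 2, 1, 2])
        cl = DiseaseClustering(labels, "kmeans", 3)
        red = reduce_clusters(Shat, cl)
        for g in range(3):
            np.testing.assert_allclose(red[g], Shat[labels == g].mean(axis=0), atol=1e-12)


class TestAggregationIdentities:
    """Exact structural identities between strategies."""

    def test_zero_outliers_is_global_mean(self, rng):
        Shat = rng.standard_normal((7, 30))
        np.testing.assert_array_equal(
            agg_mean_outliers(Shat, 0, 10).drug_order, agg_global_mean(Shat, 10).drug_order
        )

    def test_one_cluster_max_is_global_mean(self, rng):
        Shat = rng.standard_normal((7, 30))
        cl = DiseaseClustering(np.zeros(7, dtype=np.int64), "kmeans", 1)
        np.testing.assert_array_equal(
            agg_cluster_max(Shat, cl, 10).drug_order, agg_global_mean(Shat, 10).drug_order
        )

    def test_singleton_clusters_max_is_global_max(self, rng):
        Shat = rng.standard_normal((7, 30))
        cl = DiseaseClustering(np.arange(7), "kmeans", 7)
        np.testing.assert_array_equal(
            agg_cluster_max(Shat, cl, 10).drug_order, agg_global_max(Shat, 10).drug_order
        )

    def test_singleton_union_clusters_is_union_diseases(self, rng):
        Shat = rng.standard_normal((5, 25))
        cl = DiseaseClustering(np.arange(5), "kmeans", 5)
        np.testing.assert_array_equal(
            agg_union_clusters(Shat, cl, 8).drug_order, agg_union_diseases(Shat, 8).drug_order
        )

    def test_cumulative_max_order_is_global_mean_order(self, rng):
        Shat = rng.standard_normal((6, 40))
        np.testing.assert_array_equal(
            agg_cumulative_max(Shat, 40).drug_order, agg_global_mean(Shat, 40).drug_order
        )

    def test_drug_clusters_with_singletons_is_global_mean(self, rng):
        Shat = rng.standard_normal((4, 12))
        np.testing.assert_array_equal(
            agg_drug_clusters_mean(Shat, 12, 6, seed=0).drug_order,
            agg_global_mean(Shat, 6).drug_order,
        )


class TestDrugClustersMean:
    def test_whole_best_cluster_then_partial_second(self):
        # columns 0-2 high, columns 3-6 low; r=5 -> all of best cluster + top-2 of other
        Shat = np.vstack([np.array([9.0, 8.0, 7.0, 4.0, 3.0, 2.0, 1.0])] * 2)
        r = agg_drug_clusters_mean(Shat, 2, 5, seed=0)
        assert len(r) == 5
        assert set(r.drug_order[:3].tolist()) == {0, 1, 2}
        assert r.drug_order[3:].tolist() == [3, 4]

    def test_exactly_r_unique_drugs(self, small_matrix):
        std = standardize(small_matrix.scores)
        r = agg_drug_clusters_mean(std, 40, 25, seed=1)
        assert len(r) == 25
        assert len(set(r.drug_order.tolist())) == 25


class TestBicliqueCore:
    def test_forced_arithmetic_single_disease(self):
        Shat = np.array([[3.0, 2.0, 1.0]])
        res = biclique_core(Shat, [0])
        assert res.split_index == 2
        assert res.value == pytest.approx(4.0)

    def test_all_negative_sums(self):
        Shat = np.array([[-1.0, -3.0, -2.0]])
        res = biclique_core(Shat, [0])
        # brute force over i: best is i=1 with the least-negative drug
        assert res.split_index == 1
        assert res.value == pytest.approx(-1.0)

    def test_value_consistent_and_sums_decreasing(self, rng):
        Shat = rng.standard_normal((4, 8))
        res = biclique_core(Shat, [0, 2])
        assert np.all(np.diff(res.drug_sums) <= 1e-12)
        i = res.split_index
        assert res.value == pytest.approx(i * res.drug_sums[i - 1] * 2)

    def test_prefix_matches_exhaustive_i(self, rng):
        Shat = rng.standard_normal((3, 8))
        res = biclique_core(Shat, [0, 1, 2])
        best = max((i * res.drug_sums[i - 1]) for i in range(1, 9))
        assert res.split_index * res.drug_sums[res.split_index - 1] == pytest.approx(best)


class TestAggBiclique:
    def test_single_disease_is_score_order(self, rng):
        Shat = rng.standard_normal((1, 10))
        r = agg_biclique(Shat, 5, mode="max", n_clusters=1)
        np.testing.assert_array_equal(r.drug_order, top_r(Shat[0], 5).drug_order)

    def test_forced_single_cluster_matches_brute_force(self, rng):
        Shat = rng.standard_normal((4, 6))
        from redrug.aggregate import _best_subset

        best = _best_subset(Shat, np.arange(4))
        assert best.value == pytest.approx(brute_best_biclique(Shat, range(4)))

    def test_oracle_sweep_200_instances(self):
        rng = np.random.default_rng(123)
        from redrug.aggregate import _best_subset

        for _ in range(200):
            nd = int(rng.integers(1, 7))
            n = int(rng.integers(2, 9))
            Shat = rng.standard_normal((nd, n))
            best = _best_subset(Shat, np.arange(nd))
            assert best.value == pytest.approx(brute_best_biclique(Shat, range(nd)))

    def test_returned_subset_beats_full_set(self, rng):
        Shat = rng.standard_normal((5, 9))
        from redrug.aggregate import _best_subset

        best = _best_subset(Shat, np.arange(5))
        full = biclique_core(Shat, np.arange(5))
        assert best.value >= full.value - 1e-12

    def test_oversized_cluster_fatal(self, rng):
        Shat = rng.standard_normal((25, 4))
        from redrug.aggregate import _best_subset

        with pytest.raises(ValueError, match="more clusters"):
            _best_subset(Shat, np.arange(25))

    def test_union_mode_valid_ranking(self, small_matrix):
        std = standardize(small_matrix.scores)
        r = agg_biclique(std, 20, mode="union", seed=0)
        assert len(r) == 20
        assert len(set(r.drug_order.tolist())) == 20


class TestRankingProperties:
    @pytest.mark.parametrize(
        "strategy",
        [
            lambda S, r: agg_global_mean(S, r),
            lambda S, r: agg_global_max(S, r),
            lambda S, r: agg_mean_outliers(S, 2, r),
            lambda S, r: agg_union_diseases(S, r),
            lambda S, r: agg_cluster_max(S, cluster_diseases_kmeans(S, 3, 0), r),
            lambda S, r: agg_union_clusters(S, cluster_diseases_kmeans(S, 3, 0), r),
            lambda S, r: agg_drug_clusters_mean(S, 30, r, 0),
            lambda S, r: agg_biclique(S, r, "max", seed=0),
            lambda S, r: agg_biclique(S, r, "union", seed=0),
            lambda S, r: agg_cumulative_max(S, r),
        ],
        ids=[
            "global_mean", "global_max", "mean_outliers", "union_diseases",
            "kmeans_max", "union_kmeans", "drug_clusters", "biclique_max",
            "biclique_union", "cumulative_max",
        ],
    )
    def test_valid_deterministic_scale_invariant(self, strategy, small_matrix):
        std = standardize(small_matrix.scores)
        r = 15
        rank1 = strategy(std.Shat, r)
        assert len(rank1) == r
        assert len(set(rank1.drug_order.tolist())) == r
        rank2 = strategy(std.Shat, r)
        np.testing.assert_array_equal(rank1.drug_order, rank2.drug_order)
        rank3 = strategy(std.Shat * 3.0, r)
        np.testing.assert_array_equal(rank1.drug_order, rank3.drug_order)


class TestPCADiagnostic:
    def test_line_in_score_space_one_component(self):
        t = np.linspace(0, 1, 8)
        Shat = np.outer(t, np.ones(20)) * np.arange(20)
        coords, evr = pca_diagnostic(Shat)
        assert coords.shape[0] == 8
        assert evr[0] > 0.999

    def test_planted_three_clusters_prefer_k3(self, small_matrix):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        std = standardize(small_matrix.scores)
        coords, _ = pca_diagnostic(std)
        sils = {}
        for k in (2, 3):
            scores = [
                silhouette_score(coords, KMeans(k, n_init=10, random_state=s).fit_predict(coords))
                for s in (1, 2, 3)
            ]
            sils[k] = np.mean(scores)
        assert sils[3] > sils[2]


@settings(max_examples=40, deadline=None)
@given(
    Shat=arrays(
        np.float64,
        st.tuples(st.integers(1, 5), st.integers(2, 8)),
        elements=st.floats(-5, 5, allow_nan=False),
    )
)
def test_biclique_core_invariants_property(Shat):
    """The prefix objective and value identity hold on arbitrary matrices."""
    res = biclique_core(Shat, list(range(Shat.shape[0])))
    assert res.split_index >= 1
    i = res.split_index
    assert res.value == pytest.approx(i * res.drug_sums[i - 1] * Shat.shape[0])
    objective = [(j + 1) * res.drug_sums[j] for j in range(len(res.drug_sums))]
    assert i * res.drug_sums[i - 1] == pytest.approx(max(objective))
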