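import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from diffge import (
    CellLabels,
    ExpressionMatrix,
    GeneClustering,
    PPINetwork,
    build_sample_frame,
    cluster_activity,
    compute_entropy,
    differential_genes,
    edge_weight,
    match_clusters,
    select_top,
)
from diffge.entropy import activity_matrix
from _oracles import brute_force_entropy


class TestSampleFrame:
    def test_single_cell_normalization(self):
        m = ExpressionMatrix(["a", "b", "c"], ["c1"], np.array([[2.0], [3.0], [5.0]]), "log_tpm")
        frame = build_sample_frame(m)
        np.testing.assert_allclose(frame.values[:, 0], [0.2, 0.3, 0.5])

    def test_celltype_aggregation_means_before_normalizing(self):
        m = ExpressionMatrix(["a", "b"], ["c1", "c2"], np.array([[2.0, 0.0], [0.0, 2.0]]), "log_tpm")
        labels = CellLabels({"c1": "t", "c2": "t"})
        frame = build_sample_frame(m, labels=labels, aggregate=True)
        assert frame.samples == ["t"]
        np.testing.assert_allclose(frame.values[:, 0], [0.5, 0.5])

    def test_all_zero_cell_stays_zero(self):
        m = ExpressionMatrix(["a"], ["c1", "c2"], np.array([[1.0, 0.0]]), "log_tpm")
        frame = build_sample_frame(m)
        assert frame.values[0, 1] == 0.0

    def test_aggregate_without_labels_errors(self, tiny_expr):
        with pytest.raises(ValueError, match="labels"):
            build_sample_frame(tiny_expr, aggregate=True)


class TestEdgeWeightAndActivity:
    @pytest.mark.parametrize("a,b,w", [(0.5, 0.4, 0.2), (0.7, 0.0, 0.0), (1.0, 1.0, 1.0)])
    def test_edge_weight_is_product(self, a, b, w):
        assert edge_weight(a, b) == pytest.approx(w)
        assert edge_weight(b, a) == pytest.approx(w)

    def _abc_setup(self):
        clustering = GeneClustering({"A": 1, "B": 1, "C": 1}, K=1, sizes=[3],
                                    seed=0, converged=True, n_iter=1)
        ppi = PPINetwork.from_edges([("A", "B", 900), ("B", "C", 900)])
        subs = match_clusters(clustering, ppi)
        m = ExpressionMatrix(["A", "B", "C"], ["s1"], np.array([[0.5], [0.4], [0.1]]), "log_tpm")
        # values already sum to 1 -> normalization is the identity
        frame = build_sample_frame(m)
        return subs[0], frame

    def test_hand_computed_activity(self):
        sub, frame = self._abc_setup()
        # (0.5*0.4 + 0.4*0.1) / 3
        assert cluster_activity(sub, frame, "s1") == pytest.approx(0.08)

    def test_no_edges_gives_zero(self):
        clustering = GeneClustering({"A": 1, "B": 1}, K=1, sizes=[2], seed=0, converged=True, n_iter=1)
        subs = match_clusters(clustering, PPINetwork.from_edges([]))
        m = ExpressionMatrix(["A", "B"], ["s1"], np.array([[0.6], [0.4]]), "log_tpm")
        assert cluster_activity(subs[0], build_sample_frame(m), "s1") == 0.0

    def test_activity_matrix_agrees_with_scalar_path(self):
        sub, frame = self._abc_setup()
        W = activity_matrix([sub], frame)
        assert W[0, 0] == pytest.approx(cluster_activity(sub, frame, "s1"))


class TestComputeEntropy:
    def test_uniform_activity_attains_ln_s(self):
        table = compute_entropy(np.array([[1.0, 1.0, 1.0, 1.0]]), mode="per_cluster")
        assert table.entropy[0] == pytest.approx(math.log(4), abs=1e-12)

    def test_single_sample_activity_has_zero_entropy(self):
        table = compute_entropy(np.array([[0.0, 5.0, 0.0]]), mode="per_cluster")
        assert table.entropy[0] == 0.0

    def test_per_cell_hand_example(self):
        table = compute_entropy(np.array([[1.0, 3.0], [3.0, 1.0]]), mode="per_cell")
        np.testing.assert_allclose(table.shares, [[0.25, 0.75], [0.75, 0.25]])
        expected = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        np.testing.assert_allclose(table.entropy, [expected, expected], atol=1e-12)

    @pytest.mark.parametrize("mode", ["per_cell", "per_cluster"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((5, 6))
        W[rng.random((5, 6)) < 0.2] = 0.0  # exercise the 0 ln 0 branch
        table = compute_entropy(W, mode=mode)
        P, E = brute_force_entropy(W, mode)
        np.testing.assert_allclose(table.shares, P, atol=1e-12)
        np.testing.assert_allclose(table.entropy, E, atol=1e-12)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no expressed cluster edges"):
            compute_entropy(np.zeros((2, 3)))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_entropy(np.array([[1.0, -0.1]]))

    @given(arrays(np.float64, (4, 7), elements=st.floats(0, 100)).filter(lambda w: w.sum() > 0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalization_invariants(self, W):
        per_cell = compute_entropy(W, mode="per_cell")
        col_tot = W.sum(axis=0)
        sums = per_cell.shares.sum(axis=0)
        np.testing.assert_allclose(sums[col_tot > 0], 1.0, atol=1e-9)
        per_cluster = compute_entropy(W, mode="per_cluster")
        row_tot = W.sum(axis=1)
        sums = per_cluster.shares.sum(axis=1)
        np.testing.assert_allclose(sums[row_tot > 0], 1.0, atol=1e-9)
        assert np.all(per_cluster.entropy <= math.log(W.shape[1]) + 1e-9)
        assert np.all(per_cluster.entropy >= 0) and np.all(per_cell.entropy >= 0)

    @pytest.mark.parametrize("mode", ["per_cell", "per_cluster"])
    def test_scale_invariance_per_axis(self, mode):
        rng = np.random.default_rng(1)
        W = rng.random((4, 5)) + 0.1
        if mode == "per_cell":
            scaled = W * rng.uniform(0.5, 3.0, size=(1, 5))  # rescale samples
        else:
            scaled = W * rng.uniform(0.5, 3.0, size=(4, 1))  # rescale clusters
        a = compute_entropy(W, mode=mode)
        b = compute_entropy(scaled, mode=mode)
        np.testing.assert_allclose(a.shares, b.shares, atol=1e-12)
        np.testing.assert_allclose(a.entropy, b.entropy, atol=1e-12)

    def test_uniform_doubling_of_activities_preserves_entropy(self):
        """Counting both edge directions multiplies every activity by 2,
        which must leave shares and entropies unchanged in both modes."""
        rng = np.random.default_rng(2)
        W = rng.random((3, 6))
        for mode in ("per_cell", "per_cluster"):
            a = compute_entropy(W, mode=mode)
            b = compute_entropy(2 * W, mode=mode)
            np.testing.assert_allclose(a.entropy, b.entropy, atol=1e-12)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        W = rng.random((4, 8))
        perm = rng.permutation(8)
        for mode in ("per_cell", "per_cluster"):
            np.testing.assert_allclose(
                compute_entropy(W, mode=mode).entropy,
                compute_entropy(W[:, perm], mode=mode).entropy,
                atol=1e-12,
            )


class TestSelection:
    def _table(self, entropies, totals=None):
        K = len(entropies)
        if totals is None:
            totals = np.ones(K)
        W = np.outer(totals, np.ones(3)) / 3
        table = compute_entropy(W + 1e-12, mode="per_cluster")
        table.entropy = np.asarray(entropies, dtype=float)
        table.activities = np.outer(totals, np.ones(3)) / 3
        return table

    def test_ceil_rule(self):
        table = self._table(np.linspace(1, 2, 30))
        assert len(select_top(table, 0.1)) == 3
        table5 = self._table([1.0, 2.0, 3.0, 4.0, 5.0])
        assert select_top(table5, 0.1) == [5]

    def test_tie_breaks_on_total_activity_then_index(self):
        table = self._table([2.0, 1.0, 2.0], totals=[1.0, 1.0, 5.0])
        assert select_top(table, 0.3) == [3]  # E tie -> larger total activity wins
        table2 = self._table([2.0, 1.0, 2.0], totals=[1.0, 1.0, 1.0])
        assert select_top(table2, 0.3) == [1]  # full tie -> lower index wins

    def test_fraction_one_selects_everything(self):
        table = self._table([3.0, 1.0, 2.0])
        assert sorted(select_top(table, 1.0)) == [1, 2, 3]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            select_top(self._table([1.0, 2.0]), 0.0)


class TestDifferentialGenes:
    def _setup(self):
        clustering = GeneClustering(
            {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2, "g": 2},
            K=2, sizes=[3, 4], seed=0, converged=True, n_iter=1,
        )
        table = compute_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]), mode="per_cell")
        return clustering, table

    def test_union_of_selected_clusters(self):
        clustering, table = self._setup()
        select_top(table, 1.0)
        genes = differential_genes(clustering, table)
        assert genes["detected"].sum() == 7

    def test_scores_are_cluster_entropies(self):
        clustering, table = self._setup()
        select_top(table, 0.5)
        genes = differential_genes(clustering, table)
        by_cluster = genes.groupby("cluster")["score"].nunique()
        assert (by_cluster == 1).all()
        entropy_of = dict(zip(table.clusters, table.entropy))
        for _, row in genes.iterrows():
            assert row["score"] == pytest.approx(entropy_of[row["cluster"]])

    def test_no_selection_is_an_error(self):
        clustering, table = self._setup()
        with pytest.raises(ValueError, match="no clusters selected"):
            differential_genes(clustering, table)
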