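"""Distance tensors, group aggregation, clustering and trajectory summaries."""

import numpy as np
import pytest

from dtwnet import (
    AttributeSchema,
    DistanceTensor,
    aggregate_group,
    cluster_attributes,
    default_schema,
    linkage_to_newick,
    subject_distance_matrices,
    trajectory_summary,
    undirected_network,
)
from dtwnet.distances import read_matrix_csv, write_matrix_csv


def tensor_from(matrices, attributes):
    matrices = np.asarray(matrices, dtype=float)
    subjects = tuple(f"S{i:04d}" for i in range(1, matrices.shape[0] + 1))
    return DistanceTensor(subjects, tuple(attributes), matrices)


class TestSubjectMatrices:
    def test_identical_series_zero_entry(self, make_panel):
        v = np.zeros((1, 3, 2))
        v[0, :, 0] = [1.0, -1.0, 0.5]
        v[0, :, 1] = v[0, :, 0]
        t = subject_distance_matrices(make_panel(v))
        assert t.per_subject[0, 0, 1] == 0.0

    def test_constant_offset_pair(self, make_panel):
        v = np.zeros((1, 3, 2))
        v[0, :, 1] = 1.0
        t = subject_distance_matrices(make_panel(v))
        assert t.per_subject[0, 0, 1] == pytest.approx(1.0)

    def test_all_pairs_filled_symmetric(self, make_panel, rng):
        t = subject_distance_matrices(make_panel(rng.standard_normal((4, 6, 5))))
        m = t.per_subject
        assert np.allclose(m, m.transpose(0, 2, 1))
        assert np.allclose(np.diagonal(m, axis1=1, axis2=2), 0.0)
        offdiag = m[:, ~np.eye(5, dtype=bool)]
        assert np.all(offdiag > 0)

    def test_missing_data_rejected(self, make_panel, rng):
        v = rng.standard_normal((2, 3, 2))
        v[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            subject_distance_matrices(make_panel(v))


class TestAggregate:
    def test_single_subject_single_replicate_identity(self):
        m = [[0, 1.0], [1.0, 0]]
        agg = aggregate_group([tensor_from([m], ("a1", "a2"))])
        assert np.array_equal(agg.group_matrix, m)

    def test_subject_mean(self):
        t = tensor_from([[[0, 1], [1, 0]], [[0, 3], [3, 0]]], ("a1", "a2"))
        agg = aggregate_group([t])
        assert np.array_equal(agg.group_matrix, [[0, 2], [2, 0]])

    def test_replicate_mean_before_subjects(self):
        t1 = tensor_from([[[0, 0.4], [0.4, 0]]], ("a1", "a2"))
        t2 = tensor_from([[[0, 0.6], [0.6, 0]]], ("a1", "a2"))
        agg = aggregate_group([t1, t2])
        assert agg.per_subject[0, 0, 1] == pytest.approx(0.5)
        assert agg.n_imputations_pooled == 2

    def test_permutation_invariance(self, rng):
        mats = []
        for _ in range(3):
            m = np.abs(rng.standard_normal((4, 3, 3)))
            m = (m + m.transpose(0, 2, 1)) / 2
            m[:, np.eye(3, dtype=bool)] = 0
            mats.append(tensor_from(m, ("a1", "a2", "a3")))
        g1 = aggregate_group(mats).group_matrix
        g2 = aggregate_group(mats[::-1]).group_matrix
        assert np.allclose(g1, g2, atol=1e-15)

    def test_group_recomputable(self, rng):
        m = np.abs(rng.standard_normal((5, 3, 3)))
        m = (m + m.transpose(0, 2, 1)) / 2
        m[:, np.eye(3, dtype=bool)] = 0
        agg = aggregate_group([tensor_from(m, ("a1", "a2", "a3"))])
        assert np.allclose(agg.group_matrix, agg.recompute_group(), atol=1e-12)


class TestClustering:
    def test_block_matrix_recovers_two_clusters(self):
        d = np.full((4, 4), 1.0)
        d[np.ix_([0, 1], [0, 1])] = 0.2
        d[np.ix_([2, 3], [2, 3])] = 0.2
        np.fill_diagonal(d, 0.0)
        sol = cluster_attributes(d, ["a", "b", "c", "d"])
        assert sol.k == 2
        assert sol.labels["a"] == sol.labels["b"]
        assert sol.labels["c"] == sol.labels["d"]
        assert sol.labels["a"] != sol.labels["c"]

    def test_equal_distances_tie_gives_smallest_k(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        sol = cluster_attributes(d, ["a", "b", "c", "d"])
        assert sol.k == 2  # all silhouettes tie at 0; tie rule picks smallest

    def test_outlier_attribute_separated(self):
        d = np.array([[0.0, 0.1, 2.0], [0.1, 0.0, 2.0], [2.0, 2.0, 0.0]])
        sol = cluster_attributes(d, ["p", "q", "far"], k_range=(2, 2))
        assert sol.k == 2
        assert sol.labels["p"] == sol.labels["q"] != sol.labels["far"]

    def test_monotone_merge_heights(self, rng):
        m = np.abs(rng.standard_normal((6, 6)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        sol = cluster_attributes(m, [f"a{i}" for i in range(6)])
        heights = sol.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_attributes(np.zeros((3, 3)), ["a", "b", "c"])

    def test_newick_parses_with_all_leaves(self, rng):
        import dendropy

        m = np.abs(rng.standard_normal((5, 5)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        sol = cluster_attributes(m, [f"a{i}" for i in range(5)])
        tree = dendropy.Tree.get(data=linkage_to_newick(sol), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {f"a{i}" for i in range(5)}


class TestUndirectedNetwork:
    def test_weights_and_signs(self):
        schema = default_schema()
        attrs = ("depression", "anxiety", "well_being")
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        sol = cluster_attributes(d, attrs, k_range=(2, 2))
        net = undirected_network(d, sol, schema)
        edges = {(e["source"], e["target"]): e for e in net.edges}
        assert edges[("depression", "anxiety")]["weight"] == 1.0  # d = 0
        assert edges[("depression", "anxiety")]["sign"] == "positive"
        assert edges[("depression", "well_being")]["sign"] == "negative"
        assert edges[("depression", "well_being")]["weight"] == 0.5

    def test_nodes_carry_cluster_colors(self):
        d = np.array([[0.0, 0.1, 2.0], [0.1, 0.0, 2.0], [2.0, 2.0, 0.0]])
        sol = cluster_attributes(d, ("x", "y", "z"), k_range=(2, 2))
        net = undirected_network(d, sol, AttributeSchema.from_names(("x", "y", "z")))
        colors = {n["name"]: n["color"] for n in net.nodes}
        assert colors["x"] == colors["y"] != colors["z"]


class TestTrajectorySummary:
    def test_constant_attribute(self, make_panel):
        df = trajectory_summary(make_panel(np.full((3, 4, 1), 5.0)))
        assert np.allclose(df["mean"], 5.0)
        assert np.allclose(df["se"], 0.0)

    def test_balanced_mean_and_missing_excluded(self, make_panel):
        v = np.zeros((2, 3, 1))
        v[0, 0, 0], v[1, 0, 0] = 4.0, 6.0
        v[1, 2, 0] = np.nan
        v[0, 2, 0] = 9.0
        df = trajectory_summary(make_panel(v)).set_index("time")
        assert df.loc[0, "mean"] == 5.0
        assert df.loc[2, "mean"] == 9.0
        assert df.loc[2, "n_observed"] == 1


def test_matrix_csv_round_trip(tmp_path, rng):
    m = np.abs(rng.standard_normal((3, 3)))
    write_matrix_csv(m, ("a", "b", "c"), tmp_path / "m.csv")
    back, attrs = read_matrix_csv(tmp_path / "m.csv")
    assert attrs == ("a", "b", "c")
    assert np.allclose(back, m)
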