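"""Lead-lag contrasts, directed edge tests and strength centralities."""

import numpy as np
import pytest
from scipy import stats

from dtwnet import (
    DirectedDeltaTensor,
    directed_deltas,
    directed_graph,
    pool_deltas,
    strength_centrality,
)
from dtwnet.directed import test_directed_edges as run_edge_tests
from dtwnet.networks import read_edges_json, write_edges_json


def delta_tensor(per_subject, attributes):
    per_subject = np.asarray(per_subject, dtype=float)
    subjects = tuple(f"S{i:04d}" for i in range(1, per_subject.shape[0] + 1))
    return DirectedDeltaTensor(subjects, tuple(attributes), per_subject)


def antisym(rng, s, k, scale=1.0):
    m = rng.standard_normal((s, k, k)) * scale
    m = (m - m.transpose(0, 2, 1)) / 2
    m[:, np.eye(k, dtype=bool)] = 0
    return m


class TestDeltas:
    def test_identical_series_zero(self, make_panel):
        v = np.zeros((1, 4, 2))
        v[0, :, 0] = [0, 1, 0, 0]
        v[0, :, 1] = v[0, :, 0]
        t = directed_deltas(make_panel(v))
        assert t.per_subject[0, 0, 1] == 0.0

    def test_delayed_follower_positive_delta(self, make_panel):
        # b is a delayed one step: delta(a -> b) = 0.25 - 0.0
        v = np.zeros((1, 4, 2))
        v[0, :, 0] = [0, 1, 0, 0]
        v[0, :, 1] = [0, 0, 1, 0]
        t = directed_deltas(make_panel(v))
        assert t.per_subject[0, 0, 1] == pytest.approx(0.25)
        assert t.per_subject[0, 1, 0] == pytest.approx(-0.25)

    def test_antisymmetry_random(self, make_panel, rng):
        t = directed_deltas(make_panel(rng.standard_normal((5, 6, 4))))
        assert np.allclose(t.per_subject, -t.per_subject.transpose(0, 2, 1), atol=1e-12)
        assert np.allclose(t.group_mean, -t.group_mean.T, atol=1e-12)


class TestPooling:
    def test_single_replicate_identity(self, rng):
        t = delta_tensor(antisym(rng, 4, 3), ("a", "b", "c"))
        pooled = pool_deltas([t])
        assert np.array_equal(pooled.per_subject, t.per_subject)

    def test_replicates_averaged(self):
        t1 = delta_tensor([[[0, 0.2], [-0.2, 0]]], ("a", "b"))
        t2 = delta_tensor([[[0, 0.4], [-0.4, 0]]], ("a", "b"))
        pooled = pool_deltas([t1, t2])
        assert pooled.per_subject[0, 0, 1] == pytest.approx(0.3)
        assert pooled.n_imputations_pooled == 2

    def test_constant_deltas_zero_se(self):
        per = np.tile([[[0, 0.3], [-0.3, 0]]], (4, 1, 1))
        t = delta_tensor(per, ("a", "b"))
        assert t.group_se[0, 1] == 0.0


class TestEdgeTests:
    def test_all_zero_deltas_no_edges(self):
        t = delta_tensor(np.zeros((5, 3, 3)), ("a", "b", "c"))
        edges = run_edge_tests(t)
        assert not any(e.significant for e in edges)

    def test_positive_mean_detected_and_matches_t_formula(self, rng):
        vals = 0.25 + 0.05 * rng.standard_normal(100)
        per = np.zeros((100, 2, 2))
        per[:, 0, 1] = vals
        per[:, 1, 0] = -vals
        edges = {(e.source, e.target): e for e in run_edge_tests(delta_tensor(per, ("a", "b")))}
        e = edges[("a", "b")]
        # one-sided t computed directly from the subject deltas
        tstat = vals.mean() / (vals.std(ddof=1) / np.sqrt(100))
        p = float(stats.t.sf(tstat, df=99))
        assert e.statistic == pytest.approx(tstat)
        assert e.p_value == pytest.approx(p)
        assert e.significant
        assert not edges[("b", "a")].significant

    def test_sign_flip_reverses_direction(self, rng):
        per = antisym(rng, 20, 3) + 0.0
        per[:, 0, 1] += 0.5
        per[:, 1, 0] -= 0.5
        t = delta_tensor(per, ("a", "b", "c"))
        flipped = delta_tensor(-per, ("a", "b", "c"))
        e1 = {(e.source, e.target) for e in run_edge_tests(t) if e.significant}
        e2 = {(e.source, e.target) for e in run_edge_tests(flipped) if e.significant}
        assert ("a", "b") in e1
        assert ("b", "a") in e2 and ("a", "b") not in e2

    def test_at_most_one_direction_significant(self, rng):
        t = delta_tensor(antisym(rng, 30, 4, scale=0.3), tuple("abcd"))
        edges = run_edge_tests(t, alpha=0.2)
        sig = {(e.source, e.target) for e in edges if e.significant}
        assert not any((b, a) in sig for a, b in sig)

    def test_alpha_monotonicity(self, rng):
        t = delta_tensor(antisym(rng, 15, 3, scale=0.3), ("a", "b", "c"))
        # alpha = 1 flags every positive-mean pair; alpha -> 0 flags none
        for e in run_edge_tests(t, alpha=1.0):
            if e.mean_delta > 0:
                assert e.significant
        assert not [
            e for e in run_edge_tests(t, alpha=1e-12)
            if e.significant and not e.zero_variance
        ]
        sig_by_alpha = [
            sum(e.significant for e in run_edge_tests(t, alpha=a))
            for a in (0.01, 0.05, 0.2, 1.0)
        ]
        assert sig_by_alpha == sorted(sig_by_alpha)

    def test_zero_variance_convention(self):
        per = np.tile([[[0, 0.3], [-0.3, 0]]], (5, 1, 1))
        edges = {
            (e.source, e.target): e
            for e in run_edge_tests(delta_tensor(per, ("a", "b")))
        }
        assert edges[("a", "b")].significant and edges[("a", "b")].zero_variance
        assert not edges[("b", "a")].significant

    def test_bonferroni_is_more_conservative(self, rng):
        t = delta_tensor(antisym(rng, 25, 4, scale=0.3), tuple("abcd"))
        raw = sum(e.significant for e in run_edge_tests(t, alpha=0.2))
        corr = sum(
            e.significant
            for e in run_edge_tests(t, alpha=0.2, correction="bonferroni")
        )
        assert corr <= raw

    def test_too_few_subjects_rejected(self, rng):
        t = delta_tensor(antisym(rng, 2, 3), ("a", "b", "c"))
        with pytest.raises(ValueError, match="3 subjects"):
            run_edge_tests(t)


class TestStrengths:
    def test_raw_and_standardized_arithmetic(self):
        # delta(1->2)=0.3, delta(1->3)=0.2, delta(2->3)=0:
        # raw out = (0.5, 0, 0); standardized out centers by 1/6
        per = np.zeros((3, 3, 3))
        per[:, 0, 1], per[:, 1, 0] = 0.3, -0.3
        per[:, 0, 2], per[:, 2, 0] = 0.2, -0.2
        t = delta_tensor(per, ("n1", "n2", "n3"))
        est = {(s.node, s.kind): s for s in strength_centrality(t)}
        assert est[("n1", "out")].raw_mean == pytest.approx(0.5)
        assert est[("n2", "out")].raw_mean == 0.0
        assert est[("n2", "in")].raw_mean == pytest.approx(0.3)
        assert est[("n3", "in")].raw_mean == pytest.approx(0.2)
        assert est[("n1", "out")].standardized_mean == pytest.approx(0.5 - 1 / 6)
        assert est[("n2", "out")].standardized_mean == pytest.approx(-1 / 6)

    def test_standardized_sum_zero_per_kind(self, rng):
        t = delta_tensor(antisym(rng, 10, 5), tuple("abcde"))
        est = strength_centrality(t)
        for kind in ("out", "in"):
            total = sum(s.standardized_mean for s in est if s.kind == kind)
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_nothing_significant(self):
        t = delta_tensor(np.zeros((4, 3, 3)), ("a", "b", "c"))
        est = strength_centrality(t)
        assert all(s.standardized_mean == 0 for s in est)
        assert not any(s.significant for s in est)

    def test_ci_uses_t_quantile(self, rng):
        per = antisym(rng, 12, 4)
        t = delta_tensor(per, tuple("abcd"))
        est = strength_centrality(t)
        pos = np.maximum(per, 0.0)
        out = pos.sum(axis=2)
        std = out - out.mean(axis=1, keepdims=True)
        tcrit = stats.t.ppf(0.975, df=11)
        target = std[:, 0].mean() - tcrit * std[:, 0].std(ddof=1) / np.sqrt(12)
        got = [s for s in est if s.node == "a" and s.kind == "out"][0]
        assert got.ci_low == pytest.approx(target)


class TestDirectedExport:
    def test_round_trip_edge_set(self, tmp_path, rng):
        per = antisym(rng, 20, 3, scale=0.3)
        per[:, 0, 1] += 0.5
        per[:, 1, 0] -= 0.5
        t = delta_tensor(per, ("a", "b", "c"))
        edges = run_edge_tests(t)
        strengths = strength_centrality(t)
        g = directed_graph(edges, strengths)
        path = tmp_path / "directed.json"
        write_edges_json(g, path)
        back = read_edges_json(path)
        assert back["directed"] is True
        got = {(e["source"], e["target"]) for e in back["edges"]}
        assert got == {(e.source, e.target) for e in edges if e.significant}

    def test_empty_edge_set_valid(self):
        t = delta_tensor(np.zeros((4, 3, 3)), ("a", "b", "c"))
        g = directed_graph(run_edge_tests(t), strength_centrality(t))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3
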