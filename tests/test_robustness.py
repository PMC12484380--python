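import itertools

import networkx as nx
import numpy as np
import pytest

from tickmicro import robustness, synthdata
from tickmicro.robustness import (
    AdditionResult,
    add_random_nodes,
    addition_stats,
    attack,
    connectivity_loss,
    lcc_and_apl,
    loss_se,
)
from tickmicro.tables_io import CooccurrenceNetwork


def brute_force_loss(g: nx.Graph, removed) -> float:
    """Oracle: reachable ordered pairs via boolean transitive closure."""

    def pairs(graph):
        nodes = sorted(graph.nodes)
        n = len(nodes)
        if n == 0:
            return 0
        a = nx.to_numpy_array(graph, nodelist=nodes, weight=None).astype(bool)
        np.fill_diagonal(a, True)
        reach = a.copy()
        for _ in range(n):
            new = reach @ reach
            if (new == reach).all():
                break
            reach = new
        return int(reach.sum()) - n  # ordered pairs, excluding self

    base = pairs(g)
    if base == 0:
        return 0.0
    surviving = g.subgraph([n for n in g.nodes if n not in set(removed)])
    return 1.0 - pairs(surviving) / base


class TestConnectivityLoss:
    def test_empty_removal_is_zero(self, toy_suite):
        for net in toy_suite.values():
            assert connectivity_loss(net, set()) == 0.0

    def test_star_hub_removal_total_loss(self):
        net = synthdata.generate_toy_graph("star", 6)
        hub = max(net.graph.degree, key=lambda kv: kv[1])[0]
        assert connectivity_loss(net, {hub}) == 1.0

    def test_path_center_removal(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        assert connectivity_loss(CooccurrenceNetwork(g), {"b"}) == 1.0

    def test_unknown_node_rejected(self, toy_suite):
        with pytest.raises(ValueError, match="not in graph"):
            connectivity_loss(toy_suite["star8"], {"ghost"})

    def test_matches_brute_force_exhaustively(self, toy_suite):
        """All fixture graphs <= 12 nodes, every removal set of size <= 3."""
        for net in toy_suite.values():
            g = net.graph
            nodes = sorted(g.nodes)
            assert len(nodes) <= 12
            subsets = itertools.chain.from_iterable(
                itertools.combinations(nodes, k) for k in range(4)
            )
            for removed in subsets:
                assert connectivity_loss(net, set(removed)) == pytest.approx(
                    brute_force_loss(g, removed), abs=1e-12
                )


class TestAttack:
    def test_loss_curves_monotone_and_bounded(self, toy_suite):
        for net in toy_suite.values():
            if net.n_edges == 0:
                continue
            for strat in robustness.ATTACK_STRATEGIES:
                res = attack(net, strat, seed=0, n_reps=30)
                assert res.loss[0] == 0.0
                assert res.loss[-1] == pytest.approx(1.0)
                assert (np.diff(res.loss) >= -1e-12).all()

    def test_star_degree_attack_immediate(self):
        net = synthdata.generate_toy_graph("star", 10)
        res = attack(net, "degree")
        assert res.loss[1] == 1.0
        assert res.frac_for_80 <= 1 / 10

    def test_k10_closed_form_all_strategies(self):
        """On K10 every strategy's loss is 1 - (10-m)(10-m-1)/90 for all m."""
        net = synthdata.generate_toy_graph("complete", 10)
        expected = np.array([1 - (10 - m) * (9 - m) / 90 for m in range(11)])
        for strat in ("degree", "betweenness", "cascading"):
            res = attack(net, strat)
            assert np.allclose(res.loss, expected, atol=1e-12)
        rand = attack(net, "random", seed=1, n_reps=30)
        assert np.allclose(rand.loss, expected, atol=1e-12)  # order-invariant on K_n

    def test_cascading_equals_betweenness_on_disjoint_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        net = CooccurrenceNetwork(g)
        casc = attack(net, "cascading")
        betw = attack(net, "betweenness")
        assert np.allclose(casc.loss, betw.loss)
        assert casc.removal_order == betw.removal_order

    def test_targeted_beats_random_on_average(self, toy_suite):
        # Restricted to graphs whose centralities distinguish nodes: on a
        # union of identical cliques every ranking ties, the lexicographic
        # cascade dismantles one clique at a time, and spreading removals at
        # random is genuinely more destructive.
        for name in ("star8", "path7", "complete6", "er12", "er10"):
            net = toy_suite[name]
            casc = attack(net, "cascading").loss
            rand = attack(net, "random", seed=3, n_reps=40).loss
            assert (casc >= rand - 1e-9).all(), name

    def test_deterministic_given_seed(self, toy_suite):
        net = toy_suite["er12"]
        a = attack(net, "random", seed=5, n_reps=30)
        b = attack(net, "random", seed=5, n_reps=30)
        assert np.array_equal(a.loss, b.loss)
        assert np.array_equal(a.ci_low, b.ci_low)

    def test_unknown_strategy_rejected(self, toy_suite):
        with pytest.raises(ValueError, match="strategy"):
            attack(toy_suite["star8"], "voltage")


class TestLossSE:
    def test_zero_on_symmetric_graph(self):
        # on K8 every removal order produces the same curve -> SE = 0
        net = synthdata.generate_toy_graph("complete", 8)
        res = attack(net, "random", seed=0, n_reps=30)
        se = loss_se(res)
        assert np.allclose(se["se"], 0.0)

    def test_nonnegative_and_scales_with_reps(self):
        net = synthdata.generate_toy_graph("erdos_renyi", 20, p=0.15, seed=2)
        se30 = loss_se(attack(net, "random", seed=1, n_reps=30))["se"]
        se120 = loss_se(attack(net, "random", seed=1, n_reps=120))["se"]
        assert (se30 >= 0).all()
        mid = slice(3, 17)  # interior points with nonzero variability
        ratio = se30[mid].mean() / se120[mid].mean()
        assert 1.5 < ratio < 2.5  # ~ sqrt(120/30) = 2

    def test_requires_random_replicates(self, toy_suite):
        res = attack(toy_suite["star8"], "degree")
        with pytest.raises(ValueError, match="replicates"):
            loss_se(res)


class TestAddition:
    def test_k0_identity(self, toy_suite):
        net = toy_suite["two_cliques8"]
        res = add_random_nodes(net, 0, n_reps=10, seed=0)
        assert (res.lcc == res.baseline_lcc).all()
        assert np.allclose(res.apl, res.baseline_apl)
        assert res.baseline_lcc == 4
        assert res.baseline_apl == pytest.approx(1.0)  # cliques: all pairs adjacent

    def test_attach_p_one_connects_everything(self):
        net = synthdata.generate_toy_graph("two_cliques", 8)
        res = add_random_nodes(net, 5, attach_p=1.0, n_reps=5, seed=1)
        assert (res.lcc == 13).all()

    def test_attach_p_zero_changes_nothing(self):
        net = synthdata.generate_toy_graph("path", 6)
        res = add_random_nodes(net, 7, attach_p=0.0, n_reps=5, seed=1)
        assert (res.lcc == res.baseline_lcc).all()
        assert np.allclose(res.apl, res.baseline_apl)  # isolates excluded from APL

    def test_apl_finite_on_disconnected(self):
        net = synthdata.generate_toy_graph("two_cliques", 8)
        res = add_random_nodes(net, 10, attach_p=0.1, n_reps=5, seed=3)
        assert np.isfinite(res.apl).all()

    def test_lcc_bounded_by_total(self, toy_suite):
        net = toy_suite["er10"]
        res = add_random_nodes(net, 20, n_reps=5, seed=2)
        assert (res.lcc <= net.n_nodes + 20).all()

    def test_unknown_rule_rejected(self, toy_suite):
        with pytest.raises(ValueError, match="attachment"):
            add_random_nodes(toy_suite["er10"], 5, attachment="preferential??")

    def test_lcc_equals_n_iff_connected(self, toy_suite):
        import scipy.sparse as sp

        for net in toy_suite.values():
            adj = nx.to_scipy_sparse_array(net.graph, weight=None, format="csr")
            lcc, _ = lcc_and_apl(adj)
            assert (lcc == net.n_nodes) == nx.is_connected(net.graph)


class TestAdditionStats:
    def _result(self, values, baseline, k=100):
        values = np.asarray(values, dtype=float)
        return AdditionResult(
            k=k, attachment="density", lcc=values, apl=values + 1.0,
            baseline_lcc=int(baseline), baseline_apl=float(baseline) + 1.0,
            n_reps=len(values),
        )

    def test_symmetric_replicates_large_p(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(30):
            vals = 10 + rng.normal(0, 1, 20)  # symmetric around the baseline
            out = addition_stats({100: self._result(vals, 10)})
            ps.append(out["wilcoxon_p_lcc"].item())
        assert np.mean(ps) > 0.4

    def test_all_above_baseline_minimum_p(self):
        vals = 10 + np.arange(1, 21)  # 20 replicates strictly above baseline
        out = addition_stats({100: self._result(vals, 10)})
        import scipy.stats as sps

        expected = sps.wilcoxon(vals - 10).pvalue
        assert out["wilcoxon_p_lcc"].item() == pytest.approx(expected)
        assert out["wilcoxon_p_lcc"].item() < 1e-3

    def test_identical_to_baseline_p_one(self):
        out = addition_stats({100: self._result(np.full(12, 10.0), 10)})
        assert out["wilcoxon_p_lcc"].item() == 1.0

    def test_bh_monotone_across_k(self):
        rng = np.random.default_rng(4)
        results = {
            k: self._result(10 + rng.normal(d, 1, 15), 10, k=k)
            for k, d in [(100, 0.1), (300, 0.8), (500, 2.0)]
        }
        out = addition_stats(results).sort_values("wilcoxon_p_lcc")
        assert out["p_adj_lcc"].is_monotonic_increasing
        assert (out["p_adj_lcc"] >= out["wilcoxon_p_lcc"] - 1e-12).all()

    def test_requires_ten_replicates(self):
        with pytest.raises(ValueError, match="10 replicates"):
            addition_stats({100: self._result(np.arange(5.0), 2)})
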