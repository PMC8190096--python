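"""Network construction, metrics, and the cross-treatment permutation test."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from guildnet import build_network, network_metrics, permtest_metric
from guildnet.networks import Network


def _net(edge_list, name="A"):
    g = nx.Graph()
    for a, b in edge_list:
        g.add_edge(a, b, sign="+")
    return Network(treatment=name, graph=g)


def _matrices(genera, sig_pairs, rho_val=0.8):
    n = len(genera)
    rho = pd.DataFrame(np.eye(n), index=genera, columns=genera)
    p = pd.DataFrame(np.ones((n, n)), index=genera, columns=genera)
    for a, b in sig_pairs:
        i, j = genera.index(a), genera.index(b)
        rho.iloc[i, j] = rho.iloc[j, i] = rho_val
        p.iloc[i, j] = p.iloc[j, i] = 0.01
    return rho, p


class TestBuildNetwork:
    def test_all_insignificant_gives_empty_network(self):
        rho, p = _matrices(list("abcd"), [])
        net = build_network(rho, p)
        m = net.metrics()
        assert m["n_nodes"] == m["n_edges"] == 0
        assert m["empty"]

    def test_isolated_genus_excluded(self):
        genera = list("abcde")
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]  # e isolated
        rho, p = _matrices(genera, pairs)
        net = build_network(rho, p)
        assert set(net.nodes) == {"a", "b", "c", "d"}
        assert net.metrics()["n_edges"] == 4

    def test_edge_signs_match_rho(self):
        rho, p = _matrices(list("abcd"), [("a", "b")], rho_val=-0.6)
        net = build_network(rho, p)
        assert net.graph["a"]["b"]["sign"] == "-"
        m = net.metrics()
        assert m["n_neg"] == 1 and m["n_pos"] == 0

    def test_zero_rho_significant_guarded(self):
        rho, p = _matrices(list("abcd"), [("a", "b")], rho_val=0.0)
        with pytest.raises(ValueError, match="rho == 0"):
            build_network(rho, p)

    def test_conformability_checked(self):
        rho, _ = _matrices(list("abcd"), [])
        _, p = _matrices(list("abc"), [])
        with pytest.raises(ValueError):
            build_network(rho, p)


class TestNetworkMetrics:
    @pytest.mark.parametrize(
        "edges, n_nodes, connectance, mean_degree",
        [
            ([("a", "b"), ("c", "d")], 4, 2 / 16, 1.0),
            ([("a", "b"), ("b", "c"), ("a", "c")], 3, 3 / 9, 2.0),
            ([("a", "b")], 2, 1 / 4, 1.0),
        ],
    )
    def test_formulas_exact(self, edges, n_nodes, connectance, mean_degree):
        m = network_metrics(_net(edges))
        assert m["n_nodes"] == n_nodes
        assert m["connectance"] == connectance
        assert m["mean_degree"] == mean_degree

    def test_empty_network_flagged(self):
        m = network_metrics(_net([]))
        assert m == {
            "n_nodes": 0, "n_edges": 0, "n_pos": 0, "n_neg": 0,
            "connectance": 0.0, "mean_degree": 0.0, "empty": True,
        }


class TestPermtest:
    def test_identical_networks_give_p_one(self):
        net = _net([("a", "b"), ("b", "c")])
        res = permtest_metric(net, _net([("a", "b"), ("b", "c")], "B"),
                              "n_edges", n_perm=200, seed=1)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_three_pair_oracle(self):
        """Monte-Carlo p matches exact enumeration over the 8 swap patterns."""
        genera = ["x", "y", "z"]
        a_edges = [("x", "y"), ("x", "z"), ("y", "z")]
        b_edges = [("x", "y")]
        net_a, net_b = _net(a_edges), _net(b_edges, "B")
        a = [1, 1, 1]
        b = [1, 0, 0]
        obs = sum(a) - sum(b)
        exact_diffs = []
        for mask in itertools.product([0, 1], repeat=3):
            pa = [b[i] if mask[i] else a[i] for i in range(3)]
            pb = [a[i] if mask[i] else b[i] for i in range(3)]
            exact_diffs.append(sum(pa) - sum(pb))
        exact_p = np.mean([abs(d) >= abs(obs) for d in exact_diffs])
        res = permtest_metric(net_a, net_b, "n_edges", n_perm=10_000, seed=2,
                              union_genera=genera)
        se = np.sqrt(exact_p * (1 - exact_p) / 10_000)
        assert abs(res.p_value - exact_p) < 3 * se + 2 / 10_001

    def test_extreme_separation_small_p(self):
        genera = [f"g{i}" for i in range(8)]  # 28 pairs > 20
        a_edges = list(itertools.combinations(genera[:5], 2))  # 10 edges
        res = permtest_metric(_net(a_edges), _net([], "B"), "n_edges",
                              n_perm=10_000, seed=3, union_genera=genera)
        assert res.p_value <= 0.01

    def test_p_never_zero(self):
        genera = [f"g{i}" for i in range(10)]
        a_edges = list(itertools.combinations(genera, 2))
        res = permtest_metric(_net(a_edges), _net([], "B"), "n_edges",
                              n_perm=500, seed=4, union_genera=genera)
        assert res.p_value >= 1 / 501

    def test_global_shuffle_preserves_edge_total(self):
        """Pooled reshuffle conserves the total number of edges across both networks."""
        genera = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        pairs = list(itertools.combinations(genera, 2))
        a_edges = [p for p in pairs if rng.random() < 0.4]
        b_edges = [p for p in pairs if rng.random() < 0.4]
        total = len(a_edges) + len(b_edges)
        for shuffle in ("pairwise", "global"):
            res = permtest_metric(_net(a_edges), _net(b_edges, "B"), "n_edges",
                                  n_perm=300, seed=5, union_genera=genera,
                                  shuffle=shuffle)
            # sum is conserved <=> null diffs share parity/range with observed total
            assert abs(res.null_mean) <= total
            assert res.null_quantiles["q97.5"] <= total

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            permtest_metric(_net([("a", "b")]), _net([], "B"), "diameter", n_perm=10)

    def test_union_must_cover_nodes(self):
        with pytest.raises(ValueError, match="union_genera"):
            permtest_metric(_net([("a", "b")]), _net([], "B"), "n_edges",
                            n_perm=10, union_genera=["a"])

    def test_pairwise_swap_conserves_pair_multiset(self):
        """With a degenerate pair multiset {1,1}, every permuted diff is 0."""
        net_a = _net([("a", "b")])
        net_b = _net([("a", "b")], "B")
        res = permtest_metric(net_a, net_b, "n_edges", n_perm=100, seed=6,
                              union_genera=["a", "b"])
        assert res.null_mean == 0.0 and res.null_sd == 0.0

    def test_type_one_error_under_exchangeability(self):
        """Both networks drawn from one edge-probability vector: ~5% rejections."""
        rng = np.random.default_rng(7)
        genera = [f"g{i}" for i in range(10)]
        pairs = list(itertools.combinations(genera, 2))
        rejections = 0
        n_tests = 200
        for t in range(n_tests):
            pe = rng.uniform(0.2, 0.6, size=len(pairs))
            a_flags = rng.random(len(pairs)) < pe
            b_flags = rng.random(len(pairs)) < pe
            net_a = _net([p for p, f in zip(pairs, a_flags) if f])
            net_b = _net([p for p, f in zip(pairs, b_flags) if f], "B")
            res = permtest_metric(net_a, net_b, "n_edges", n_perm=1000,
                                  seed=10_000 + t, union_genera=genera)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_tests <= 0.09
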