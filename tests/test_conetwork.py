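import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilwebdex.conetwork import (
    CoNetwork,
    build_network,
    edge_list,
    global_efficiency,
    network_summary,
    node_roles,
    robustness,
    spearman_pvalue,
    topology,
    vulnerability,
)
from soilwebdex.io_tables import ValidationError
from soilwebdex.synth import generate_test_graphs, planted_two_block_table


def _net(g: nx.Graph, n_samples: int = 8) -> CoNetwork:
    for u, v in g.edges:
        g.edges[u, v].setdefault("rho", 1.0)
        g.edges[u, v].setdefault("sign", "+")
    return CoNetwork(graph=g, n_samples=n_samples)


# ---------------------------------------------------------------------------
# brute-force oracles

def _floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def _oracle_metrics(g: nx.Graph) -> dict:
    nodes = list(g.nodes)
    n = len(nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes)
    L = adj.sum() / 2
    d = _floyd_warshall(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    # local clustering by triangle count: 2*T_i / (k_i (k_i - 1))
    k = adj.sum(axis=1)
    tri = np.diag(adj @ adj @ adj) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)
    with np.errstate(divide="ignore"):
        inv_d = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return {
        "avgK": 2.0 * L / n,
        "avgCC": cc.mean(),
        "GD": d[finite].mean() if finite.any() else np.nan,
        "Con": L / (n * (n - 1) / 2.0),
        "efficiency": inv_d[off].sum() / (n * (n - 1)),
    }


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


# ---------------------------------------------------------------------------

class TestSpearmanScreen:
    def test_exact_p_matches_direct_enumeration(self):
        # oracle: permute y, Pearson correlation of ranks, two-sided count
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = stats.pearsonr(rx, ry)[0]
        null = [stats.pearsonr(rx, np.array(p))[0]
                for p in itertools.permutations(ry)]
        p_oracle = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        assert spearman_pvalue(obs, 5) == pytest.approx(p_oracle)

    def test_perfect_monotone_pair_gets_positive_edge(self):
        x = np.arange(8.0)
        table = pd.DataFrame({"f1": x, "f2": np.exp(x), "f3": 5.0 + 0 * x,
                              "f4": [3, 1, 4, 1, 5, 9, 2, 6]})
        net = build_network(table)
        assert net.graph.has_edge("f1", "f2")
        assert net.graph.edges["f1", "f2"]["rho"] == pytest.approx(1.0)
        assert net.graph.edges["f1", "f2"]["sign"] == "+"

    def test_constant_feature_excluded(self):
        table = pd.DataFrame({"f1": np.arange(8.0), "f2": np.full(8, 2.0),
                              "f3": np.arange(8.0)[::-1]})
        net = build_network(table)
        assert "f2" not in net.nodes

    def test_low_prevalence_feature_excluded(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "sparse": [0, 0, 0, 0, 0, 0, 1, 2],
            "dense1": rng.normal(size=8), "dense2": rng.normal(size=8)})
        net = build_network(table)
        assert "sparse" not in net.nodes

    def test_screen_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(8, 10)),
                             columns=[f"f{i}" for i in range(10)])
        counts = [build_network(table, rho_threshold=t, alpha=1.0).n_edges
                  for t in (0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_false_edge_rate_controlled(self):
        # independent features: compound screen keeps well under alpha
        rng = np.random.default_rng(3)
        rates = []
        for _ in range(60):
            table = pd.DataFrame(rng.normal(size=(8, 10)),
                                 columns=[f"f{i}" for i in range(10)])
            net = build_network(table)
            rates.append(net.n_edges / 45)
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert rates.mean() <= 0.05 + 3 * se

    def test_too_few_samples(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValidationError):
            build_network(table)


class TestTopology:
    def test_complete_graph_identities(self):
        m = topology(_net(nx.complete_graph(6)))
        assert (m.avgK, m.avgCC, m.GD, m.Con) == (5.0, 1.0, 1.0, 1.0)
        assert m.n_pos_links == 15 and m.n_neg_links == 0

    def test_path_graph_hand_enumeration(self):
        m = topology(_net(nx.path_graph(4)))
        assert m.avgK == pytest.approx(1.5)
        assert m.avgCC == 0.0
        assert m.GD == pytest.approx(10 / 6)
        assert m.Con == pytest.approx(0.5)

    def test_two_triangles_modularity_vs_exhaustive(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        m = topology(_net(g))
        assert m.n_modules == 2
        best = max(
            nx.community.modularity(g, [set(c) for c in part])
            for part in _all_partitions(list(g.nodes))
        )
        assert m.modularity == pytest.approx(best)
        assert m.modularity == pytest.approx(0.5)

    @pytest.mark.parametrize("n,p,seed", [
        (5, 0.4, 0), (6, 0.5, 1), (7, 0.3, 2), (8, 0.5, 3), (8, 0.2, 4),
    ])
    def test_matches_brute_force_on_random_graphs(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        expected = _oracle_metrics(g)
        m = topology(_net(g.copy()))
        assert m.avgK == pytest.approx(expected["avgK"])
        assert m.avgCC == pytest.approx(expected["avgCC"])
        assert m.Con == pytest.approx(expected["Con"])
        if not np.isnan(expected["GD"]):
            assert m.GD == pytest.approx(expected["GD"])
        assert global_efficiency(g) == pytest.approx(expected["efficiency"])

    def test_all_four_node_graphs_match_oracle(self):
        # exhaustive over every labeled graph on 4 nodes with >=1 edge
        pairs = list(itertools.combinations(range(4), 2))
        for mask in range(1, 2 ** len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(range(4))
            g.add_edges_from(e for i, e in enumerate(pairs) if mask >> i & 1)
            expected = _oracle_metrics(g)
            m = topology(_net(g.copy()))
            assert m.avgK == pytest.approx(expected["avgK"])
            assert m.avgCC == pytest.approx(expected["avgCC"])
            assert m.Con == pytest.approx(expected["Con"])
            if not np.isnan(expected["GD"]):
                assert m.GD == pytest.approx(expected["GD"])
            assert global_efficiency(g) == pytest.approx(
                expected["efficiency"])

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(7, 0.4, seed=9)
        relabeled = nx.relabel_nodes(g, {i: f"taxon_{i}" for i in g.nodes})
        a, b = topology(_net(g.copy())), topology(_net(relabeled))
        for attr in ("avgK", "avgCC", "GD", "Con", "modularity", "n_modules"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))


class TestRobustness:
    def test_complete_graph_exactly_one(self):
        assert robustness(_net(nx.complete_graph(6)), seed=0) == 1.0

    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(6)
        assert robustness(_net(g), seed=0) == 0.0

    def test_star_matches_exact_enumeration(self):
        g = nx.star_graph(5)  # center 0 + 5 leaves
        scores = []
        for removed in itertools.combinations(range(6), 3):
            survivors = set(range(6)) - set(removed)
            alive = sum(
                1 for v in survivors
                if any(u in survivors for u in g.neighbors(v)))
            scores.append(alive / len(survivors))
        exact = np.mean(scores)
        assert exact == pytest.approx(0.5)
        est = robustness(_net(g.copy()), remove_fraction=0.5, reps=1000,
                         seed=4)
        se = np.sqrt(0.25 / 1000)  # per-rep scores are Bernoulli(0.5)
        assert abs(est - exact) < 3 * se

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            robustness(_net(nx.complete_graph(4)), remove_fraction=1.5)


class TestVulnerability:
    def test_path3_is_one(self):
        net = _net(nx.path_graph(3))
        assert global_efficiency(net.graph) == pytest.approx(5 / 6)
        assert vulnerability(net) == pytest.approx(1.0)

    def test_complete_graph_zero(self):
        assert vulnerability(_net(nx.complete_graph(4))) == pytest.approx(0.0)

    def test_bounded_by_one(self):
        for seed in range(5):
            g = nx.gnp_random_graph(7, 0.4, seed=seed)
            if g.number_of_edges() == 0:
                continue
            assert vulnerability(_net(g)) <= 1.0 + 1e-12


class TestNodeRoles:
    def test_single_module_clique_all_peripheral(self):
        net = _net(nx.complete_graph(5))
        m = topology(net)
        roles = node_roles(net, m.partition)
        assert (roles["Zi"] == 0).all()
        assert (roles["Pi"] == 0).all()
        assert (roles["role"] == "peripheral").all()
        assert roles["keystone"].sum() == 0

    def test_participation_split_between_two_modules(self):
        g = nx.Graph([(0, 1), (0, 2), ("x", 1), ("x", 2)])
        partition = [frozenset({0, 1}), frozenset({"x", 2})]
        roles = node_roles(_net(g), partition)
        # node 0: one edge in own module, one across -> Pi = 1 - 2*(1/2)^2
        assert roles.loc[0, "Pi"] == pytest.approx(0.5)

    def test_constructed_module_hub(self):
        # hub wired to all 20 members of its module; members chained so
        # their within-module degree stays ~3
        g = nx.Graph()
        members = [f"m{i}" for i in range(20)]
        for m_ in members:
            g.add_edge("hub", m_)
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
        # second, disconnected module to make participation meaningful
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        partition = [frozenset(members + ["hub"]), frozenset({"a", "b", "c"})]
        roles = node_roles(_net(g), partition)
        assert roles.loc["hub", "Zi"] > 2.5
        assert roles.loc["hub", "Pi"] == 0.0
        assert roles.loc["hub", "role"] == "module hub"
        assert roles.loc["hub", "keystone"]

    def test_partition_must_cover_nodes(self):
        net = _net(nx.path_graph(3))
        with pytest.raises(ValidationError):
            node_roles(net, [frozenset({0, 1})])


class TestNetworkSummary:
    def test_enzyme_table_edge_bound(self, small_bundle):
        table = small_bundle["activity"].values.iloc[:8]
        net, metrics, roles = network_summary(table, seed=1)
        assert net.n_edges <= 28
        assert len(roles) == len(net.nodes)

    def test_planted_two_block_recovers_modules(self):
        table = planted_two_block_table(seed=5)
        net, metrics, roles = network_summary(table, seed=1)
        assert metrics.n_modules == 2
        blocks = [frozenset(c) for c in metrics.partition if len(c) >= 2]
        names = sorted(frozenset(n[0] for n in c) for c in blocks)
        assert names == [frozenset("A"), frozenset("B")]

    def test_edge_list_round_trip(self):
        table = planted_two_block_table(seed=6)
        net, _, _ = network_summary(table, seed=1)
        el = edge_list(net)
        assert set(el.columns) == {"node1", "node2", "rho", "sign"}
        assert len(el) == net.n_edges


class TestGraphFixtures:
    def test_attached_ground_truth_matches_module(self):
        for fx in generate_test_graphs():
            net = _net(fx["graph"].copy())
            expected = fx["expected"]
            if {"avgK", "avgCC", "GD", "Con"} & set(expected):
                m = topology(net)
                for key in ("avgK", "avgCC", "GD", "Con"):
                    if key in expected:
                        assert getattr(m, key) == pytest.approx(
                            expected[key]), fx["name"]
            if "n_modules" in expected:
                assert topology(net).n_modules == expected["n_modules"]
            if "modularity" in expected:
                assert topology(net).modularity == pytest.approx(
                    expected["modularity"])
            if "vulnerability" in expected:
                assert vulnerability(net) == pytest.approx(
                    expected["vulnerability"])
            if "efficiency" in expected:
                assert global_efficiency(net.graph) == pytest.approx(
                    expected["efficiency"])
            if "robustness" in expected:
                assert robustness(net, seed=0) == pytest.approx(
                    expected["robustness"])
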