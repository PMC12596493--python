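import itertools

import numpy as np
import pytest

from multimorbnet.netbuild import (
    ContingencyTable,
    MultimorbidityNetwork,
    NetworkCriteria,
    PatternEdge,
)
from multimorbnet.netmetrics import (
    CoverageStats,
    compute_metrics,
    coverage,
    hub_associated_network,
    hub_network,
    top_hubs,
)
from oracles import (
    betweenness_oracle,
    closeness_oracle,
    clustering_oracle,
    degree_oracle,
    mcc_oracle,
    random_graph,
)


def net_from_pairs(pairs, extra_nodes=(), freqs=None):
    freqs = freqs or {}
    edges = tuple(
        PatternEdge(
            min(x, y), max(x, y),
            ContingencyTable(freqs.get((x, y), 5), 5, 5, 85), 3.0, 1e-6,
        )
        for x, y in pairs
    )
    nodes = frozenset({v for p in pairs for v in p} | set(extra_nodes))
    return MultimorbidityNetwork(
        stratum_label="t", nodes=nodes, edges=edges, criteria=NetworkCriteria()
    )


def net_from_adj(adj):
    pairs = {tuple(sorted((u, v))) for u in adj for v in adj[u]}
    return net_from_pairs(sorted(pairs), extra_nodes=adj.keys())


class TestClosedForms:
    def test_triangle(self):
        m = compute_metrics(net_from_pairs([("A00", "B00"), ("B00", "C00"), ("A00", "C00")]))
        for v in m:
            assert m[v].degree == 2
            assert m[v].clustering == pytest.approx(1.0)
            assert m[v].mcc == 2  # one maximal 3-clique, (3-1)!
            assert m[v].pagerank == pytest.approx(1 / 3)

    def test_path_betweenness(self):
        m = compute_metrics(net_from_pairs([("A00", "B00"), ("B00", "C00")]))
        assert m["B00"].betweenness == pytest.approx(1.0)
        assert m["B00"].degree == 2
        assert m["A00"].betweenness == 0.0

    def test_two_node_edge_pagerank_split(self):
        m = compute_metrics(net_from_pairs([("A00", "B00")]))
        assert m["A00"].pagerank == pytest.approx(0.5)
        assert m["A00"].eigencentrality == pytest.approx(1.0)

    def test_isolated_node_conventions(self):
        m = compute_metrics(net_from_pairs([("A00", "B00")], extra_nodes={"Z51"}))
        z = m["Z51"]
        assert z.degree == 0 and z.mcc == 1 and z.closeness == 0.0
        assert z.eigencentrality == 0.0

    def test_empty_network(self):
        assert compute_metrics(net_from_pairs([])) == {}

    def test_pagerank_sums_to_one_and_eig_max_is_one(self):
        rng = np.random.default_rng(5)
        net = net_from_adj(random_graph(rng))
        m = compute_metrics(net)
        assert sum(v.pagerank for v in m.values()) == pytest.approx(1.0)
        if net.n_edges:
            assert max(v.eigencentrality for v in m.values()) == pytest.approx(1.0)


def test_metrics_match_bruteforce_on_random_graphs():
    """Spot check against the exhaustive oracles; the 200-graph sweep runs in
    the acceptance suite."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        adj = random_graph(rng, n_max=10)
        m = compute_metrics(net_from_adj(adj))
        deg, clu = degree_oracle(adj), clustering_oracle(adj)
        clo, bet, mcc = closeness_oracle(adj), betweenness_oracle(adj), mcc_oracle(adj)
        for v in adj:
            assert m[v].degree == deg[v]
            assert m[v].clustering == pytest.approx(clu[v], abs=1e-9)
            assert m[v].closeness == pytest.approx(clo[v], abs=1e-9)
            assert m[v].betweenness == pytest.approx(bet[v], abs=1e-9)
            assert m[v].mcc == mcc[v]


class TestHubs:
    def test_star_center_is_the_hub(self):
        leaves = [f"B{i:02d}" for i in range(5)]
        net = net_from_pairs([("A00", leaf) for leaf in leaves])
        hubs = top_hubs(net, k=1)
        assert tuple(hubs) == ("A00",)

    def test_ties_broken_by_mcc_then_code(self):
        # C6 cycle: all degree 2, all MCC equal -> code order decides
        cyc = ["A00", "B00", "C00", "D50", "E11", "F10"]
        net = net_from_pairs(list(zip(cyc, cyc[1:] + cyc[:1])))
        hubs = top_hubs(net, k=3)
        assert tuple(hubs) == ("A00", "B00", "C00")

    def test_fewer_than_k_positive_degree_nodes(self):
        net = net_from_pairs([("A00", "B00")], extra_nodes={"Z51"})
        assert len(tuple(top_hubs(net, k=10))) == 2

    def test_non_hub_degree_never_exceeds_minimum_hub_degree(self):
        rng = np.random.default_rng(2)
        net = net_from_adj(random_graph(rng))
        m = compute_metrics(net)
        hubs = set(top_hubs(net, k=3, metrics=m))
        min_hub = min(m[v].degree for v in hubs)
        assert all(m[v].degree <= min_hub for v in m if v not in hubs)

    def test_edgeless_network_rejected(self):
        with pytest.raises(ValueError):
            top_hubs(net_from_pairs([], extra_nodes={"A00"}))


class TestHubNetworks:
    def _star_plus_tail(self):
        pairs = [("A00", f"B{i:02d}") for i in range(4)] + [("B00", "B01"), ("C00", "D50")]
        return net_from_pairs(pairs)

    def test_hub_network_keeps_only_hub_hub_edges(self):
        net = self._star_plus_tail()
        hubs = top_hubs(net, k=2)  # A00 plus one of the B's
        hn = hub_network(net, hubs)
        assert set(hn.nodes) == set(hubs)
        assert all(e.x in set(hubs) and e.y in set(hubs) for e in hn.edges)

    def test_hub_associated_keeps_any_hub_endpoint(self):
        net = self._star_plus_tail()
        hubs = top_hubs(net, k=1)
        assoc = hub_associated_network(net, hubs)
        assert assoc.edge_keys() == {(min("A00", f"B{i:02d}"), max("A00", f"B{i:02d}")) for i in range(4)}
        # a (C00, D50) pattern has no hub endpoint, so neither node appears
        assert "C00" not in assoc.nodes

    def test_subgraph_chain(self):
        net = self._star_plus_tail()
        hubs = top_hubs(net, k=2)
        hn, assoc = hub_network(net, hubs), hub_associated_network(net, hubs)
        assert hn.edge_keys() <= assoc.edge_keys() <= net.edge_keys()


class TestCoverage:
    def test_published_frequency_shares(self):
        cov = CoverageStats.from_counts(1, 1, 1, 1, 128_025, 174_985)
        assert round(cov.freq_pct, 2) == 73.16
        cov = CoverageStats.from_counts(1, 1, 1, 1, 64_403, 99_086)
        assert round(cov.freq_pct, 2) == 65.00

    def test_identity_coverage_is_100(self):
        net = net_from_pairs([("A00", "B00"), ("B00", "C00")])
        cov = coverage(net, net)
        assert cov.node_pct == cov.edge_pct == cov.freq_pct == pytest.approx(100.0)

    def test_sub_with_foreign_edges_rejected(self):
        parent = net_from_pairs([("A00", "B00")])
        sub = net_from_pairs([("C00", "D50")])
        with pytest.raises(ValueError):
            coverage(sub, parent)

    def test_freq_share_invariant_to_relabeling(self):
        freqs = {("A00", "B00"): 30, ("B00", "C00"): 10}
        net = net_from_pairs(list(freqs), freqs=freqs)
        sub = net_from_pairs([("A00", "B00")], freqs=freqs)
        relabel = {("E11", "E12"): 30, ("E12", "E13"): 10}
        net2 = net_from_pairs(list(relabel), freqs=relabel)
        sub2 = net_from_pairs([("E11", "E12")], freqs=relabel)
        assert coverage(sub, net).freq_pct == coverage(sub2, net2).freq_pct == pytest.approx(75.0)
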