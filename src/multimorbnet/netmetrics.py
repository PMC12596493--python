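"""Node centralities, hub-disease identification and coverage statistics.

Seven metrics are computed per disease node on the unweighted undirected
network: degree, maximal clique centrality (MCC), closeness, clustering
coefficient, betweenness, PageRank and eigenvector centrality.  Hubs are
the top-10 nodes by degree; the induced hub network and the hub-associated
network (all patterns touching a hub) are compared against the parent
complete network via node/edge/pattern-frequency coverage percentages.

Disconnected-graph conventions: closeness is the within-component value
scaled by (component size − 1)/(n − 1); betweenness is the raw count of
shortest paths through a node, so only connected pairs contribute;
eigenvector centrality is computed on the largest connected component,
zero elsewhere, then normalized to max 1; PageRank uses damping 0.85 over
the whole graph.  MCC of an isolated node is 1 (its singleton maximal
clique, 0! = 1), though degree-0 nodes never qualify as hubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .netbuild import MultimorbidityNetwork
from .profiles import pct

__all__ = [
    "NodeMetrics",
    "HubSet",
    "CoverageStats",
    "to_graph",
    "compute_metrics",
    "top_hubs",
    "hub_network",
    "hub_associated_network",
    "coverage",
]


@dataclass(frozen=True, slots=True)
class NodeMetrics:
    degree: int
    mcc: int
    closeness: float
    clustering: float
    betweenness: float
    pagerank: float
    eigencentrality: float


@dataclass(frozen=True)
class HubSet:
    """Top-k nodes by degree, deterministically ordered."""

    hubs: tuple[str, ...]
    rank_basis: str = "degree"

    def __contains__(self, code: str) -> bool:
        return code in self.hubs

    def __iter__(self):
        return iter(self.hubs)


@dataclass(frozen=True, slots=True)
class CoverageStats:
    """Sub-network size relative to its parent complete network."""

    node_count: int
    node_pct: float
    edge_count: int
    edge_pct: float
    freq_total: int
    freq_pct: float

    @classmethod
    def from_counts(
        cls,
        sub_nodes: int,
        parent_nodes: int,
        sub_edges: int,
        parent_edges: int,
        sub_freq: int,
        parent_freq: int,
    ) -> "CoverageStats":
        return cls(
            node_count=sub_nodes,
            node_pct=pct(sub_nodes, parent_nodes),
            edge_count=sub_edges,
            edge_pct=pct(sub_edges, parent_edges),
            freq_total=sub_freq,
            freq_pct=pct(sub_freq, parent_freq),
        )


def to_graph(net: MultimorbidityNetwork) -> nx.Graph:
    """networkx view of a network (unweighted; statistics as edge attributes)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for e in net.edges:
        g.add_edge(e.x, e.y, odds_ratio=e.odds_ratio, p_value=e.p_value, frequency=e.frequency)
    return g


def _mcc(g: nx.Graph) -> dict[str, int]:
    scores = {v: 0 for v in g}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def compute_metrics(net: MultimorbidityNetwork) -> dict[str, NodeMetrics]:
    """The seven per-node metrics of a network; empty map for an empty network."""
    g = to_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        return {}
    degree = dict(g.degree())
    mcc = _mcc(g)
    closeness = nx.closeness_centrality(g)  # wf_improved: component-scaled
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    if g.number_of_edges() > 0:
        pagerank = nx.pagerank(g, alpha=0.85)
        giant = sorted(max(nx.connected_components(g), key=len))
        adj = nx.to_numpy_array(g.subgraph(giant), nodelist=giant)
        import numpy as np

        w, vecs = np.linalg.eigh(adj)
        principal = np.abs(vecs[:, int(np.argmax(w))])
        peak = principal.max()
        eig_cc = dict(zip(giant, principal / peak if peak > 0 else principal))
        eig = {v: eig_cc.get(v, 0.0) for v in g}
    else:
        pagerank = {v: 1.0 / n for v in g}
        eig = {v: 0.0 for v in g}
    return {
        v: NodeMetrics(
            degree=degree[v],
            mcc=mcc[v],
            closeness=closeness[v],
            clustering=clustering[v],
            betweenness=betweenness[v],
            pagerank=pagerank[v],
            eigencentrality=eig[v],
        )
        for v in g
    }


def top_hubs(
    net: MultimorbidityNetwork,
    k: int = 10,
    metrics: dict[str, NodeMetrics] | None = None,
) -> HubSet:
    """The k hub diseases: highest degree, ties by MCC then by code.

    Only nodes with at least one pattern qualify; if fewer than k such
    nodes exist they are all returned.
    """
    if net.n_edges == 0:
        raise ValueError("hub identification needs a network with at least one edge")
    metrics = metrics if metrics is not None else compute_metrics(net)
    eligible = [v for v, m in metrics.items() if m.degree > 0]
    eligible.sort(key=lambda v: (-metrics[v].degree, -metrics[v].mcc, v))
    return HubSet(hubs=tuple(eligible[:k]))


def hub_network(net: MultimorbidityNetwork, hubs: HubSet) -> MultimorbidityNetwork:
    """Subgraph induced on the hubs: patterns with both endpoints a hub."""
    hub_set = set(hubs)
    kept = tuple(e for e in net.edges if e.x in hub_set and e.y in hub_set)
    return MultimorbidityNetwork(
        stratum_label=net.stratum_label,
        nodes=frozenset(hub_set),
        edges=kept,
        criteria=net.criteria,
        operation="hub",
        parents=(net.stratum_label,),
    )


def hub_associated_network(net: MultimorbidityNetwork, hubs: HubSet) -> MultimorbidityNetwork:
    """Patterns with at least one hub endpoint, plus their incident nodes."""
    hub_set = set(hubs)
    kept = tuple(e for e in net.edges if e.x in hub_set or e.y in hub_set)
    nodes = frozenset(v for e in kept for v in (e.x, e.y))
    return MultimorbidityNetwork(
        stratum_label=net.stratum_label,
        nodes=nodes,
        edges=kept,
        criteria=net.criteria,
        operation="hub_associated",
        parents=(net.stratum_label,),
    )


def coverage(sub: MultimorbidityNetwork, parent: MultimorbidityNetwork) -> CoverageStats:
    """Node/edge/pattern-frequency share of ``sub`` within ``parent``."""
    if parent.n_nodes == 0 or parent.n_edges == 0:
        raise ValueError("coverage against an empty parent network is undefined")
    if not sub.edge_keys() <= parent.edge_keys():
        raise ValueError("sub-network has edges outside its parent")
    return CoverageStats.from_counts(
        sub.n_nodes,
        parent.n_nodes,
        sub.n_edges,
        parent.n_edges,
        sub.total_pattern_frequency,
        parent.total_pattern_frequency,
    )
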