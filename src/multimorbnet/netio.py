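"""Network writers/readers: audit edge-list TSV and GraphML.

The edge TSV lists every scored pair (accepted or not) with its 2×2
counts, odds ratio, p-value, prevalence and — for rejected pairs — the
first criterion it failed.  The accepted network round-trips losslessly
through the TSV.  GraphML output carries node attributes (chapter,
metrics, hub flag) and edge attributes (odds ratio, p, frequency), and is
written through networkx.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .icd10 import chapter_of
from .netbuild import (
    ContingencyTable,
    MultimorbidityNetwork,
    NetworkCriteria,
    PatternEdge,
)
from .netmetrics import HubSet, NodeMetrics, to_graph

__all__ = [
    "edges_to_frame",
    "write_edge_tsv",
    "read_edge_tsv",
    "write_graphml",
    "metrics_to_frame",
    "criteria_provenance",
]

EDGE_COLUMNS = [
    "x", "y", "a", "b", "c", "d",
    "odds_ratio", "p_value", "prevalence", "accepted", "rejection_reason",
]


def _rejection_reason(e: PatternEdge, crit: NetworkCriteria) -> str:
    if not math.isfinite(e.odds_ratio):
        return "non_finite_or"
    if e.odds_ratio <= crit.or_floor:
        return "or_floor"
    if not (math.isfinite(e.p_value) and e.p_value < crit.p_threshold):
        return "p_threshold"
    if e.prevalence <= crit.prevalence_floor:
        return "prevalence_floor"
    return ""


def edges_to_frame(
    edges: Iterable[PatternEdge],
    criteria: NetworkCriteria,
    accepted_keys: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    rows = []
    for e in edges:
        reason = _rejection_reason(e, criteria)
        accepted = reason == "" if accepted_keys is None else e.key in accepted_keys
        rows.append(
            {
                "x": e.x, "y": e.y,
                "a": e.table.a, "b": e.table.b, "c": e.table.c, "d": e.table.d,
                "odds_ratio": e.odds_ratio, "p_value": e.p_value,
                "prevalence": e.prevalence,
                "accepted": accepted,
                "rejection_reason": reason if not accepted else "",
            }
        )
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return df.sort_values(["x", "y"]).reset_index(drop=True)


def write_edge_tsv(
    path: str | Path,
    net: MultimorbidityNetwork,
    candidates: Sequence[PatternEdge] | None = None,
) -> None:
    """Write the network's (or full candidate list's) edge table as TSV."""
    edges = candidates if candidates is not None else net.edges
    df = edges_to_frame(edges, net.criteria, accepted_keys=net.edge_keys())
    df.to_csv(path, sep="\t", index=False)


def read_edge_tsv(path: str | Path) -> list[PatternEdge]:
    """Accepted edges back from an edge TSV."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out: list[PatternEdge] = []
    for row in df.itertuples(index=False):
        if not row.accepted:
            continue
        out.append(
            PatternEdge(
                x=row.x,
                y=row.y,
                table=ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d)),
                odds_ratio=float(row.odds_ratio),
                p_value=float(row.p_value),
            )
        )
    return out


def metrics_to_frame(
    metrics: dict[str, NodeMetrics], hubs: HubSet | None = None
) -> pd.DataFrame:
    hub_set = set(hubs) if hubs is not None else set()
    rows = [
        {
            "node": v,
            "chapter": chapter_of(v),
            "degree": m.degree,
            "mcc": m.mcc,
            "closeness": m.closeness,
            "clustering": m.clustering,
            "betweenness": m.betweenness,
            "pagerank": m.pagerank,
            "eigencentrality": m.eigencentrality,
            "is_hub": v in hub_set,
        }
        for v, m in sorted(metrics.items())
    ]
    return pd.DataFrame(rows)


def write_graphml(
    path: str | Path,
    net: MultimorbidityNetwork,
    metrics: dict[str, NodeMetrics] | None = None,
    hubs: HubSet | None = None,
) -> None:
    g = to_graph(net)
    hub_set = set(hubs) if hubs is not None else set()
    for v in g.nodes:
        g.nodes[v]["chapter"] = chapter_of(v)
        g.nodes[v]["is_hub"] = v in hub_set
        if metrics and v in metrics:
            m = metrics[v]
            g.nodes[v].update(
                degree=m.degree, mcc=m.mcc, closeness=m.closeness,
                clustering=m.clustering, betweenness=m.betweenness,
                pagerank=m.pagerank, eigencentrality=m.eigencentrality,
            )
    nx.write_graphml(g, path)


def criteria_provenance(net: MultimorbidityNetwork) -> str:
    """JSON provenance block: criteria, realized Bonferroni N, operation, parents."""
    c = net.criteria
    return json.dumps(
        {
            "stratum": net.stratum_label,
            "operation": net.operation,
            "parents": list(net.parents),
            "or_floor": c.or_floor,
            "alpha": c.alpha,
            "prevalence_floor": c.prevalence_floor,
            "n_bonferroni": c.n_bonferroni,
            "p_threshold": None if not c.n_bonferroni else c.p_threshold,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "total_pattern_frequency": net.total_pattern_frequency,
        },
        indent=2,
    )
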