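"""Second- and third-level networks: sex-specific, sex-overlapped, sex–age.

Patterns are matched purely by their unordered disease-pair identity; the
statistics attached to an edge (odds ratio, frequency) play no role in the
set algebra.  Derived networks keep only the nodes incident to surviving
edges, so a "635 patterns across 211 diseases" style count reads directly
off the result.

The decomposition identity
``edges(complete) = edges(specific) ⊎ edges(overlapped)`` (a disjoint
union) holds by construction from either side.
"""

from __future__ import annotations

from typing import Literal, Sequence

from .ingest import AdmissionRecord, stratify
from .netbuild import MultimorbidityNetwork, NetworkCriteria, PatternEdge, build_network

__all__ = ["overlapped", "specific", "decompose_by_age", "overlap_count_from_totals"]


def _incident_nodes(edges: Sequence[PatternEdge]) -> frozenset[str]:
    return frozenset(v for e in edges for v in (e.x, e.y))


def overlapped(
    left: MultimorbidityNetwork, right: MultimorbidityNetwork
) -> MultimorbidityNetwork:
    """Patterns present in both networks (edge-set intersection).

    Edge statistics from both sides are retained side-by-side in
    ``side_stats``; the edge objects themselves carry the left network's
    statistics.  Symmetric in its arguments up to which side's statistics
    the edges carry.
    """
    right_by_key = {e.key: e for e in right.edges}
    kept = tuple(e for e in left.edges if e.key in right_by_key)
    side = {
        e.key: {
            left.stratum_label: {"odds_ratio": e.odds_ratio, "frequency": e.frequency},
            right.stratum_label: {
                "odds_ratio": right_by_key[e.key].odds_ratio,
                "frequency": right_by_key[e.key].frequency,
            },
        }
        for e in kept
    }
    return MultimorbidityNetwork(
        stratum_label=f"{left.stratum_label}&{right.stratum_label}",
        nodes=_incident_nodes(kept),
        edges=kept,
        criteria=left.criteria,
        operation="overlapped",
        parents=(left.stratum_label, right.stratum_label),
        side_stats=side,
    )


def specific(
    left: MultimorbidityNetwork, right: MultimorbidityNetwork
) -> MultimorbidityNetwork:
    """Patterns of ``left`` absent from ``right`` (edge-set difference)."""
    right_keys = {e.key for e in right.edges}
    kept = tuple(e for e in left.edges if e.key not in right_keys)
    return MultimorbidityNetwork(
        stratum_label=f"{left.stratum_label}-{right.stratum_label}",
        nodes=_incident_nodes(kept),
        edges=kept,
        criteria=left.criteria,
        operation="specific",
        parents=(left.stratum_label, right.stratum_label),
    )


def decompose_by_age(
    records: Sequence[AdmissionRecord],
    sex: Literal["male", "female"],
    criteria: NetworkCriteria | None = None,
) -> dict[str, MultimorbidityNetwork]:
    """One complete network per 5-year age band for a single sex.

    Each band is an independent stratum with its own Bonferroni N, so band
    networks need not nest: a pattern accepted at 40–44 can fail at 45–49.
    """
    sexed = [r for r in records if r.sex == sex]
    strata = stratify(sexed, scheme="sex_age")
    return {label: build_network(s, criteria) for label, s in strata.items()}


def overlap_count_from_totals(
    complete_left: int, specific_left: int, complete_right: int, specific_right: int
) -> int:
    """Overlap size from published complete/specific edge counts.

    Computed from both sides (complete − specific); the two must agree,
    otherwise the published counts are inconsistent and a ``ValueError``
    carries both values.
    """
    from_left = complete_left - specific_left
    from_right = complete_right - specific_right
    if from_left != from_right:
        raise ValueError(
            f"inconsistent overlap: {from_left} from one side, {from_right} from the other"
        )
    return from_left
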