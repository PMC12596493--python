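"""Pairwise disease association and multimorbidity-network construction.

Every unordered pair of diseases observed in a stratum is scored with a 2×2
contingency table over the stratum's inpatients.  The association is the
odds ratio of a logistic regression of one disease on the other; with a
single binary predictor the maximum-likelihood odds ratio is exactly the
cross-product ratio a·d/(b·c) and the Wald test on the log-odds coefficient
has standard error sqrt(1/a + 1/b + 1/c + 1/d), so both are computed in
closed form.

An edge enters the network when the pattern satisfies all three criteria:

1. odds ratio > 1,
2. p-value < alpha / N, Bonferroni-corrected with N the number of candidate
   patterns with odds ratio > 1 in the stratum,
3. pattern prevalence (co-occurrence count / stratum size) > 1/10 000.

Pairs with a zero off-diagonal cell have a non-finite odds ratio and are
never acceptable; no continuity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import norm

from .icd10 import chapter_of
from .ingest import CohortStratum

__all__ = [
    "ContingencyTable",
    "PatternEdge",
    "NetworkCriteria",
    "MultimorbidityNetwork",
    "pair_contingency",
    "estimate_association",
    "bonferroni_threshold",
    "build_network",
    "disease_matrix",
]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2×2 co-occurrence table of a disease pair over a stratum.

    ``a``: inpatients with both diseases; ``b``: disease X only;
    ``c``: disease Y only; ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class PatternEdge:
    """A multimorbidity pattern: an unordered disease pair with its statistics.

    Canonical orientation ``x < y`` by code.  ``frequency`` is the
    co-occurrence count (cell a); ``prevalence`` is frequency / stratum size.
    """

    x: str
    y: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float

    @property
    def frequency(self) -> int:
        return self.table.a

    @property
    def prevalence(self) -> float:
        return self.table.a / self.table.n

    @property
    def key(self) -> tuple[str, str]:
        return (self.x, self.y)


@dataclass(frozen=True, slots=True)
class NetworkCriteria:
    """The three edge-selection thresholds with the realized Bonferroni N."""

    or_floor: float = 1.0
    alpha: float = 0.05
    prevalence_floor: float = 1e-4
    n_bonferroni: int | None = None  # filled in during the build

    @property
    def p_threshold(self) -> float:
        if not self.n_bonferroni:
            return float("nan")
        return self.alpha / self.n_bonferroni


@dataclass(frozen=True)
class MultimorbidityNetwork:
    """Diseases (nodes) plus accepted patterns (edges) of one stratum.

    The node set covers every disease observed in the stratum, isolated
    nodes included, for a complete network; derived networks (specific,
    overlapped, hub subgraphs) carry only incident nodes.
    """

    stratum_label: str
    nodes: frozenset[str]
    edges: tuple[PatternEdge, ...]
    criteria: NetworkCriteria
    operation: str = "complete"
    parents: tuple[str, ...] = ()
    #: side-by-side per-parent statistics for derived (overlap) networks
    side_stats: Mapping[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_pattern_frequency(self) -> int:
        return sum(e.frequency for e in self.edges)

    def edge_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.edges}

    def degree(self) -> dict[str, int]:
        deg = {v: 0 for v in self.nodes}
        for e in self.edges:
            deg[e.x] += 1
            deg[e.y] += 1
        return deg

    def node_chapters(self) -> dict[str, int]:
        return {v: chapter_of(v) for v in self.nodes}


def disease_matrix(stratum: CohortStratum) -> tuple[np.ndarray, list[str]]:
    """Record × disease boolean indicator matrix with the sorted disease list."""
    codes = sorted(stratum.observed_codes())
    index = {c: j for j, c in enumerate(codes)}
    mat = np.zeros((stratum.n_records, len(codes)), dtype=bool)
    for i, rec in enumerate(stratum.records):
        for c in rec.codes:
            mat[i, index[c]] = True
    return mat, codes


def pair_contingency(stratum: CohortStratum, x: str, y: str) -> ContingencyTable:
    """2×2 table for one disease pair, counted directly over the records."""
    if x == y:
        raise ValueError("a pattern needs two distinct diseases")
    observed = stratum.observed_codes()
    for code in (x, y):
        if code not in observed:
            raise ValueError(f"disease {code!r} not observed in stratum {stratum.label}")
    a = b = c = 0
    for rec in stratum.records:
        has_x, has_y = x in rec.codes, y in rec.codes
        a += has_x and has_y
        b += has_x and not has_y
        c += has_y and not has_x
    return ContingencyTable(a=a, b=b, c=c, d=stratum.n_records - a - b - c)


def estimate_association(table: ContingencyTable) -> tuple[float, float]:
    """Odds ratio and two-sided Wald p-value for a 2×2 table.

    Equals the single-binary-predictor logistic regression MLE and Wald
    test.  Degenerate tables yield a non-finite odds ratio (``inf`` for a
    zero off-diagonal cell, ``nan`` when the ratio is 0/0) with p-value
    ``nan``; an absent disease (zero margin) is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("degenerate margin: a disease is absent or universal")
    if b == 0 or c == 0:
        oddsr = float("nan") if (a == 0 or d == 0) else float("inf")
        return oddsr, float("nan")
    oddsr = (a * d) / (b * c)
    if a == 0 or d == 0:
        return oddsr, float("nan")  # OR = 0: log-odds at -inf boundary
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(oddsr) / se
    p = 2.0 * norm.sf(abs(z))
    return oddsr, p


def bonferroni_threshold(candidates: Iterable[PatternEdge], alpha: float = 0.05) -> float:
    """alpha / N with N the number of candidate patterns with OR > 1.

    Returns ``nan`` (no edge can be accepted) when no candidate exceeds 1.
    """
    n = sum(1 for e in candidates if math.isfinite(e.odds_ratio) and e.odds_ratio > 1)
    if n == 0:
        return float("nan")
    return alpha / n


def _pairwise_stats(mat: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized a/b/c/d, OR and Wald p over all column pairs of ``mat``."""
    n = mat.shape[0]
    x = mat.astype(np.float64)  # BLAS path; counts are exact in float64
    co = x.T @ x  # co-occurrence counts
    m = np.diag(co)
    iu, ju = np.triu_indices(mat.shape[1], k=1)
    a = co[iu, ju].astype(float)
    b = m[iu] - a
    c = m[ju] - a
    d = n - m[iu] - m[ju] + a
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsr = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.log(oddsr) / se
    p = np.where(np.isfinite(z), 2.0 * norm.sf(np.abs(z)), np.nan)
    oddsr = np.where((b == 0) | (c == 0), np.where((a == 0) | (d == 0), np.nan, np.inf), oddsr)
    p = np.where((a == 0) | (b == 0) | (c == 0) | (d == 0), np.nan, p)
    return iu, ju, a, b, c, d, oddsr, p


def build_network(
    stratum: CohortStratum,
    criteria: NetworkCriteria | None = None,
    return_candidates: bool = False,
):
    """Construct the complete multimorbidity network of one stratum.

    All unordered pairs of observed diseases are scored; candidates are the
    pairs with a finite odds ratio, N counts candidates with OR above the
    floor, and edges are the candidates passing all three criteria.  The
    result is deterministic and invariant to record order.

    With ``return_candidates=True`` also returns the full scored pair list
    (accepted or not) for audit output.
    """
    criteria = criteria or NetworkCriteria()
    mat, codes = disease_matrix(stratum)
    nodes = frozenset(codes)
    if len(codes) < 2 or stratum.n_records == 0:
        net = MultimorbidityNetwork(
            stratum_label=stratum.label, nodes=nodes, edges=(),
            criteria=replace(criteria, n_bonferroni=0),
        )
        return (net, []) if return_candidates else net

    iu, ju, a, b, c, d, oddsr, p = _pairwise_stats(mat)
    finite = np.isfinite(oddsr)
    n_bonf = int(np.sum(finite & (oddsr > criteria.or_floor)))
    threshold = criteria.alpha / n_bonf if n_bonf else float("nan")
    prevalence = a / stratum.n_records
    accepted = (
        finite
        & (oddsr > criteria.or_floor)
        & np.isfinite(p)
        & (p < threshold)
        & (prevalence > criteria.prevalence_floor)
    )

    def make_edge(k: int) -> PatternEdge:
        return PatternEdge(
            x=codes[iu[k]],
            y=codes[ju[k]],
            table=ContingencyTable(int(a[k]), int(b[k]), int(c[k]), int(d[k])),
            odds_ratio=float(oddsr[k]),
            p_value=float(p[k]),
        )

    edges = tuple(make_edge(k) for k in np.nonzero(accepted)[0])
    net = MultimorbidityNetwork(
        stratum_label=stratum.label,
        nodes=nodes,
        edges=edges,
        criteria=replace(criteria, n_bonferroni=n_bonf),
    )
    if not return_candidates:
        return net
    candidates = [make_edge(k) for k in range(len(a))]
    return net, candidates
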