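"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is implemented from first principles (exhaustive
enumeration, BFS counting, an external statsmodels fit) so it exercises a
different code path than the library it checks.
"""

import itertools
import math
from collections import deque

import numpy as np


def logistic_fit_oracle(a, b, c, d):
    """Odds ratio and Wald p from an explicit statsmodels logistic fit."""
    import statsmodels.api as sm

    # outcome: disease Y; predictor: disease X; four weighted covariate rows
    y = np.array([1.0, 0.0, 1.0, 0.0])
    x = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    w = np.array([a, b, c, d], dtype=float)
    res = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit()
    return math.exp(res.params[1]), res.pvalues[1]


def adjacency(g):
    nodes = sorted(g)
    return nodes, {v: set(g[v]) for v in nodes}


def degree_oracle(g):
    return {v: len(set(g[v])) for v in g}


def clustering_oracle(g):
    out = {}
    for v in g:
        nbrs = list(set(g[v]))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k) if nbrs[j] in set(g[nbrs[i]])
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def _bfs(adj, source):
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def closeness_oracle(g):
    """Within-component closeness scaled by (component size − 1)/(n − 1)."""
    nodes, adj = adjacency(g)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist, _ = _bfs(adj, v)
        total = sum(dist.values())
        k = len(dist)
        if total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((k - 1) / total) * ((k - 1) / (n - 1))
    return out


def betweenness_oracle(g):
    """Raw betweenness: pair-by-pair shortest-path fractions (connected pairs only)."""
    nodes, adj = adjacency(g)
    dist = {}
    sigma = {}
    for v in nodes:
        dist[v], sigma[v] = _bfs(adj, v)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        n_st = sigma[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or t not in dist[v]:
                continue
            if dist[s][v] + dist[v][t] == d_st:
                out[v] += sigma[s][v] * sigma[v][t] / n_st
    return out


def mcc_oracle(g):
    """Maximal-clique centrality by exhaustive subset enumeration (n <= ~15)."""
    nodes, adj = adjacency(g)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(b in adj[a] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    out = {v: 0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def random_graph(rng, n_max=12):
    """A random simple graph as an adjacency dict over string node names."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.15, 0.45))
    names = [f"v{i}" for i in range(n)]
    adj = {v: set() for v in names}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    return adj
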