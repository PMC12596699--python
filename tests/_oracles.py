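"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — explicit loops over pairs,
exhaustive subset enumeration, BFS path counting — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.special import zeta


def clustering_unweighted(g, u):
    nbrs = list(g.neighbors(u))
    d = len(nbrs)
    if d < 2:
        return 0.0
    tri = 0
    for v, w in itertools.combinations(nbrs, 2):
        if g.has_edge(v, w):
            tri += 1
    return 2.0 * tri / (d * (d - 1))


def clustering_weighted(g, u):
    """Geometric-mean triangle intensity, weights normalized by the max."""
    wmax = max(d["weight"] for _, _, d in g.edges(data=True))
    nbrs = list(g.neighbors(u))
    d = len(nbrs)
    if d < 2:
        return 0.0
    total = 0.0
    for v, w in itertools.combinations(nbrs, 2):
        if g.has_edge(v, w):
            wuv = g[u][v]["weight"] / wmax
            wuw = g[u][w]["weight"] / wmax
            wvw = g[v][w]["weight"] / wmax
            total += (wuv * wuw * wvw) ** (1.0 / 3.0)
    return 2.0 * total / (d * (d - 1))


def rich_club_phi(g, k):
    """Density of the subgraph induced by nodes of degree > k (NaN if <2)."""
    rich = [u for u in g if g.degree(u) > k]
    if len(rich) < 2:
        return float("nan")
    edges = 0
    for v, w in itertools.combinations(rich, 2):
        if g.has_edge(v, w):
            edges += 1
    return 2.0 * edges / (len(rich) * (len(rich) - 1))


def density(g):
    n = g.number_of_nodes()
    m = 0
    for _ in g.edges():
        m += 1
    return 2.0 * m / (n * (n - 1))


def jaccard(ga, gb, u):
    na, nb = set(ga.neighbors(u)), set(gb.neighbors(u))
    union = na | nb
    return len(na & nb) / len(union) if union else 0.0


def _bfs_dist(g, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def closeness(g, u):
    """(n_c - 1)/sum(d) scaled by (n_c - 1)/(n - 1) for disconnected graphs."""
    dist = _bfs_dist(g, u)
    reach = len(dist) - 1
    if reach == 0:
        return 0.0
    total = sum(dist.values())
    n = g.number_of_nodes()
    return (reach / total) * (reach / (n - 1))


def _all_shortest_paths(g, s, t):
    dist = _bfs_dist(g, s)
    if t not in dist:
        return []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in g.neighbors(v):
            if dist.get(u, -2) == dist[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths


def betweenness(g):
    """Normalized betweenness from explicit shortest-path enumeration."""
    nodes = list(g)
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for u in nodes:
            if u in (s, t):
                continue
            through = sum(1 for p in paths if u in p[1:-1])
            bc[u] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {u: v / norm for u, v in bc.items()}


def maximal_cliques(g):
    """Exhaustive subset enumeration; only for small graphs (n <= 12)."""
    nodes = list(g)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return sorted((sorted(map(str, c)) for c in maximal), key=lambda c: (-len(c), c))


def ks_distance(tail, alpha, kmin):
    """CDF-difference scan, with the model CDF built by pmf accumulation."""
    tail = sorted(int(k) for k in tail)
    z = zeta(alpha, kmin)
    worst = 0.0
    cum_model = 0.0
    for k in range(kmin, tail[-1] + 1):
        cum_model += k**-alpha / z
        ecdf = sum(1 for x in tail if x <= k) / len(tail)
        worst = max(worst, abs(ecdf - cum_model))
    return worst
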