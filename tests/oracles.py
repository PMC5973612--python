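"""Brute-force reference implementations, independent of the package internals.

Everything here works on plain node/edge collections with pure-Python
loops (Floyd–Warshall, explicit triangle counting), so it can serve as an
oracle for the igraph-backed metrics.
"""

from __future__ import annotations

import itertools
import math


def floyd_warshall_cpl(nodes, edges):
    """All-pairs shortest paths; returns (mean over reachable unordered pairs,
    number of unreachable unordered pairs)."""
    nodes = list(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    INF = math.inf
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in edges:
        i, j = idx[a], idx[b]
        d[i][j] = d[j][i] = 1
    for k in range(n):
        dk = d[k]
        for i in range(n):
            dik = d[i][k]
            if dik == INF:
                continue
            di = d[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    total, reachable, unreachable = 0.0, 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i][j] == INF:
                unreachable += 1
            else:
                total += d[i][j]
                reachable += 1
    mean = total / reachable if reachable else math.nan
    return mean, unreachable


def triangle_cc(nodes, edges):
    """Network-average local clustering via explicit neighbour-pair checks;
    degree < 2 nodes contribute 0."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    ccs = []
    for v in nodes:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        links = sum(
            1 for x, y in itertools.combinations(nbrs, 2) if y in adj[x]
        )
        ccs.append(2.0 * links / (k * (k - 1)))
    return sum(ccs) / len(ccs)


def random_simple_graph(rng, n_max=10):
    """A random simple undirected graph on <= n_max nodes (edge prob. ~U(0,1))."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    nodes = list(range(n))
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return nodes, edges
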