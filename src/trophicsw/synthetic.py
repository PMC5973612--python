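"""Synthetic network generators with known topology class.

These provide positive and negative controls for the small-world test and
the degree-distribution fitter: Watts–Strogatz rewired lattices (small-world
when the rewiring probability is small but positive), pure ring lattices
(clustered but long paths — not small-world), preferential-attachment
graphs (heavy-tailed degrees) and configuration-model graphs with uniformly
distributed degrees.

All generators return simple undirected graphs.  Food webs are directed, so
:func:`orient` turns any projection into a directed fixture by orienting
each edge uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .net_io import TrophicNetwork, UndirectedProjection

__all__ = [
    "GeneratorSpec",
    "generate",
    "watts_strogatz",
    "ring_lattice",
    "preferential_attachment",
    "uniform_degree",
    "orient",
]


def _from_networkx(g: nx.Graph) -> UndirectedProjection:
    nodes = tuple(sorted(g.nodes()))
    return UndirectedProjection.from_edges(nodes, g.edges())


def _check_ws_params(n: int, k: int) -> None:
    if not (n > k >= 2):
        raise ValueError(f"need n > k >= 2, got n={n}, k={k}")
    if k % 2:
        raise ValueError(f"neighbour count k must be even, got {k}")


def watts_strogatz(n: int, k: int, p: float, seed: int) -> UndirectedProjection:
    """Ring lattice over n nodes, k neighbours each, each edge rewired with prob. p.

    Keeps exactly n*k/2 edges.  p = 0 is the pure lattice; small p > 0 gives
    the canonical small-world graph; p = 1 approaches an Erdős–Rényi graph.
    """
    _check_ws_params(n, k)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    return _from_networkx(nx.watts_strogatz_graph(n, k, p, seed=seed))


def ring_lattice(n: int, k: int) -> UndirectedProjection:
    """Deterministic circulant graph: each node linked to its k nearest ring neighbours."""
    _check_ws_params(n, k)
    return _from_networkx(nx.circulant_graph(n, range(1, k // 2 + 1)))


def preferential_attachment(n: int, m: int, seed: int) -> UndirectedProjection:
    """Growth with preferential attachment; each new node brings m edges.

    Yields m(n - m) edges and a heavy-tailed degree distribution.
    """
    if not n > m >= 1:
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    return _from_networkx(nx.barabasi_albert_graph(n, m, seed=seed))


def uniform_degree(
    n: int,
    d_min: int,
    d_max: int,
    seed: int,
    max_tries: int = 100,
) -> UndirectedProjection:
    """Configuration-model graph with degrees drawn uniformly on [d_min, d_max].

    The stub-matching realization is simplified (loops and multi-edges
    removed) and then repaired: nodes left short of their target degree are
    re-linked to other deficient, non-adjacent nodes, for at most
    ``max_tries`` repair sweeps.  Raises if the requested sequence is
    infeasible or the repair cannot restore every degree.
    """
    if not (0 <= d_min <= d_max < n):
        raise ValueError(f"need 0 <= d_min <= d_max < n, got ({d_min}, {d_max}, {n})")
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        target = rng.integers(d_min, d_max + 1, size=n)
        if target.sum() % 2:
            # flip one node's degree by 1 within range to make the sum even
            i = int(rng.integers(n))
            target[i] += 1 if target[i] < d_max else -1
            if target.sum() % 2:
                continue
        g = nx.configuration_model(target.tolist(), seed=int(rng.integers(2**31)))
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        if _repair_degrees(g, target, rng, max_tries):
            return _from_networkx(g)
    raise RuntimeError(
        f"could not realize a uniform degree sequence on [{d_min}, {d_max}] "
        f"after {max_tries} attempts"
    )


def _repair_degrees(g: nx.Graph, target, rng, max_sweeps: int) -> bool:
    for _ in range(max_sweeps):
        deficit = [v for v in g.nodes() if g.degree(v) < target[v]]
        if not deficit:
            return True
        rng.shuffle(deficit)
        added = False
        for i, u in enumerate(deficit):
            if g.degree(u) >= target[u]:
                continue
            for v in deficit[i + 1:]:
                if g.degree(v) < target[v] and v != u and not g.has_edge(u, v):
                    g.add_edge(u, v)
                    added = True
                    break
        if not added:
            return False
    return not [v for v in g.nodes() if g.degree(v) < target[v]]


def orient(proj: UndirectedProjection, seed: int, name: str = "synthetic") -> TrophicNetwork:
    """Orient each undirected edge uniformly at random into a directed fixture web."""
    rng = np.random.default_rng(seed)
    flips = rng.random(proj.E) < 0.5
    links = tuple(
        (b, a) if flip else (a, b) for (a, b), flip in zip(proj.edges, flips)
    )
    return TrophicNetwork(name=name, nodes=proj.nodes, links=links)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # er | watts_strogatz | ring_lattice | preferential_attachment | uniform_degree
    params: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: GeneratorSpec) -> UndirectedProjection:
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    kind, p, seed = spec.kind, spec.params, spec.seed
    if kind == "er":
        from .null_ensemble import generate_er

        return generate_er(p["n"], p["m"], seed)
    if kind == "watts_strogatz":
        return watts_strogatz(p["n"], p["k"], p["p"], seed)
    if kind == "ring_lattice":
        return ring_lattice(p["n"], p["k"])
    if kind == "preferential_attachment":
        return preferential_attachment(p["n"], p["m"], seed)
    if kind == "uniform_degree":
        return uniform_degree(p["n"], p["d_min"], p["d_max"], seed)
    raise ValueError(f"unknown generator kind {kind!r}")
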