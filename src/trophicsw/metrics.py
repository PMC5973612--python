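"""Structural food-web metrics: connectance, path length, clustering, degrees.

Connectance is defined on the *directed* web (C = L / S^2); the path-length
and clustering metrics are defined on the undirected simple projection.
Shortest-path lengths are counted in edges, averaged over the unordered node
pairs that are mutually reachable; unreachable pairs are excluded from the
average and reported as a separate count.  Clustering follows the standard
zero convention: a node of degree < 2 contributes CC_i = 0 and is included
in the network average.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np

from .net_io import TrophicNetwork, UndirectedProjection, to_projection

__all__ = [
    "TopologySummary",
    "connectance",
    "characteristic_path_length",
    "clustering_coefficient",
    "degree_sequence",
    "summarize",
]


@dataclass(frozen=True)
class TopologySummary:
    """Per-web structural properties."""

    name: str
    S: int
    L: int
    C: float
    CPL: float
    CC: float
    degrees: tuple
    n_unreachable_pairs: int

    @property
    def E(self) -> int:
        """Edge count of the undirected projection (handshake identity)."""
        return int(sum(self.degrees)) // 2


def connectance(S: int, L: int) -> float:
    """Realized fraction of the S^2 possible directed links, C = L / S^2."""
    if S < 1:
        raise ValueError(f"connectance undefined for S={S}")
    if L < 0:
        raise ValueError("negative link count")
    return L / (S * S)


def _as_igraph(g) -> ig.Graph:
    if isinstance(g, ig.Graph):
        return g
    if isinstance(g, UndirectedProjection):
        return g.to_igraph()
    raise TypeError(f"expected UndirectedProjection or igraph.Graph, got {type(g).__name__}")


def _unreachable_pairs(graph: ig.Graph) -> int:
    n = graph.vcount()
    sizes = [len(c) for c in graph.connected_components()]
    reachable = sum(s * (s - 1) // 2 for s in sizes)
    return n * (n - 1) // 2 - reachable


def characteristic_path_length(g) -> tuple[float, int]:
    """Mean shortest-path length (in edges) over mutually reachable pairs.

    Returns ``(CPL, n_unreachable_pairs)``.  Raises if the graph has no
    connected pair at all, where the average is undefined.
    """
    graph = _as_igraph(g)
    n = graph.vcount()
    if n < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    n_unreachable = _unreachable_pairs(graph)
    if n_unreachable == n * (n - 1) // 2:
        raise ValueError("no connected node pair: characteristic path length undefined")
    cpl = graph.average_path_length(directed=False, unconn=True)
    return float(cpl), n_unreachable


def clustering_coefficient(g) -> float:
    """Network-average local clustering CC = mean_i 2 E_i / (K_i (K_i - 1)).

    E_i is the number of edges among the K_i neighbours of node i; nodes with
    K_i < 2 contribute 0.
    """
    graph = _as_igraph(g)
    if graph.vcount() < 1:
        raise ValueError("clustering coefficient needs at least 1 node")
    local = graph.transitivity_local_undirected(mode="zero")
    return float(np.mean(local))


def degree_sequence(g) -> tuple:
    """One degree per node, in node order, on the undirected projection."""
    graph = _as_igraph(g)
    return tuple(graph.degree())


def summarize(net: TrophicNetwork) -> TopologySummary:
    """Compute all structural properties of one web.

    C uses the directed link count; CPL, CC and degrees use the undirected
    simple projection.
    """
    proj = to_projection(net)
    graph = proj.to_igraph()
    cpl, n_unreachable = characteristic_path_length(graph)
    return TopologySummary(
        name=net.name,
        S=net.S,
        L=net.L,
        C=connectance(net.S, net.L),
        CPL=cpl,
        CC=clustering_coefficient(graph),
        degrees=degree_sequence(graph),
        n_unreachable_pairs=n_unreachable,
    )
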