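"""Reading and writing food-web networks.

Food webs arrive as directed trophic-link edge lists (resource -> consumer)
or as binary adjacency matrices.  All structural metrics in this package are
defined on the *undirected simple projection* of the directed web: self-loops
(cannibalism) are dropped and reciprocal link pairs are merged into a single
edge.  Self-loops are nonetheless retained in the directed link count L used
for connectance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import igraph as ig
import pandas as pd

__all__ = [
    "TrophicNetwork",
    "UndirectedProjection",
    "read_edge_list",
    "read_adjacency_matrix",
    "to_projection",
    "write_edge_list",
    "write_results_table",
    "RESULT_COLUMNS",
]


class NetworkParseError(ValueError):
    """Raised when an input file cannot be interpreted as a food web."""


@dataclass(frozen=True)
class TrophicNetwork:
    """A directed food web: nodes are trophic species, links run resource -> consumer."""

    name: str
    nodes: tuple
    links: tuple
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        if len(self.nodes) < 1:
            raise ValueError("a network needs at least one node")
        node_set = set(self.nodes)
        seen = set()
        for link in self.links:
            if len(link) != 2:
                raise ValueError(f"link {link!r} is not a (resource, consumer) pair")
            if link[0] not in node_set or link[1] not in node_set:
                raise ValueError(f"link {link!r} references an undeclared node")
            if link in seen:
                raise ValueError(f"duplicate directed link {link!r}")
            seen.add(link)

    @property
    def S(self) -> int:
        return len(self.nodes)

    @property
    def L(self) -> int:
        return len(self.links)

    @property
    def n_self_loops(self) -> int:
        return sum(1 for a, b in self.links if a == b)


@dataclass(frozen=True)
class UndirectedProjection:
    """Undirected simple graph underlying a directed web; no loops, no multi-edges.

    Edges are stored canonically: endpoints ordered by their position in
    ``nodes``, the edge tuple sorted, so equal graphs compare equal and a
    fixed generator seed yields a byte-identical edge list.
    """

    nodes: tuple
    edges: tuple
    n_loops_dropped: int = 0
    n_reciprocal_merged: int = 0

    def __post_init__(self) -> None:
        index = {v: i for i, v in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node labels")
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge {a!r}")
            key = (index[a], index[b]) if index[a] < index[b] else (index[b], index[a])
            if key in seen:
                raise ValueError(f"duplicate edge {{{a!r}, {b!r}}}")
            seen.add(key)

    @property
    def S(self) -> int:
        return len(self.nodes)

    @property
    def E(self) -> int:
        return len(self.edges)

    def to_igraph(self) -> ig.Graph:
        index = {v: i for i, v in enumerate(self.nodes)}
        g = ig.Graph(
            n=len(self.nodes),
            edges=[(index[a], index[b]) for a, b in self.edges],
            directed=False,
        )
        g.vs["name"] = [str(v) for v in self.nodes]
        return g

    @classmethod
    def from_edges(
        cls,
        nodes: Sequence,
        edges: Iterable[tuple],
        **counts,
    ) -> "UndirectedProjection":
        """Canonicalize an edge iterable (dedupe, drop loops, order endpoints)."""
        nodes = tuple(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        keys = set()
        for a, b in edges:
            if a == b:
                continue
            i, j = index[a], index[b]
            keys.add((i, j) if i < j else (j, i))
        canon = tuple((nodes[i], nodes[j]) for i, j in sorted(keys))
        return cls(nodes=nodes, edges=canon, **counts)


def to_projection(net: TrophicNetwork) -> UndirectedProjection:
    """Project a directed web onto its undirected simple graph.

    Self-loops are dropped and reciprocal pairs (a->b plus b->a) merged; the
    counts of both are recorded on the result.
    """
    index = {v: i for i, v in enumerate(net.nodes)}
    n_loops = 0
    n_reciprocal = 0
    keys = set()
    for a, b in net.links:
        if a == b:
            n_loops += 1
            continue
        i, j = index[a], index[b]
        key = (i, j) if i < j else (j, i)
        if key in keys:
            n_reciprocal += 1
        else:
            keys.add(key)
    edges = tuple((net.nodes[i], net.nodes[j]) for i, j in sorted(keys))
    return UndirectedProjection(
        nodes=net.nodes,
        edges=edges,
        n_loops_dropped=n_loops,
        n_reciprocal_merged=n_reciprocal,
    )


def read_edge_list(
    path,
    delimiter: str = "\t",
    directed: bool = True,
    name: str | None = None,
) -> TrophicNetwork:
    """Read a delimited trophic edge list into a :class:`TrophicNetwork`.

    Dialect: lines starting with ``#`` are comments, except a ``#nodes:``
    line which declares the full node list (so isolated species survive the
    round trip).  Each data row is ``resource<delim>consumer`` with an
    optional third column (interaction strength) that is ignored.  Duplicate
    rows are collapsed with a warning.  With ``directed=False`` each row is
    additionally mirrored, which is only useful for undirected fixtures.
    """
    path = Path(path)
    declared: list = []
    links: list[tuple] = []
    seen: set[tuple] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("nodes:"):
                    declared.extend(
                        lab.strip()
                        for lab in body[len("nodes:"):].split(delimiter)
                        if lab.strip()
                    )
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected at least 2 fields "
                    f"(resource{delimiter!r}consumer), got {line!r}"
                )
            pairs = [(fields[0], fields[1])]
            if not directed and fields[0] != fields[1]:
                pairs.append((fields[1], fields[0]))
            for pair in pairs:
                if pair in seen:
                    n_dup += 1
                else:
                    seen.add(pair)
                    links.append(pair)
    if not links and not declared:
        raise NetworkParseError(f"{path}: no links or node declarations found")
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate link rows", stacklevel=2)

    nodes: list = []
    known = set()
    for lab in declared:
        if lab not in known:
            known.add(lab)
            nodes.append(lab)
    for a, b in links:
        for lab in (a, b):
            if lab not in known:
                known.add(lab)
                nodes.append(lab)
    net = TrophicNetwork(
        name=name if name is not None else path.stem,
        nodes=tuple(nodes),
        links=tuple(links),
        metadata={"n_duplicate_rows": n_dup, "source": str(path)},
    )
    return net


def read_adjacency_matrix(path, delimiter: str = ",", name: str | None = None) -> TrophicNetwork:
    """Read a labelled binary adjacency matrix; entry (i, j) = 1 means link i -> j."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise NetworkParseError(
            f"{path}: adjacency matrix must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    df.columns = [str(c) for c in df.columns]
    df.index = [str(r) for r in df.index]
    if list(df.columns) != list(df.index):
        raise NetworkParseError(f"{path}: row and column labels differ")
    values = df.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise NetworkParseError(f"{path}: adjacency entries must be 0 or 1")
    nodes = tuple(df.index)
    links = tuple(
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(len(nodes))
        if values[i, j] == 1
    )
    n_loops = sum(1 for a, b in links if a == b)
    return TrophicNetwork(
        name=name if name is not None else path.stem,
        nodes=nodes,
        links=links,
        metadata={"n_self_loops": n_loops, "source": str(path)},
    )


def write_edge_list(obj, path, delimiter: str = "\t") -> None:
    """Write a network or projection as a delimited edge list with a #nodes: header."""
    path = Path(path)
    if isinstance(obj, TrophicNetwork):
        nodes, pairs = obj.nodes, obj.links
    elif isinstance(obj, UndirectedProjection):
        nodes, pairs = obj.nodes, obj.edges
    else:
        raise TypeError(f"cannot write {type(obj).__name__}")
    with path.open("w") as fh:
        fh.write("#nodes:" + delimiter.join(str(v) for v in nodes) + "\n")
        for a, b in pairs:
            fh.write(f"{a}{delimiter}{b}\n")


RESULT_COLUMNS = [
    "name",
    "S",
    "L",
    "C",
    "CPL",
    "CC",
    "DD_best_model",
    "CPL_ratio",
    "CC_ratio",
    "SW_conf",
    "SWS",
    "SW_sws",
]

_FLOAT_COLUMNS = ["C", "CPL", "CC", "CPL_ratio", "CC_ratio", "SWS"]


def write_results_table(rows: list[dict], path, precision: int = 2) -> pd.DataFrame:
    """Write per-web results as CSV with floats rounded to ``precision`` decimals."""
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for col in _FLOAT_COLUMNS:
        if col in df.columns and len(df):
            df[col] = df[col].astype(float).round(precision)
    df.to_csv(path, index=False)
    return df
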