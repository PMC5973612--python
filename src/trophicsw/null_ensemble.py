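"""Erdős–Rényi G(n, M) null ensembles with percentile confidence intervals.

The null model matches the empirical web in node count S and edge count:
graphs are drawn uniformly from all simple undirected graphs with exactly S
nodes and L edges.  For each replicate the same path-length and clustering
metrics are computed as for the empirical web, and the replicate
distribution is summarized by its mean and an empirical percentile
confidence interval (default 99%: the 0.5% and 99.5% quantiles, linear
interpolation between order statistics).

Connectivity is not enforced; a replicate's unreachable pairs are excluded
from its CPL exactly as for empirical webs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metrics import characteristic_path_length, clustering_coefficient
from .net_io import UndirectedProjection

__all__ = ["EnsembleSummary", "generate_er", "ensemble_metrics", "percentile_ci"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate values of one metric over a matched random ensemble."""

    metric_name: str  # "CPL" or "CC"
    replicates: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_rep: int
    seed: int
    S: int
    L: int
    level: float = 0.99


def percentile_ci(values, level: float = 0.99) -> tuple[float, float]:
    """Central empirical quantile interval at coverage ``level``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _decode_pair_index(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map linear index m in [0, n(n-1)/2) to the unordered pair (i, j), i < j.

    Pairs are ordered by the larger endpoint: index = j(j-1)/2 + i.
    """
    j = ((1.0 + np.sqrt(8.0 * m + 1.0)) / 2.0).astype(np.int64)
    j = np.where(j * (j - 1) // 2 > m, j - 1, j)
    j = np.where((j + 1) * j // 2 <= m, j + 1, j)
    i = m - j * (j - 1) // 2
    return i, j


def generate_er(S: int, L: int, seed) -> UndirectedProjection:
    """Draw one G(n, M) graph: S nodes, exactly L edges, uniform over all such graphs.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; a fixed int seed is fully deterministic.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    max_edges = S * (S - 1) // 2
    if not 0 <= L <= max_edges:
        raise ValueError(f"L={L} outside [0, {max_edges}] for S={S}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(max_edges, size=L, replace=False) if L else np.empty(0, dtype=np.int64)
    i, j = _decode_pair_index(np.sort(idx).astype(np.int64))
    edges = tuple(zip(i.tolist(), j.tolist()))
    return UndirectedProjection(nodes=tuple(range(S)), edges=edges)


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # substream per replicate: the first n replicates are identical whatever n_rep is
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(r)]))


def ensemble_metrics(
    S: int,
    L: int,
    n_rep: int = 1000,
    seed: int = 0,
    level: float = 0.99,
) -> tuple[EnsembleSummary, EnsembleSummary]:
    """Generate the matched ensemble and summarize CPL and CC distributions.

    Returns ``(cpl_summary, cc_summary)`` with aligned replicate vectors
    (replicate r of both summaries comes from the same random graph).
    Replicates whose CPL is undefined (no connected pair) are skipped; more
    than 1% skipped is an error.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    cpls: list[float] = []
    ccs: list[float] = []
    n_skipped = 0
    for r in range(n_rep):
        g = generate_er(S, L, _replicate_rng(seed, r)).to_igraph()
        try:
            cpl, _ = characteristic_path_length(g)
        except ValueError:
            n_skipped += 1
            logger.warning("replicate %d of ER(%d, %d) has no connected pair; skipped", r, S, L)
            continue
        cpls.append(cpl)
        ccs.append(clustering_coefficient(g))
    if n_skipped > 0.01 * n_rep:
        raise RuntimeError(
            f"{n_skipped}/{n_rep} replicates of ER({S}, {L}) had no connected pair"
        )

    def _summary(name: str, values: list[float]) -> EnsembleSummary:
        arr = np.asarray(values, dtype=float)
        lo, hi = percentile_ci(arr, level)
        return EnsembleSummary(
            metric_name=name,
            replicates=arr,
            mean=float(arr.mean()),
            ci_low=lo,
            ci_high=hi,
            n_rep=len(values),
            seed=seed,
            S=S,
            L=L,
            level=level,
        )

    return _summary("CPL", cpls), _summary("CC", ccs)
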