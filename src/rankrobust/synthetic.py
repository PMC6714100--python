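"""Synthetic scored-network generators.

Two generators mirror the study designs used to probe context
dependence: a Bernoulli random graph with scores resampled from an
empirical pool (homogeneous topology, random scores) and a
score-shuffled induced subgraph (fixed topology, randomized score
placement).  A preferential-attachment fixture with a bimodal score
distribution stands in for a real interactome when none is available.

All scores are rounded to 6 decimals so networks survive the TSV writer
round-trip bit-exactly.  Node labels are zero-padded ("n0001", ...) for
stable lexicographic ordering.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .network_io import ScoredNetwork

__all__ = [
    "bernoulli_scored",
    "score_shuffle",
    "empirical_score_pool",
    "score_histogram",
    "heterogeneous_scored_fixture",
]


def _labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"n{i + 1:0{width}d}" for i in range(n)]


def _round_scores(scores: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(scores, dtype=float), 6)


def bernoulli_scored(
    n: int, p: float, score_pool: Sequence[float], seed: int
) -> ScoredNetwork:
    """G(n, p) with each edge scored by a uniform draw (with
    replacement) from ``score_pool``."""
    if n < 2:
        raise ValueError(f"need n >= 2 nodes, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    pool = _round_scores(np.asarray(score_pool, dtype=float))
    if pool.size == 0:
        raise ValueError("score_pool must be non-empty")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < p
    scores = rng.choice(pool, size=int(present.sum()), replace=True)
    edges = {
        (labels[i], labels[j]): float(s)
        for i, j, s in zip(iu[present], ju[present], scores)
    }
    return ScoredNetwork(node_ids=tuple(labels), edges=edges)


def score_shuffle(net: ScoredNetwork, n_sub: int, seed: int) -> ScoredNetwork:
    """Induced random subgraph with its scores permuted over its edges.

    Picks ``n_sub`` nodes uniformly at random, takes the induced
    subgraph, and rearranges the subgraph's score multiset uniformly at
    random over its (fixed) edge set.  Topology and score multiset are
    preserved exactly.
    """
    if n_sub > net.n_nodes:
        raise ValueError(
            f"n_sub = {n_sub} exceeds network size N = {net.n_nodes}"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(net.node_ids, size=n_sub, replace=False))
    pairs = sorted(
        (u, v) for (u, v) in net.edges if u in chosen and v in chosen
    )
    scores = np.array([net.edges[pair] for pair in pairs])
    perm = rng.permutation(len(pairs))
    edges = {pair: float(scores[perm[i]]) for i, pair in enumerate(pairs)}
    return ScoredNetwork(node_ids=tuple(sorted(chosen)), edges=edges)


def empirical_score_pool(net: ScoredNetwork) -> np.ndarray:
    """The multiset of edge scores (canonical edge order), for
    resampling."""
    if net.n_edges == 0:
        raise ValueError("cannot build a score pool from an edgeless network")
    return net.scores()


def score_histogram(pool: Sequence[float]) -> pd.DataFrame:
    """0.01-wide score histogram; counts sum to the pool size."""
    pool = np.asarray(pool, dtype=float)
    counts, edges = np.histogram(pool, bins=100, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def heterogeneous_scored_fixture(
    n: int, seed: int, m: int = 3
) -> ScoredNetwork:
    """PIN-like stand-in: preferential-attachment topology with a
    right-skewed bimodal score distribution on [0.15, 1].

    Growth: start from a (m+1)-clique; each new node attaches to ``m``
    distinct existing nodes chosen proportionally to degree.  Scores mix
    a low mode (~0.2-0.3) and a high mode (~0.85-0.95), echoing typical
    combined-score histograms.
    """
    if n < 10:
        raise ValueError(f"need n >= 10 nodes, got {n}")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    edges_idx: list[tuple[int, int]] = []
    stubs: list[int] = []  # node repeated once per unit of degree
    core = m + 1
    for i in range(core):
        for j in range(i + 1, core):
            edges_idx.append((i, j))
            stubs.extend((i, j))
    for v in range(core, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(stubs[rng.integers(len(stubs))])
        for u in sorted(targets):
            edges_idx.append((u, v))
            stubs.extend((u, v))
    n_edges = len(edges_idx)
    low = 0.15 + 0.85 * rng.beta(1.8, 8.0, size=n_edges)
    high = 0.15 + 0.85 * rng.beta(8.0, 1.8, size=n_edges)
    scores = _round_scores(np.where(rng.random(n_edges) < 0.55, low, high))
    edges = {}
    for (i, j), s in zip(edges_idx, scores):
        u, v = labels[i], labels[j]
        edges[(u, v) if u <= v else (v, u)] = float(s)
    return ScoredNetwork(node_ids=tuple(labels), edges=edges)
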