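"""Confidence-score thresholding of a scored network.

Thresholds are carried as integer hundredths (``theta=40`` means 0.40) so
that an 85-step sweep from 0.15 to 0.99 lands exactly on the grid with no
floating-point drift.  An edge scoring exactly the threshold is kept:
only edges scoring *strictly below* the threshold are discarded.  The
node set is never altered — thresholding may isolate nodes but never
removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .network_io import ScoredNetwork

__all__ = [
    "ThresholdedNetwork",
    "ConfidenceRegion",
    "apply_threshold",
    "threshold_series",
    "series_summaries",
]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """A simple unweighted graph at threshold ``theta`` (hundredths),
    on the full node universe of the parent :class:`ScoredNetwork`."""

    theta: int
    node_ids: tuple[str, ...]
    graph: ig.Graph

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()

    def edge_pairs(self) -> set[tuple[str, str]]:
        names = self.node_ids
        out = set()
        for a, b in self.graph.get_edgelist():
            u, v = names[a], names[b]
            out.add((u, v) if u <= v else (v, u))
        return out


@dataclass(frozen=True)
class ConfidenceRegion:
    """Inclusive threshold interval [mu, nu], both in hundredths."""

    mu: int
    nu: int

    def __post_init__(self) -> None:
        if not (15 <= self.mu <= self.nu <= 99):
            raise ValueError(
                f"require 15 <= mu <= nu <= 99, got mu={self.mu}, nu={self.nu}"
            )

    def contains(self, theta: int) -> bool:
        return self.mu <= theta <= self.nu


def apply_threshold(net: ScoredNetwork, theta: int) -> ThresholdedNetwork:
    """Keep edges with score >= theta/100; node set unchanged."""
    theta = int(theta)
    if not 0 <= theta <= 100:
        raise ValueError(f"theta must be in 0..100 hundredths, got {theta}")
    cut = theta / 100.0
    index = {node: i for i, node in enumerate(net.node_ids)}
    pairs = [
        (index[u], index[v]) for (u, v), s in net.edges.items() if s >= cut
    ]
    g = ig.Graph(n=net.n_nodes, edges=pairs, directed=False)
    g.vs["name"] = list(net.node_ids)
    return ThresholdedNetwork(theta=theta, node_ids=net.node_ids, graph=g)


def threshold_series(
    net: ScoredNetwork, lo: int = 15, hi: int = 99, step: int = 1
) -> list[ThresholdedNetwork]:
    """Sweep the threshold from ``lo`` to ``hi`` inclusive (hundredths).

    With the defaults (15, 99, 1) this yields 85 nested networks: the
    edge set at a higher threshold is always a subset of the edge set at
    any lower one.
    """
    lo, hi, step = int(lo), int(hi), int(step)
    if step <= 0:
        raise ValueError(f"step must be a positive number of hundredths, got {step}")
    if lo > hi:
        raise ValueError(f"require lo <= hi, got lo={lo}, hi={hi}")
    return [apply_threshold(net, t) for t in range(lo, hi + 1, step)]


def series_summaries(series: list[ThresholdedNetwork]) -> pd.DataFrame:
    """Per-threshold structural summaries (one row per theta).

    Columns: ``theta`` (as 0.15-style float), ``avg_degree`` = 2|E|/N,
    ``avg_local_clustering`` (degree<2 nodes contribute 0),
    ``giant_fraction`` = |largest component|/N.
    """
    if not series:
        raise ValueError("empty threshold series")
    rows = []
    for tn in series:
        g = tn.graph
        n = tn.n_nodes
        lc = np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)
        giant = max(g.connected_components().sizes()) / n
        rows.append(
            {
                "theta": tn.theta / 100.0,
                "avg_degree": 2.0 * g.ecount() / n,
                "avg_local_clustering": float(lc.mean()) if n else 0.0,
                "giant_fraction": giant,
            }
        )
    return pd.DataFrame(rows)
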