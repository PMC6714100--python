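"""Leave-one-out difference (LOUD) metrics.

For a global summary ``f`` and each node ``v`` of degree >= 2,

    loud_f(v) = f(G) - f(G_v)

where ``G_v`` is ``G`` with every edge incident to ``v`` removed (the
node itself stays).  Leaves and isolated nodes get NA (NaN): the rank
module later sends NA nodes to the bottom of the ranking.

The thirteen summaries are means over *all* N nodes of the per-node
metrics (isolated nodes contribute 0 through the node-metric
conventions), plus the global clustering coefficient, average path
length over connected pairs, the number of connected pairs, and natural
connectivity — the log of the average exponentiated adjacency
eigenvalue, computed by dense symmetric eigendecomposition with a
log-sum-exp overflow guard.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import igraph as ig
import numpy as np
from scipy.special import logsumexp

from . import node_metrics as nm
from .thresholding import ThresholdedNetwork

SUMMARY_NAMES: tuple[str, ...] = (
    "avg_local_clustering",
    "global_clustering",
    "avg_redundancy",
    "avg_closeness",
    "avg_path_length",
    "connected_pairs",
    "avg_betweenness",
    "natural_connectivity",
    "avg_e_one",
    "avg_n_two",
    "avg_n_diff",
    "avg_n_sqdiff",
    "avg_n_ratio",
)

LOUD_METRIC_NAMES: tuple[str, ...] = tuple(f"loud_{n}" for n in SUMMARY_NAMES)

# which shared intermediates each summary needs
_NEEDS = {
    "avg_local_clustering": {"lc"},
    "global_clustering": {"transitivity"},
    "avg_redundancy": {"lc", "deg"},
    "avg_closeness": {"dist"},
    "avg_path_length": {"dist"},
    "connected_pairs": {"dist"},
    "avg_betweenness": {"dist"},
    "natural_connectivity": {"eig"},
    "avg_e_one": {"lc", "deg"},
    "avg_n_two": {"dist"},
    "avg_n_diff": {"dist"},
    "avg_n_sqdiff": {"dist", "deg"},
    "avg_n_ratio": {"dist", "deg"},
}

__all__ = [
    "SUMMARY_NAMES",
    "LOUD_METRIC_NAMES",
    "isolate_node",
    "natural_connectivity",
    "global_summary",
    "global_summaries",
    "loud_table",
]


def isolate_node(G, v):
    """Remove all edges incident to ``v``; the node set is unchanged.

    ``v`` may be a vertex index (igraph input) or a node id string
    (ThresholdedNetwork input).  Returns the same type it was given.
    """
    if isinstance(G, ThresholdedNetwork):
        if v not in G.node_ids:
            raise KeyError(f"unknown node {v!r}")
        idx = G.node_ids.index(v)
        g2 = _isolate(G.graph, idx)
        return ThresholdedNetwork(theta=G.theta, node_ids=G.node_ids, graph=g2)
    g: ig.Graph = G
    if not 0 <= int(v) < g.vcount():
        raise KeyError(f"unknown vertex index {v!r}")
    return _isolate(g, int(v))


def _isolate(g: ig.Graph, idx: int) -> ig.Graph:
    g2 = g.copy()
    g2.delete_edges(g2.incident(idx))
    return g2


def natural_connectivity(G) -> float:
    """ln( (1/N) * sum_i exp(lambda_i) ) over adjacency eigenvalues."""
    g = nm.as_igraph(G)
    n = g.vcount()
    if n == 0:
        raise ValueError("natural connectivity undefined on the empty vertex set")
    eig = np.linalg.eigvalsh(nm.adjacency_matrix(g))
    return float(logsumexp(eig) - np.log(n))


def _summaries_from_parts(g: ig.Graph, names: Sequence[str]) -> dict[str, float]:
    need: set[str] = set()
    for name in names:
        need |= _NEEDS[name]
    n = g.vcount()
    parts: dict[str, np.ndarray] = {}
    if {"lc", "deg"} & need:
        parts["deg"] = nm._degree(g)
        parts["lc"] = nm._local_clustering(g)
    if "dist" in need:
        parts["dist"] = nm.distance_matrix(g)
    out: dict[str, float] = {}
    for name in names:
        if name == "avg_local_clustering":
            out[name] = float(parts["lc"].mean())
        elif name == "global_clustering":
            t = g.transitivity_undirected(mode="zero")
            out[name] = float(t)
        elif name == "avg_redundancy":
            out[name] = float((parts["lc"] * (parts["deg"] - 1.0)).mean())
        elif name == "avg_e_one":
            e1 = parts["deg"] + nm._triangles(parts["deg"], parts["lc"])
            out[name] = float(e1.mean())
        elif name == "avg_betweenness":
            # sum of (endpoint-excluded, unnormalized) betweenness over all
            # nodes equals sum over connected pairs of (d(u,w) - 1), since
            # every shortest path has exactly d-1 interior vertices
            d = parts["dist"]
            finite = np.isfinite(d) & (d > 0)
            out[name] = float((d[finite].sum() - finite.sum()) / 2.0 / n)
        elif name == "natural_connectivity":
            eig = np.linalg.eigvalsh(nm.adjacency_matrix(g))
            out[name] = float(logsumexp(eig) - np.log(n))
        elif name in ("avg_closeness", "avg_path_length", "connected_pairs",
                      "avg_n_two", "avg_n_diff", "avg_n_sqdiff", "avg_n_ratio"):
            d = parts["dist"]
            if name == "avg_closeness":
                sums = np.where(np.isfinite(d), d, 0.0).sum(axis=1)
                clo = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
                out[name] = float(clo.mean())
            elif name == "avg_path_length":
                finite = np.isfinite(d) & (d > 0)
                cnt = finite.sum()
                out[name] = float(d[finite].sum() / cnt) if cnt else 0.0
            elif name == "connected_pairs":
                finite = np.isfinite(d) & (d > 0)
                out[name] = float(finite.sum() / 2)
            else:
                n_two = (d <= 2).sum(axis=1).astype(float)
                if name == "avg_n_two":
                    out[name] = float(n_two.mean())
                elif name == "avg_n_diff":
                    out[name] = float((d == 2).sum(axis=1).mean())
                elif name == "avg_n_sqdiff":
                    out[name] = float((n_two - parts["deg"] ** 2).mean())
                else:  # avg_n_ratio
                    out[name] = float(((parts["deg"] + 1.0) / n_two).mean())
        else:
            raise ValueError(f"unknown global summary {name!r}")
    return out


def global_summaries(G, names: Iterable[str] | None = None) -> dict[str, float]:
    """Compute several global summaries in one pass, sharing the distance
    matrix, degree/clustering vectors and eigendecomposition."""
    g = nm.as_igraph(G)
    names = tuple(SUMMARY_NAMES if names is None else names)
    for name in names:
        if name not in _NEEDS:
            raise ValueError(f"unknown global summary {name!r}")
    return _summaries_from_parts(g, names)


def global_summary(G, name: str) -> float:
    """A single named global summary of a simple undirected graph."""
    return global_summaries(G, [name])[name]


def _normalize_loud_names(names: Iterable[str] | None) -> tuple[str, ...]:
    if names is None:
        return SUMMARY_NAMES
    out = []
    for name in names:
        base = name[5:] if name.startswith("loud_") else name
        if base not in _NEEDS:
            raise ValueError(f"unknown LOUD metric {name!r}")
        out.append(base)
    return tuple(out)


def loud_table(
    G,
    names: Iterable[str] | None = None,
    nodes: Iterable[int] | None = None,
) -> dict[str, np.ndarray]:
    """LOUD values per node for the requested summaries.

    Returns ``{"loud_<name>": array}`` aligned with vertex order; nodes
    of degree < 2 hold NaN (the NA policy), as do nodes outside an
    explicit ``nodes`` subset (a cost cap for large graphs).  ``f(G)``
    is computed once per summary.
    """
    g = nm.as_igraph(G)
    base_names = _normalize_loud_names(names)
    n = g.vcount()
    deg = np.asarray(g.degree())
    eligible = np.flatnonzero(deg >= 2)
    if nodes is not None:
        subset = set(int(v) for v in nodes)
        eligible = np.array([v for v in eligible if v in subset], dtype=int)
    f_g = _summaries_from_parts(g, base_names)
    out = {f"loud_{name}": np.full(n, np.nan) for name in base_names}
    for v in eligible:
        f_gv = _summaries_from_parts(_isolate(g, int(v)), base_names)
        for name in base_names:
            out[f"loud_{name}"][v] = f_g[name] - f_gv[name]
    return out
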