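"""The twelve per-node centralities.

All functions accept either a :class:`~rankrobust.thresholding.ThresholdedNetwork`
or a bare :class:`igraph.Graph` and return dicts mapping metric name to a
float array aligned with the graph's vertex order.

Conventions (ranks, not raw values, are consumed downstream):

* local clustering of degree-<2 nodes is 0, never NA;
* closeness sums distances to reachable nodes only and is 0 for a node
  with nothing reachable;
* betweenness is unnormalized with endpoints excluded;
* the step-two neighbourhood count ``n_two`` includes the ego itself,
  hence ``n_ratio = (degree+1)/n_two`` and the identity
  ``n_two = 1 + degree + n_diff``.
"""

from __future__ import annotations

import igraph as ig
import numpy as np
import scipy.sparse as sp

CENTRALITY_NAMES: tuple[str, ...] = (
    "degree",
    "local_clustering",
    "redundancy",
    "pagerank",
    "closeness",
    "harmonic",
    "betweenness",
    "e_one",
    "n_two",
    "n_diff",
    "n_sqdiff",
    "n_ratio",
)

__all__ = [
    "CENTRALITY_NAMES",
    "degree_family",
    "path_family",
    "ego_family",
    "all_centralities",
]


def as_igraph(G) -> ig.Graph:
    return G.graph if hasattr(G, "graph") else G


def distance_matrix(g: ig.Graph) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths, inf for unreachable.

    Level-synchronous BFS from all sources at once, with the frontier
    expansion done as a BLAS matrix product — much faster than per-source
    BFS on the dense-ish graphs this package targets, and exact.
    """
    n = g.vcount()
    a = adjacency_matrix(g)
    af = a.astype(np.float32)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = (a > 0) & ~reach
    level = 1
    while frontier.any():
        d[frontier] = level
        reach |= frontier
        nxt = (frontier.astype(np.float32) @ af) > 0
        frontier = nxt & ~reach
        level += 1
    return d


def adjacency_matrix(g: ig.Graph) -> np.ndarray:
    n = g.vcount()
    a = np.zeros((n, n))
    if g.ecount():
        idx = np.asarray(g.get_edgelist())
        a[idx[:, 0], idx[:, 1]] = 1.0
        a[idx[:, 1], idx[:, 0]] = 1.0
    return a


def _degree(g: ig.Graph) -> np.ndarray:
    return np.asarray(g.degree(), dtype=float)


def _local_clustering(g: ig.Graph) -> np.ndarray:
    return np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)


def _triangles(deg: np.ndarray, lc: np.ndarray) -> np.ndarray:
    # edges among a node's neighbours, recovered exactly from clustering
    return np.rint(lc * deg * (deg - 1.0) / 2.0)


def _pagerank(g: ig.Graph, damping: float = 0.85, tol: float = 1e-9,
              max_iter: int = 10_000) -> np.ndarray:
    """Power-iteration PageRank with uniform teleport and uniform
    redistribution of isolated-node mass; L1 convergence tolerance."""
    n = g.vcount()
    if n == 0:
        return np.zeros(0)
    deg = _degree(g)
    if g.ecount():
        idx = np.asarray(g.get_edgelist())
        rows = np.concatenate([idx[:, 0], idx[:, 1]])
        cols = np.concatenate([idx[:, 1], idx[:, 0]])
        a = sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n, n)
        )
    else:
        a = sp.csr_matrix((n, n))
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    dangling = deg == 0
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = a @ (x * inv_deg)
        y += x[dangling].sum() / n
        x_new = (1.0 - damping) / n + damping * y
        if np.abs(x_new - x).sum() < tol:
            return x_new
        x = x_new
    return x


def degree_family(G) -> dict[str, np.ndarray]:
    """degree, local_clustering, redundancy = clustering * (degree - 1)."""
    g = as_igraph(G)
    deg = _degree(g)
    lc = _local_clustering(g)
    return {
        "degree": deg,
        "local_clustering": lc,
        "redundancy": lc * (deg - 1.0) + 0.0,  # +0.0 normalizes -0.0
    }


def path_family(G, damping: float = 0.85, *, _dist: np.ndarray | None = None
                ) -> dict[str, np.ndarray]:
    """closeness, harmonic, betweenness, pagerank."""
    g = as_igraph(G)
    d = distance_matrix(g) if _dist is None else _dist
    finite = np.isfinite(d)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    closeness = np.divide(
        1.0, sums, out=np.zeros_like(sums), where=sums > 0
    )
    with np.errstate(divide="ignore"):
        inv = np.where((d > 0) & finite, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    harmonic = inv.sum(axis=1)
    return {
        "closeness": closeness,
        "harmonic": harmonic,
        "betweenness": np.asarray(g.betweenness(), dtype=float),
        "pagerank": _pagerank(g, damping=damping),
    }


def ego_family(G, *, _dist: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """e_one, n_two, n_diff, n_sqdiff, n_ratio (see module docstring)."""
    g = as_igraph(G)
    d = distance_matrix(g) if _dist is None else _dist
    deg = _degree(g)
    lc = _local_clustering(g)
    e_one = deg + _triangles(deg, lc)
    n_two = (d <= 2).sum(axis=1).astype(float)  # diag 0 counts the ego
    n_diff = (d == 2).sum(axis=1).astype(float)
    return {
        "e_one": e_one,
        "n_two": n_two,
        "n_diff": n_diff,
        "n_sqdiff": n_two - deg**2,
        "n_ratio": (deg + 1.0) / n_two,
    }


def all_centralities(G, damping: float = 0.85) -> dict[str, np.ndarray]:
    """All 12 centralities, sharing one distance-matrix computation.

    Returned dict is keyed and ordered by :data:`CENTRALITY_NAMES`.
    """
    g = as_igraph(G)
    d = distance_matrix(g)
    out: dict[str, np.ndarray] = {}
    out.update(degree_family(g))
    out.update(path_family(g, damping=damping, _dist=d))
    out.update(ego_family(g, _dist=d))
    return {name: out[name] for name in CENTRALITY_NAMES}
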