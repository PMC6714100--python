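"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written against networkx / scipy.expm /
explicit set arithmetic, never through the code paths under test.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import scipy.linalg


# ---------------------------------------------------------------- centralities

def oracle_centralities(g: nx.Graph) -> dict[str, dict]:
    nodes = sorted(g.nodes())
    deg = {v: g.degree(v) for v in nodes}
    lc = {v: nx.clustering(g, v) if deg[v] >= 2 else 0.0 for v in nodes}
    closeness, harmonic = {}, {}
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        s = sum(d for u, d in lengths.items() if u != v)
        closeness[v] = 1.0 / s if s > 0 else 0.0
        harmonic[v] = sum(1.0 / d for u, d in lengths.items() if u != v)
    betw = nx.betweenness_centrality(g, normalized=False)
    pr = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
    e_one, n_two, n_diff = {}, {}, {}
    for v in nodes:
        e_one[v] = nx.ego_graph(g, v, radius=1).number_of_edges()
        lengths = nx.single_source_shortest_path_length(g, v, cutoff=2)
        n_two[v] = len(lengths)
        n_diff[v] = sum(1 for d in lengths.values() if d == 2)
    return {
        "degree": {v: float(deg[v]) for v in nodes},
        "local_clustering": lc,
        "redundancy": {v: lc[v] * (deg[v] - 1) for v in nodes},
        "pagerank": pr,
        "closeness": closeness,
        "harmonic": harmonic,
        "betweenness": betw,
        "e_one": {v: float(e_one[v]) for v in nodes},
        "n_two": {v: float(n_two[v]) for v in nodes},
        "n_diff": {v: float(n_diff[v]) for v in nodes},
        "n_sqdiff": {v: float(n_two[v] - deg[v] ** 2) for v in nodes},
        "n_ratio": {v: (deg[v] + 1) / n_two[v] for v in nodes},
    }


# ------------------------------------------------------------ global summaries

def oracle_natural_connectivity(g: nx.Graph) -> float:
    # independent route: trace of the matrix exponential
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
    return float(np.log(np.trace(scipy.linalg.expm(a)) / g.number_of_nodes()))


def oracle_summary(g: nx.Graph, name: str) -> float:
    n = g.number_of_nodes()
    if name == "global_clustering":
        return nx.transitivity(g)
    if name == "natural_connectivity":
        return oracle_natural_connectivity(g)
    if name == "connected_pairs":
        return float(sum(len(c) * (len(c) - 1) // 2
                         for c in nx.connected_components(g)))
    if name == "avg_path_length":
        total, cnt = 0.0, 0
        for v, lengths in nx.all_pairs_shortest_path_length(g):
            for u, d in lengths.items():
                if u != v:
                    total += d
                    cnt += 1
        return total / cnt if cnt else 0.0
    cent = oracle_centralities(g)
    base = {
        "avg_local_clustering": "local_clustering",
        "avg_redundancy": "redundancy",
        "avg_closeness": "closeness",
        "avg_betweenness": "betweenness",
        "avg_e_one": "e_one",
        "avg_n_two": "n_two",
        "avg_n_diff": "n_diff",
        "avg_n_sqdiff": "n_sqdiff",
        "avg_n_ratio": "n_ratio",
    }[name]
    return float(np.mean(list(cent[base].values())))


def oracle_loud(g: nx.Graph, name: str) -> dict:
    """f(G) - f(G_v) per node, NA (None) below degree 2."""
    f_g = oracle_summary(g, name)
    out = {}
    for v in sorted(g.nodes()):
        if g.degree(v) < 2:
            out[v] = None
            continue
        gv = g.copy()
        gv.remove_edges_from(list(g.edges(v)))
        out[v] = f_g - oracle_summary(gv, name)
    return out


# ------------------------------------------------------------------- rankings

def oracle_top(ranks: dict, n: int) -> set:
    """Nodes with the n largest ranks (ranks are a 1..N bijection)."""
    return set(sorted(ranks, key=ranks.get, reverse=True)[:n])


def oracle_size(n: int, k: float) -> int:
    return max(1, min(n, math.floor(n * k + 0.5)))


def oracle_k_sim(a: dict, b: dict, k: float) -> float:
    n = len(a)
    m = oracle_size(n, k)
    return len(oracle_top(a, m) & oracle_top(b, m)) / m


def oracle_relaxed(a: dict, b: dict, k: float, alpha: float) -> float:
    n = len(a)
    m = oracle_size(n, k)
    ma = max(m, oracle_size(n, min(k * alpha, 1.0)))
    return len(oracle_top(b, m) & oracle_top(a, ma)) / m


def oracle_continuity(rank_by_theta: dict, k_grid, cutoff=0.90) -> float:
    thetas = sorted(rank_by_theta)
    hits = total = 0
    for t1, t2 in zip(thetas[:-1], thetas[1:]):
        for k in k_grid:
            total += 1
            if oracle_k_sim(rank_by_theta[t1], rank_by_theta[t2], k) >= cutoff:
                hits += 1
    return hits / total


def oracle_identifiability(rank_by_theta: dict, b: dict, top_n: int,
                           alpha: float) -> float:
    n = len(b)
    return min(
        oracle_relaxed(a, b, top_n / n, alpha)
        for a in rank_by_theta.values()
    )


def oracle_instability(rank_by_theta: dict, b: dict, top_frac=0.01) -> float:
    n = len(b)
    u = oracle_top(b, max(1, math.floor(top_frac * n + 0.5)))
    total = 0.0
    for v in u:
        rs = [a[v] for a in rank_by_theta.values()]
        total += (max(rs) - min(rs)) / n
    return total / len(u)
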