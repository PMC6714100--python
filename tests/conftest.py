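from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from rankrobust import ScoredNetwork, ThresholdedNetwork, apply_threshold
from rankrobust.ranking import Ranking


def label(i: int) -> str:
    return f"v{i:03d}"


def tn_from_nx(g: nx.Graph, theta: int = 50) -> ThresholdedNetwork:
    """Build a ThresholdedNetwork through the public API from a
    networkx graph (all edges scored 1.0, full node set preserved)."""
    mapping = {v: label(i) for i, v in enumerate(sorted(g.nodes()))}
    edges = {}
    for u, v in g.edges():
        a, b = mapping[u], mapping[v]
        edges[(a, b) if a <= b else (b, a)] = 1.0
    net = ScoredNetwork.from_edges(edges, extra_nodes=mapping.values())
    return apply_threshold(net, theta)


def tn_and_nx(g: nx.Graph) -> tuple[ThresholdedNetwork, nx.Graph]:
    """The thresholded network plus the same graph relabelled to match
    its node ids (for oracle comparison)."""
    mapping = {v: label(i) for i, v in enumerate(sorted(g.nodes()))}
    return tn_from_nx(g), nx.relabel_nodes(g, mapping)


def random_graphs(count: int, n_max: int, seed: int, n_min: int = 4):
    """Erdős–Rényi graphs of varied size/density, isolated nodes kept."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.05, 0.5))
        out.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return out


def random_ranking(nodes: tuple[str, ...], rng: np.random.Generator) -> Ranking:
    return Ranking(nodes=nodes, ranks=rng.permutation(len(nodes)) + 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
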