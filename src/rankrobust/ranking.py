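"""Turning metric values into full node rankings.

A ranking assigns every node an integer rank in 1..N, with N the *best*
(highest metric value).  NA nodes receive the smallest ranks, permuted
uniformly at random among themselves; exact-value ties are likewise
permuted uniformly within the tied block.  Tie-break randomness for each
(metric, threshold) cell comes from an independently seeded substream
derived from a master seed, so results do not depend on computation
order.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thresholding import ConfidenceRegion

__all__ = [
    "Ranking",
    "RankMatrix",
    "OverallRanking",
    "rank_nodes",
    "substream",
    "rank_matrix_from_table",
    "overall_ranking",
]


def substream(master_seed: int, *labels) -> np.random.Generator:
    """Independent reproducible RNG stream for a labelled cell.

    The labels (e.g. metric name and threshold) are hashed so the stream
    depends only on the cell identity and master seed, never on the
    order in which cells are computed.
    """
    digest = hashlib.sha256("|".join(str(x) for x in labels).encode()).digest()
    return np.random.default_rng(
        [int(master_seed) & 0xFFFFFFFF, int.from_bytes(digest[:8], "big")]
    )


@dataclass(frozen=True)
class Ranking:
    """A bijection node -> rank in 1..N; rank N is the best."""

    nodes: tuple[str, ...]
    ranks: np.ndarray  # int array aligned with nodes

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=int)
        n = len(self.nodes)
        if r.shape != (n,) or sorted(r.tolist()) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        object.__setattr__(self, "ranks", r)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __getitem__(self, node: str) -> int:
        return int(self.ranks[self.nodes.index(node)])

    def as_dict(self) -> dict[str, int]:
        return {v: int(r) for v, r in zip(self.nodes, self.ranks)}

    def top(self, n: int) -> frozenset[str]:
        """The n highest-ranking nodes (ranks > N - n)."""
        cut = self.n - int(n)
        return frozenset(
            v for v, r in zip(self.nodes, self.ranks) if r > cut
        )


def rank_nodes(
    values: Mapping[str, float] | pd.Series,
    rng: np.random.Generator,
) -> Ranking:
    """Rank the full node universe by metric value.

    ``values`` maps every node to a real or NaN (NA).  NA nodes form a
    tie block at the bottom; ties (including the NA block) are permuted
    uniformly at random from ``rng``.  Nodes are processed in sorted-id
    order so the result is deterministic given the stream state.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    nodes = tuple(sorted(values))
    vals = np.array([values[v] for v in nodes], dtype=float)
    keys = np.where(np.isnan(vals), -np.inf, vals)
    jitter = rng.random(len(nodes))
    order = np.lexsort((jitter, keys))  # ascending value, random within ties
    ranks = np.empty(len(nodes), dtype=int)
    ranks[order] = np.arange(1, len(nodes) + 1)
    return Ranking(nodes=nodes, ranks=ranks)


@dataclass
class RankMatrix:
    """Rankings per (metric, theta) over one shared node universe."""

    nodes: tuple[str, ...]
    _cells: dict[tuple[str, int], Ranking] = field(default_factory=dict)

    def set(self, metric: str, theta: int, ranking: Ranking) -> None:
        if ranking.nodes != self.nodes:
            raise ValueError("ranking node universe mismatch")
        self._cells[(metric, int(theta))] = ranking

    def get(self, metric: str, theta: int) -> Ranking:
        try:
            return self._cells[(metric, int(theta))]
        except KeyError:
            raise KeyError(
                f"no ranking for metric {metric!r} at theta={theta}"
            ) from None

    def metrics(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m, _ in self._cells:
            seen.setdefault(m)
        return tuple(seen)

    def thetas(self, metric: str) -> tuple[int, ...]:
        return tuple(sorted(t for m, t in self._cells if m == metric))

    def region_thetas(self, metric: str, region: ConfidenceRegion) -> tuple[int, ...]:
        """Thresholds of this matrix inside [mu, nu], checked for gaps.

        The grid step is inferred from the stored thresholds; a missing
        grid point inside the region raises, naming the threshold.
        """
        all_t = self.thetas(metric)
        if not all_t:
            raise KeyError(f"no rankings for metric {metric!r}")
        inside = [t for t in all_t if region.contains(t)]
        if not inside:
            raise ValueError(
                f"no thresholds for metric {metric!r} inside "
                f"[{region.mu}, {region.nu}]"
            )
        step = min(np.diff(all_t)) if len(all_t) > 1 else 1
        expected = range(inside[0], inside[-1] + 1, int(step))
        for t in expected:
            if t not in inside:
                raise ValueError(
                    f"missing ranking for metric {metric!r} at theta={t}"
                )
        return tuple(inside)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (theta, metric, node, rank) table."""
        rows = []
        for (metric, theta), ranking in sorted(self._cells.items()):
            for v, r in zip(ranking.nodes, ranking.ranks):
                rows.append((theta / 100.0, metric, v, int(r)))
        return pd.DataFrame(rows, columns=["theta", "metric", "node", "rank"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankMatrix":
        nodes = tuple(sorted(df["node"].unique()))
        rm = cls(nodes=nodes)
        for (theta, metric), grp in df.groupby(["theta", "metric"], sort=True):
            ranks = grp.set_index("node")["rank"]
            rm.set(
                str(metric),
                int(round(float(theta) * 100)),
                Ranking(nodes=nodes, ranks=ranks.reindex(list(nodes)).to_numpy()),
            )
        return rm


@dataclass(frozen=True)
class OverallRanking:
    """Region-averaged ranking B for one metric."""

    metric: str
    region: ConfidenceRegion
    ranking: Ranking


def rank_matrix_from_table(
    table: pd.DataFrame, master_seed: int
) -> RankMatrix:
    """Build the full rank matrix from a long-format metric table.

    ``table`` has columns (theta, node, metric, value) with NaN for NA.
    Each (metric, theta) cell is ranked with its own RNG substream.
    """
    nodes = tuple(sorted(table["node"].unique()))
    rm = RankMatrix(nodes=nodes)
    for (theta, metric), grp in table.groupby(["theta", "metric"], sort=True):
        t = int(round(float(theta) * 100))
        values = grp.set_index("node")["value"].reindex(list(nodes))
        rng = substream(master_seed, "rank", metric, t)
        rm.set(str(metric), t, rank_nodes(values, rng))
    return rm


def overall_ranking(
    rm: RankMatrix,
    metric: str,
    region: ConfidenceRegion,
    rng: np.random.Generator,
) -> OverallRanking:
    """Mean rank per node over the region's thresholds, then re-ranked
    (ties broken at random — no NA can occur at this stage)."""
    thetas = rm.region_thetas(metric, region)
    total = np.zeros(len(rm.nodes))
    for t in thetas:
        total += rm.get(metric, t).ranks
    means = dict(zip(rm.nodes, total / len(thetas)))
    return OverallRanking(
        metric=metric, region=region, ranking=rank_nodes(means, rng)
    )
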