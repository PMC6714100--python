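"""k-similarity, relaxed k-similarity, and the three robustness measures.

Top-set sizes are realized as ``n_k = max(1, round(N*k))`` (round half
away from zero) and similarities are normalized by the realized size, so
every measure lies in [0, 1] and identical rankings always score 1.  A
``size_mode`` flag exposes ceil/floor alternatives for the literal
non-integer ``N*k`` corner of the defining formulas.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ranking import OverallRanking, Ranking, RankMatrix, overall_ranking, substream
from .thresholding import ConfidenceRegion

DEFAULT_K_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(1, 51) / 1000.0, 3)
)

__all__ = [
    "DEFAULT_K_GRID",
    "RobustnessReport",
    "k_similarity",
    "relaxed_k_similarity",
    "rank_continuity",
    "rank_identifiability",
    "rank_instability",
    "robustness_report",
]


def _top_size(n: int, k: float, size_mode: str = "round") -> int:
    if size_mode == "round":
        m = math.floor(n * k + 0.5)
    elif size_mode == "ceil":
        m = math.ceil(n * k)
    elif size_mode == "floor":
        m = math.floor(n * k)
    else:
        raise ValueError(f"unknown size_mode {size_mode!r}")
    return max(1, min(n, m))


def _check_universe(a: Ranking, b: Ranking) -> int:
    if a.nodes != b.nodes:
        raise ValueError("rankings are over different node universes")
    return a.n


def k_similarity(a: Ranking, a2: Ranking, k: float, size_mode: str = "round") -> float:
    """Overlap fraction of the two rankings' top-100k% node sets.

    Symmetric in its arguments; 1 for identical rankings, 0 for disjoint
    top sets.
    """
    n = _check_universe(a, a2)
    if not 0.0 < k <= 1.0:
        raise ValueError(f"k must be in (0, 1], got {k}")
    n_k = _top_size(n, k, size_mode)
    return len(a.top(n_k) & a2.top(n_k)) / n_k


def relaxed_k_similarity(
    a: Ranking, b: Ranking, k: float, alpha: float, size_mode: str = "round"
) -> float:
    """Fraction of B's top-100k% nodes found in A's top-100k*alpha%.

    Asymmetric (A is the tested ranking, B the reference); reduces to
    :func:`k_similarity` at alpha=1.
    """
    n = _check_universe(a, b)
    if not 0.0 < k <= 1.0:
        raise ValueError(f"k must be in (0, 1], got {k}")
    if alpha < 1.0:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    if k * alpha > 1.0 + 1e-12:
        raise ValueError(f"k*alpha must be <= 1, got {k * alpha}")
    n_k = _top_size(n, k, size_mode)
    n_ka = max(n_k, _top_size(n, min(k * alpha, 1.0), size_mode))
    return len(b.top(n_k) & a.top(n_ka)) / n_k


def rank_continuity(
    rm: RankMatrix,
    metric: str,
    region: ConfidenceRegion,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    cutoff: float = 0.90,
    size_mode: str = "round",
    pair_policy: str = "within",
) -> float:
    """Fraction of (consecutive-threshold pair, k) cells whose
    k-similarity reaches the cutoff (comparison is >=).

    ``pair_policy="within"`` (default) pairs adjacent thresholds with
    both endpoints inside the region; ``"extend"`` additionally pairs
    the region's upper endpoint with the next threshold outside it when
    one exists (the literal reading of the defining index set).
    """
    thetas = list(rm.region_thetas(metric, region))
    if pair_policy == "extend":
        all_t = rm.thetas(metric)
        later = [t for t in all_t if t > thetas[-1]]
        if later:
            thetas.append(later[0])
    elif pair_policy != "within":
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    if len(thetas) < 2:
        raise ValueError(
            "rank continuity needs at least two thresholds in the region"
        )
    hits = 0
    total = 0
    for t1, t2 in zip(thetas[:-1], thetas[1:]):
        a1, a2 = rm.get(metric, t1), rm.get(metric, t2)
        for k in k_grid:
            total += 1
            if k_similarity(a1, a2, k, size_mode) >= cutoff:
                hits += 1
    return hits / total


def rank_identifiability(
    rm: RankMatrix,
    metric: str,
    b: OverallRanking,
    top_n: int = 100,
    alpha: float = 1.5,
    size_mode: str = "round",
) -> float:
    """Worst-case relaxed similarity of any single-threshold ranking to
    the overall ranking: min over theta of M_k^alpha(A_theta, B) with
    k = top_n/N."""
    n = len(rm.nodes)
    if top_n * alpha > n:
        raise ValueError(
            f"top_n*alpha = {top_n * alpha} exceeds N = {n}"
        )
    k = top_n / n
    thetas = rm.region_thetas(metric, b.region)
    return min(
        relaxed_k_similarity(rm.get(metric, t), b.ranking, k, alpha, size_mode)
        for t in thetas
    )


def rank_instability(
    rm: RankMatrix,
    metric: str,
    b: OverallRanking,
    top_frac: float = 0.01,
) -> float:
    """Mean scaled rank range, across the region, of the overall top
    ``top_frac`` of nodes (lower is more stable)."""
    n = len(rm.nodes)
    u = b.ranking.top(max(1, int(math.floor(top_frac * n + 0.5))))
    thetas = rm.region_thetas(metric, b.region)
    rank_rows = np.stack([rm.get(metric, t).ranks for t in thetas])
    node_index = {v: i for i, v in enumerate(rm.nodes)}
    cols = [node_index[v] for v in u]
    ranges = rank_rows[:, cols].max(axis=0) - rank_rows[:, cols].min(axis=0)
    return float(ranges.mean() / n)


@dataclass(frozen=True)
class RobustnessReport:
    """Per-metric (continuity, identifiability, instability) triples
    plus the parameters they were computed with."""

    table: pd.DataFrame  # columns: metric, continuity, identifiability, instability
    params: dict

    def as_comments(self) -> list[str]:
        return [f"{key} = {value}" for key, value in sorted(self.params.items())]


def robustness_report(
    rm: RankMatrix,
    region: ConfidenceRegion,
    metrics: Iterable[str] | None = None,
    master_seed: int = 0,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    cutoff: float = 0.90,
    top_n: int = 100,
    alpha: float = 1.5,
    top_frac: float = 0.01,
    size_mode: str = "round",
) -> RobustnessReport:
    """All three robustness measures for every metric in the matrix.

    ``top_n`` is capped at floor(N/alpha) with a warning when the
    network is too small for the requested top set (mirrors dropping the
    overall top-100 target to top-20 on a 500-node network).
    """
    metrics = tuple(rm.metrics() if metrics is None else metrics)
    n = len(rm.nodes)
    eff_top_n = min(top_n, int(n // alpha))
    if eff_top_n < top_n:
        warnings.warn(
            f"top_n reduced from {top_n} to {eff_top_n} so that "
            f"top_n*alpha <= N = {n}",
            stacklevel=2,
        )
    rows = []
    for metric in metrics:
        b = overall_ranking(
            rm, metric, region, substream(master_seed, "overall", metric)
        )
        rows.append(
            {
                "metric": metric,
                "continuity": rank_continuity(
                    rm, metric, region, k_grid, cutoff, size_mode
                ),
                "identifiability": rank_identifiability(
                    rm, metric, b, eff_top_n, alpha, size_mode
                ),
                "instability": rank_instability(rm, metric, b, top_frac),
            }
        )
    params = {
        "region_mu": region.mu / 100.0,
        "region_nu": region.nu / 100.0,
        "k_grid_min": float(min(k_grid)),
        "k_grid_max": float(max(k_grid)),
        "k_grid_size": len(tuple(k_grid)),
        "cutoff": cutoff,
        "top_n": eff_top_n,
        "alpha": alpha,
        "top_frac": top_frac,
        "size_mode": size_mode,
        "master_seed": master_seed,
    }
    return RobustnessReport(table=pd.DataFrame(rows), params=params)
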