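"""End-to-end pipeline: scored network -> thresholds -> metric table ->
rank matrix -> robustness report.  Shared by the CLI and by scripted
use; everything is deterministic given the master seed."""

from __future__ import annotations

import time
from collections.abc import Callable, Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import loud_metrics, node_metrics
from .network_io import ScoredNetwork
from .ranking import RankMatrix, rank_matrix_from_table
from .robustness import DEFAULT_K_GRID, RobustnessReport, robustness_report
from .thresholding import (
    ConfidenceRegion,
    ThresholdedNetwork,
    series_summaries,
    threshold_series,
)

ALL_METRIC_NAMES: tuple[str, ...] = (
    node_metrics.CENTRALITY_NAMES + loud_metrics.LOUD_METRIC_NAMES
)

__all__ = ["ALL_METRIC_NAMES", "RunConfig", "metric_table", "run_pipeline"]


def metric_table(
    series: Iterable[ThresholdedNetwork],
    metrics: Iterable[str] | None = None,
    loud_nodes: Iterable[int] | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Long-format (theta, node, metric, value) table over a threshold
    series; NaN marks NA (LOUD metrics at degree-<2 nodes)."""
    metrics = tuple(ALL_METRIC_NAMES if metrics is None else metrics)
    unknown = set(metrics) - set(ALL_METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    cent = [m for m in metrics if m in node_metrics.CENTRALITY_NAMES]
    loud = [m for m in metrics if m in loud_metrics.LOUD_METRIC_NAMES]
    frames = []
    for tn in series:
        t0 = time.perf_counter()
        values: dict[str, np.ndarray] = {}
        if cent:
            allc = node_metrics.all_centralities(tn)
            values.update({m: allc[m] for m in cent})
        if loud:
            values.update(loud_metrics.loud_table(tn, loud, nodes=loud_nodes))
        for m in metrics:
            frames.append(
                pd.DataFrame(
                    {
                        "theta": tn.theta / 100.0,
                        "node": list(tn.node_ids),
                        "metric": m,
                        "value": values[m],
                    }
                )
            )
        if progress is not None:
            progress(
                f"theta={tn.theta / 100.0:.2f}: {len(metrics)} metrics in "
                f"{time.perf_counter() - t0:.2f}s"
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run (defaults follow the
    study: grid 0.15-0.99 step 0.01, region 0.60-0.90, k-grid
    0.001-0.05, alpha 1.5, top_n 100, top 1%, cutoff 0.90)."""

    lo: int = 15
    hi: int = 99
    step: int = 1
    mu: int = 60
    nu: int = 90
    metrics: tuple[str, ...] = ALL_METRIC_NAMES
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    alpha: float = 1.5
    top_n: int = 100
    top_frac: float = 0.01
    cutoff: float = 0.90
    seed: int = 0
    loud_nodes: tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lo <= self.mu <= self.nu <= self.hi):
            raise ValueError(
                "confidence region must lie within the threshold grid: "
                f"lo={self.lo} mu={self.mu} nu={self.nu} hi={self.hi}"
            )
        unknown = set(self.metrics) - set(ALL_METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    def region(self) -> ConfidenceRegion:
        return ConfidenceRegion(mu=self.mu, nu=self.nu)

    def as_comments(self) -> list[str]:
        return [
            f"grid = {self.lo / 100:.2f}..{self.hi / 100:.2f} step {self.step / 100:.2f}",
            f"region = [{self.mu / 100:.2f}, {self.nu / 100:.2f}]",
            f"metrics = {','.join(self.metrics)}",
            f"k_grid = {min(self.k_grid)}..{max(self.k_grid)} ({len(self.k_grid)} values)",
            f"alpha = {self.alpha}",
            f"top_n = {self.top_n}",
            f"top_frac = {self.top_frac}",
            f"cutoff = {self.cutoff}",
            f"seed = {self.seed}",
        ]


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    metrics: pd.DataFrame
    rank_matrix: RankMatrix
    report: RobustnessReport


def run_pipeline(
    net: ScoredNetwork,
    config: RunConfig,
    progress: Callable[[str], None] | None = None,
) -> PipelineResult:
    """Threshold, measure, rank and score one scored network."""
    log = progress or (lambda _msg: None)
    t0 = time.perf_counter()
    series = threshold_series(net, config.lo, config.hi, config.step)
    log(f"thresholding: {len(series)} networks in {time.perf_counter() - t0:.2f}s")

    t0 = time.perf_counter()
    summaries = series_summaries(series)
    log(f"summaries in {time.perf_counter() - t0:.2f}s")

    t0 = time.perf_counter()
    table = metric_table(
        series, config.metrics, loud_nodes=config.loud_nodes, progress=progress
    )
    log(f"metric table in {time.perf_counter() - t0:.2f}s")

    t0 = time.perf_counter()
    rm = rank_matrix_from_table(table, config.seed)
    log(f"rank matrix in {time.perf_counter() - t0:.2f}s")

    t0 = time.perf_counter()
    report = robustness_report(
        rm,
        config.region(),
        metrics=config.metrics,
        master_seed=config.seed,
        k_grid=config.k_grid,
        cutoff=config.cutoff,
        top_n=config.top_n,
        alpha=config.alpha,
        top_frac=config.top_frac,
    )
    log(f"robustness report in {time.perf_counter() - t0:.2f}s")
    return PipelineResult(
        summaries=summaries, metrics=table, rank_matrix=rm, report=report
    )
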