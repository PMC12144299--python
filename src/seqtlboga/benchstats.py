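"""Benchmark harness and nonparametric comparison statistics.

Implements the rank-based comparison workflow: per-block average ranks
(midranks for ties, rank 1 = best), the average-rank form of the Friedman
chi-square statistic, and z-based post-hoc comparisons against the control
(best-ranked) algorithm with Holm, Hochberg, and Li adjusted thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from seqtlboga.optimizer import OptimizerConfig, RunRecord, run

__all__ = [
    "RankTable",
    "PosthocResult",
    "average_ranks",
    "friedman_statistic",
    "friedman_pvalue",
    "posthoc_z",
    "run_benchmark",
    "BenchmarkReport",
]


@dataclass(frozen=True)
class RankTable:
    """Per-block scores with midrank-tied rankings (rank 1 = best score)."""

    scores: np.ndarray  # (N blocks, k algorithms); higher is better
    ranks: np.ndarray  # same shape; midranks
    avg_ranks: np.ndarray  # length k

    @property
    def n_blocks(self) -> int:
        return self.scores.shape[0]

    @property
    def n_algorithms(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise z statistics vs the control and adjusted thresholds.

    ``comparisons`` lists the competitor column indices in decreasing-z
    (i.e. increasing-p) order; thresholds are aligned with that order.
    """

    control_index: int
    comparisons: np.ndarray  # competitor indices, sorted by p ascending
    z_values: np.ndarray
    p_values: np.ndarray
    thresholds: dict = field(default_factory=dict)  # {"holm": ..., "hochberg": ..., "li": ...}
    rejections: dict = field(default_factory=dict)
    alpha: float = 0.05


def average_ranks(scores: np.ndarray) -> RankTable:
    """Rank each block's scores descending (1 = best) with midranks for
    ties, then average per column."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be an N x k matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 algorithms")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    # rank descending: rankdata on negated scores gives 1 = best, midranks for ties
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in scores])
    return RankTable(scores=scores, ranks=ranks, avg_ranks=ranks.mean(axis=0))


def friedman_statistic(avg_ranks: np.ndarray, n_blocks: int, k: int | None = None) -> tuple[float, int]:
    """Average-rank form of the Friedman chi-square statistic.

    ``chi2 = [12 N / (k (k+1))] * sum_j (Rbar_j - (k+1)/2)**2`` with
    ``df = k - 1``.
    """
    avg_ranks = np.asarray(avg_ranks, dtype=float)
    if k is None:
        k = avg_ranks.size
    if avg_ranks.size != k:
        raise ValueError("avg_ranks length must equal k")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    center = (k + 1) / 2.0
    chi2 = 12.0 * n_blocks / (k * (k + 1)) * float(np.sum((avg_ranks - center) ** 2))
    return chi2, k - 1


def friedman_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square p-value."""
    return float(stats.chi2.sf(chi2, df))


def _holm_thresholds(m: int, alpha: float) -> np.ndarray:
    # step-down: alpha / (m - i) for the i-th smallest p (0-based)
    return alpha / (m - np.arange(m))


def _li_thresholds(p_sorted: np.ndarray, alpha: float) -> np.ndarray:
    # the largest p is compared to alpha; the rest to alpha(1-p_max)/(1-alpha)
    m = p_sorted.size
    out = np.full(m, alpha * (1.0 - p_sorted[-1]) / (1.0 - alpha))
    out[-1] = alpha
    return out


def posthoc_z(
    avg_ranks: np.ndarray,
    control_index: int,
    n_blocks: int,
    k: int | None = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Compare every algorithm against the control by rank difference.

    ``z_i = (Rbar_i - Rbar_0) / SE`` with ``SE = sqrt(k (k+1) / (6 N))``;
    two-sided normal p-values; Holm (step-down), Hochberg (step-up) and Li
    thresholds at level ``alpha``.  The control must hold the minimal
    average rank.
    """
    avg_ranks = np.asarray(avg_ranks, dtype=float)
    if k is None:
        k = avg_ranks.size
    if not (0 <= control_index < k):
        raise ValueError("control_index out of range")
    if avg_ranks[control_index] > avg_ranks.min() + 1e-12:
        raise ValueError("control must have the minimal average rank")
    se = np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    competitors = np.array([j for j in range(k) if j != control_index])
    z = (avg_ranks[competitors] - avg_ranks[control_index]) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    order = np.argsort(p, kind="stable")
    competitors, z, p = competitors[order], z[order], p[order]
    m = competitors.size

    holm = _holm_thresholds(m, alpha)
    hochberg = holm.copy()  # same thresholds, step-up scan
    li = _li_thresholds(p, alpha)

    rejections: dict[str, np.ndarray] = {}
    # Holm: step-down — stop at the first non-significant p
    rej = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[i] <= holm[i]:
            rej[i] = True
        else:
            break
    rejections["holm"] = rej
    # Hochberg: step-up — find the largest i with p_i <= threshold_i
    rej = np.zeros(m, dtype=bool)
    for i in range(m - 1, -1, -1):
        if p[i] <= hochberg[i]:
            rej[: i + 1] = True
            break
    rejections["hochberg"] = rej
    rejections["li"] = p <= li

    return PosthocResult(
        control_index=control_index,
        comparisons=competitors,
        z_values=z,
        p_values=p,
        thresholds={"holm": holm, "hochberg": hochberg, "li": li},
        rejections=rejections,
        alpha=alpha,
    )


@dataclass
class BenchmarkReport:
    """Aggregate of repeated seeded runs for several algorithms."""

    algorithms: list[str]
    scores: np.ndarray  # (n_runs, n_algorithms) final fitness per run
    records: list[list[RunRecord]]  # [algorithm][run]
    fp_rates: np.ndarray  # (n_runs, n_algorithms)
    fn_rates: np.ndarray
    rank_table: RankTable | None = None
    friedman: tuple[float, int, float] | None = None  # (chi2, df, p)
    posthoc: PosthocResult | None = None

    def histogram(self, which: str, algorithm: str, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts) for the FP- or FN-rate distribution."""
        col = self.algorithms.index(algorithm)
        data = {"fp": self.fp_rates, "fn": self.fn_rates}[which][:, col]
        data = data[np.isfinite(data)]
        counts, edges = np.histogram(data, bins=bins, range=(0.0, 1.0))
        return edges, counts

    def summary_rows(self) -> list[dict]:
        rows = []
        for j, algo in enumerate(self.algorithms):
            col = self.scores[:, j]
            rows.append(
                {
                    "algorithm": algo,
                    "mean_fitness": float(col.mean()),
                    "sd_fitness": float(col.std(ddof=1)) if col.size > 1 else 0.0,
                    "mean_fp_rate": float(np.nanmean(self.fp_rates[:, j])),
                    "mean_fn_rate": float(np.nanmean(self.fn_rates[:, j])),
                    "avg_rank": float(self.rank_table.avg_ranks[j])
                    if self.rank_table is not None
                    else float("nan"),
                }
            )
        return rows


def run_benchmark(
    dataset,
    algorithms: list[str],
    n_runs: int,
    config: OptimizerConfig,
) -> BenchmarkReport:
    """Run each algorithm ``n_runs`` times with seeds ``config.seed + r``.

    Per-run final fitness feeds the rank table (runs are the blocks); the
    Friedman test and post-hoc comparisons are attached when the shape
    permits (N >= 2, k >= 2).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not algorithms:
        raise ValueError("need at least one algorithm")
    from dataclasses import replace as _dc_replace

    records: list[list[RunRecord]] = []
    for algo in algorithms:
        algo_records = []
        for r in range(n_runs):
            cfg = _dc_replace(config, algorithm=algo, seed=config.seed + r)
            algo_records.append(run(dataset, cfg))
        records.append(algo_records)

    scores = np.array(
        [[records[j][r].best_fitness for j in range(len(algorithms))] for r in range(n_runs)]
    )
    fp = np.array(
        [[records[j][r].final_metrics.fpr for j in range(len(algorithms))] for r in range(n_runs)]
    )
    fn = np.array(
        [[records[j][r].final_metrics.fnr for j in range(len(algorithms))] for r in range(n_runs)]
    )

    report = BenchmarkReport(
        algorithms=list(algorithms),
        scores=scores,
        records=records,
        fp_rates=fp,
        fn_rates=fn,
    )
    if n_runs >= 2 and len(algorithms) >= 2:
        table = average_ranks(scores)
        chi2, df = friedman_statistic(table.avg_ranks, table.n_blocks)
        report.rank_table = table
        report.friedman = (chi2, df, friedman_pvalue(chi2, df))
        control = int(np.argmin(table.avg_ranks))
        report.posthoc = posthoc_z(table.avg_ranks, control, table.n_blocks)
    return report
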