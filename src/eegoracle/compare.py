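"""Inter-method comparison: per-epoch ranks, paired Wilcoxon tests, win rates.

Methods are compared strictly within a paired design — every method is
evaluated on the identical epochs of a (kind, NSR bin) stratum, typically at
each method's own bin-wise Opt1 configuration.  Per epoch, methods are
ranked by RRMSE (1 = lowest); the stratum summary reports the rank
distribution P1|P2|P3|P4 and the mean rank.  Pairwise differences are tested
with two-sided Wilcoxon signed-rank tests, Holm-adjusted within the stratum,
and summarized by the median paired difference and the win rate (ties count
for neither side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RankTable",
    "PairedStat",
    "rank_epochs",
    "rank_distribution",
    "wilcoxon_paired",
    "holm_adjust",
    "paired_summary",
    "run_comparison",
]


@dataclass
class RankTable:
    kind: str
    bin: str
    n: int
    methods: list[str]
    #: per method: percentages P1..PM of epochs at each rank
    p_rank: dict[str, np.ndarray]
    mean_rank: dict[str, float]

    def row(self, method: str) -> str:
        p = self.p_rank[method]
        return "|".join(f"{v:.1f}" for v in p) + f" ({self.mean_rank[method]:.2f})"


@dataclass
class PairedStat:
    a: str
    b: str
    kind: str
    bin: str
    median_diff: float  # median of per-epoch (a - b)
    win_rate: float  # fraction of epochs with a strictly lower
    p_raw: float
    p_holm: float = float("nan")


def rank_epochs(rrmse: np.ndarray, method_order: list[str] | None = None) -> np.ndarray:
    """Within-epoch ranks (1 = lowest RRMSE) for an epochs x methods matrix.

    Exact ties resolve by column order, so every row is a permutation of
    1..M and the comparison stays deterministic.
    """
    rrmse = np.asarray(rrmse, dtype=float)
    if rrmse.ndim != 2:
        raise ValueError("rank_epochs expects an epochs x methods matrix")
    if not np.all(np.isfinite(rrmse)):
        raise ValueError("rank_epochs: missing or non-finite cells")
    n, m = rrmse.shape
    cols = np.broadcast_to(np.arange(m), (n, m))
    order = np.lexsort((cols, rrmse), axis=1)  # value first, column index on ties
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, m + 1)
    return ranks


def rank_distribution(
    ranks: np.ndarray, methods: list[str], kind: str = "", bin_: str = ""
) -> RankTable:
    """P1..PM percentages and mean rank per method for one stratum."""
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise ValueError("empty stratum")
    n, m = ranks.shape
    if len(methods) != m:
        raise ValueError("method list does not match rank matrix width")
    p_rank = {}
    mean_rank = {}
    for j, name in enumerate(methods):
        counts = np.bincount(ranks[:, j], minlength=m + 1)[1:]
        p_rank[name] = 100.0 * counts / n
        mean_rank[name] = float(ranks[:, j].mean())
    return RankTable(kind=kind, bin=bin_, n=n, methods=list(methods), p_rank=p_rank, mean_rank=mean_rank)


def wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    small samples without ties, the tie-corrected normal approximation
    otherwise.  All-zero differences give p = 1 (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        logger.info("wilcoxon_paired: all differences zero; p = 1")
        return 1.0
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = _scipy_wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("holm_adjust requires at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adjusted]


def paired_summary(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Median of (a - b) and win rate of ``a`` (strictly lower; ties win nothing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    return float(np.median(a - b)), float(np.mean(a < b))


def run_comparison(
    per_epoch: pd.DataFrame,
    metric: str = "rrmse",
    method_col: str = "family",
) -> tuple[list[RankTable], list[PairedStat]]:
    """Rank tables and Holm-adjusted pairwise stats for every (kind, bin) stratum.

    ``per_epoch`` needs columns: epoch_id, kind, bin, ``method_col`` and
    ``metric`` — one row per (epoch, method), with every method covering the
    identical epochs within a stratum (e.g. produced at the method's bin-wise
    Opt1 config).  Strata are each (kind, bin) pair present plus the pooled
    ALL bin per kind.
    """
    from .mixture import ALL_BIN

    needed = {"epoch_id", "kind", "bin", method_col, metric}
    missing = needed - set(per_epoch.columns)
    if missing:
        raise ValueError(f"comparison table lacks columns: {sorted(missing)}")

    pooled = per_epoch.copy()
    pooled["bin"] = ALL_BIN
    table = pd.concat([per_epoch, pooled], ignore_index=True)
    methods = sorted(table[method_col].unique())

    rank_tables: list[RankTable] = []
    paired_stats: list[PairedStat] = []
    for (kind, bin_), stratum in table.groupby(["kind", "bin"], sort=True):
        wide = stratum.pivot_table(
            index="epoch_id", columns=method_col, values=metric, aggfunc="first"
        ).reindex(columns=methods)
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()].tolist()
            raise ValueError(
                f"stratum ({kind}, {bin_}): methods {bad} missing epochs (paired design)"
            )
        values = wide.to_numpy()
        ranks = rank_epochs(values)
        rank_tables.append(rank_distribution(ranks, methods, kind=kind, bin_=bin_))

        stats: list[PairedStat] = []
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a, b = values[:, i], values[:, j]
                med, win = paired_summary(a, b)
                stats.append(
                    PairedStat(
                        a=methods[i],
                        b=methods[j],
                        kind=kind,
                        bin=bin_,
                        median_diff=med,
                        win_rate=win,
                        p_raw=wilcoxon_paired(a, b),
                    )
                )
        adjusted = holm_adjust([s.p_raw for s in stats])
        for s, p in zip(stats, adjusted):
            s.p_holm = p
        paired_stats.extend(stats)
    return rank_tables, paired_stats


def rank_report(rank_tables: list[RankTable]) -> pd.DataFrame:
    """Flat 'P1|P2|P3|P4 (mean rank)' report, one row per (kind, bin, method)."""
    rows = []
    for rt in rank_tables:
        for m in rt.methods:
            rows.append(
                {
                    "kind": rt.kind,
                    "bin": rt.bin,
                    "n": rt.n,
                    "method": m,
                    "ranks": rt.row(m),
                    "mean_rank": rt.mean_rank[m],
                    **{f"P{i + 1}": rt.p_rank[m][i] for i in range(len(rt.methods))},
                }
            )
    return pd.DataFrame(rows)
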