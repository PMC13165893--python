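"""Hyperparameter selection per (family, kind, NSR bin) stratum.

Three selectors operate on per-epoch oracle results aggregated per config:

* **Best** — lowest mean RRMSE, runtime ignored.
* **Opt1** — effect-size-aware: among configs whose per-epoch RRMSE
  distribution differs from Best's by at most |Cohen's d| <= d0 (default
  0.05, a deliberately stringent "visually negligible" threshold), pick the
  fastest.
* **Opt2** — two-objective: Pareto front over (mean RRMSE, mean latency),
  min-max rescale both objectives over the front, pick the point nearest the
  utopia corner (0, 0).

All tie-breaks are deterministic: Best ties resolve by smaller mean latency
then grid order; Opt1 latency ties by smaller mean RRMSE then grid order;
Opt2 distance ties by smaller mean RRMSE then grid order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .decomp import MethodConfig, enumerate_grid
from .mixture import ALL_BIN, BIN_LABELS

__all__ = [
    "ConfigSummary",
    "SelectionTriple",
    "summarize",
    "select_best",
    "cohens_d",
    "select_opt1",
    "pareto_front",
    "select_opt2",
    "run_selection",
    "D0_DEFAULT",
    "VMD_OPT2_K_FLOOR",
]

D0_DEFAULT = 0.05
VMD_OPT2_K_FLOOR = 7  # very small mode counts excluded from Opt2 analysis


@dataclass
class ConfigSummary:
    """Per-stratum aggregate of one config over its (paired) epoch set."""

    family: str
    kind: str
    bin: str
    config: MethodConfig
    grid_index: int
    n: int
    mean_rrmse: float
    sd_rrmse: float
    mean_pcc: float
    sd_pcc: float
    mean_tdec: float
    rrmse_values: np.ndarray = field(repr=False)


@dataclass
class SelectionTriple:
    family: str
    kind: str
    bin: str
    best: ConfigSummary
    opt1: ConfigSummary
    opt2: ConfigSummary
    d_opt1: float
    pareto_set: list[MethodConfig]


def _grid_order(family: str) -> dict[str, int]:
    return {cfg.label: i for i, cfg in enumerate(enumerate_grid(family))}


def summarize(results: pd.DataFrame) -> list[ConfigSummary]:
    """Aggregate a per-epoch results table into per-config summaries.

    ``results`` needs columns: epoch_id, family, kind, bin, config_label,
    rrmse, pcc, t_dec.  All configs of a (family, kind, bin) stratum must
    cover the identical epoch set (paired design); NaN PCCs (undefined
    correlations) are excluded from PCC means only.
    """
    required = {"epoch_id", "family", "kind", "bin", "config_label", "rrmse", "pcc", "t_dec"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    if results.empty:
        raise ValueError("empty results table")

    summaries: list[ConfigSummary] = []
    for (family, kind, bin_), stratum in results.groupby(["family", "kind", "bin"], sort=True):
        order = _grid_order(family)
        epoch_sets = {
            label: frozenset(g["epoch_id"]) for label, g in stratum.groupby("config_label")
        }
        reference = next(iter(epoch_sets.values()))
        unequal = [lbl for lbl, s in epoch_sets.items() if s != reference]
        if unequal:
            raise ValueError(
                f"paired design violated in ({family}, {kind}, {bin_}): "
                f"configs {sorted(unequal)} cover different epoch sets"
            )
        for label, g in stratum.groupby("config_label"):
            g = g.sort_values("epoch_id")
            rr = g["rrmse"].to_numpy()
            pc = g["pcc"].to_numpy()
            pc_def = pc[~np.isnan(pc)]
            n = len(g)
            if n < 2:
                raise ValueError(
                    f"stratum ({family}, {kind}, {bin_}) has n={n} < 2 epochs for {label}"
                )
            summaries.append(
                ConfigSummary(
                    family=family,
                    kind=kind,
                    bin=bin_,
                    config=_config_from_label(family, label),
                    grid_index=order[label],
                    n=n,
                    mean_rrmse=float(rr.mean()),
                    sd_rrmse=float(rr.std(ddof=1)),
                    mean_pcc=float(pc_def.mean()) if pc_def.size else float("nan"),
                    sd_pcc=float(pc_def.std(ddof=1)) if pc_def.size > 1 else float("nan"),
                    mean_tdec=float(g["t_dec"].mean()),
                    rrmse_values=rr,
                )
            )
    return summaries


def _config_from_label(family: str, label: str) -> MethodConfig:
    for cfg in enumerate_grid(family):
        if cfg.label == label:
            return cfg
    raise ValueError(f"config label {label!r} not on the {family} grid")


def select_best(summaries: list[ConfigSummary]) -> ConfigSummary:
    """Argmin of mean RRMSE; ties by smaller mean latency, then grid order."""
    if not summaries:
        raise ValueError("no summaries to select from")
    return min(summaries, key=lambda s: (s.mean_rrmse, s.mean_tdec, s.grid_index))


def cohens_d(rrmse_h: np.ndarray, rrmse_best: np.ndarray) -> float:
    """Standardized mean difference (h minus Best) with pooled n-1 variances.

    Equal samples give exactly 0; zero pooled spread with unequal means gives
    a signed infinity flag.
    """
    a = np.asarray(rrmse_h, dtype=float)
    b = np.asarray(rrmse_best, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires n >= 2 in both samples")
    diff = a.mean() - b.mean()
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))


def select_opt1(
    summaries: list[ConfigSummary],
    best: ConfigSummary,
    d0: float = D0_DEFAULT,
) -> tuple[ConfigSummary, float]:
    """Fastest config within the |d| <= d0 tolerance set around Best.

    Returns the selection and its Cohen's d versus Best.  Best itself has
    d = 0, so the tolerance set is never empty.
    """
    tol_set = [
        s for s in summaries if abs(cohens_d(s.rrmse_values, best.rrmse_values)) <= d0
    ]
    opt1 = min(tol_set, key=lambda s: (s.mean_tdec, s.mean_rrmse, s.grid_index))
    return opt1, cohens_d(opt1.rrmse_values, best.rrmse_values)


def pareto_front(summaries: list[ConfigSummary]) -> list[ConfigSummary]:
    """Non-dominated set under (mean RRMSE, mean latency), both minimized.

    Exact duplicates on both objectives collapse to the grid-order-first one.
    """
    if not summaries:
        raise ValueError("no summaries to select from")
    ordered = sorted(summaries, key=lambda s: s.grid_index)
    front: list[ConfigSummary] = []
    seen: set[tuple[float, float]] = set()
    for s in ordered:
        key = (s.mean_rrmse, s.mean_tdec)
        if key in seen:
            continue
        dominated = any(
            (o.mean_rrmse <= s.mean_rrmse and o.mean_tdec <= s.mean_tdec)
            and (o.mean_rrmse < s.mean_rrmse or o.mean_tdec < s.mean_tdec)
            for o in ordered
        )
        if not dominated:
            front.append(s)
            seen.add(key)
    return front


def select_opt2(summaries: list[ConfigSummary]) -> tuple[ConfigSummary, list[ConfigSummary]]:
    """Utopia-nearest Pareto point after min-max rescaling over the front.

    A zero-range objective maps every front point to 0 in that coordinate, so
    the distance then depends only on the informative objective.
    """
    front = pareto_front(summaries)

    def _scaled(values: list[float]) -> list[float]:
        lo, hi = min(values), max(values)
        if hi == lo:
            return [0.0] * len(values)
        return [(v - lo) / (hi - lo) for v in values]

    err = _scaled([s.mean_rrmse for s in front])
    lat = _scaled([s.mean_tdec for s in front])
    dist = [math.hypot(e, t) for e, t in zip(err, lat)]
    best_i = min(
        range(len(front)), key=lambda i: (dist[i], front[i].mean_rrmse, front[i].grid_index)
    )
    return front[best_i], front


def run_selection(
    results: pd.DataFrame,
    d0: float = D0_DEFAULT,
    vmd_opt2_k_floor: int | None = VMD_OPT2_K_FLOOR,
) -> list[SelectionTriple]:
    """Best/Opt1/Opt2 for every (family, kind, bin) stratum in the table.

    The pooled ALL bin is synthesized here by re-aggregating over all bins.
    For VMD, configurations with K below ``vmd_opt2_k_floor`` are excluded
    from the Opt2 Pareto analysis only (pass None to disable).

    (kind, bin) strata with fewer than two epochs never enter selection and
    are skipped for every family alike (the pooled bin still uses all
    epochs); a family missing rows in a populated stratum is an error.
    """
    counts = results.groupby(["kind", "bin"])["epoch_id"].nunique()
    thin = {kb for kb, n in counts.items() if n < 2}
    if thin:
        logger.debug("skipping strata with < 2 epochs: %s", sorted(thin))
    kept = results[~results.set_index(["kind", "bin"]).index.isin(thin)]
    pooled = results.copy()
    pooled["bin"] = ALL_BIN
    summaries = summarize(pd.concat([kept, pooled], ignore_index=True))

    by_stratum: dict[tuple[str, str, str], list[ConfigSummary]] = {}
    for s in summaries:
        by_stratum.setdefault((s.family, s.kind, s.bin), []).append(s)

    families = sorted(results["family"].unique())
    kinds = sorted(results["kind"].unique())
    bins = [b for b in BIN_LABELS if b in set(kept["bin"])] + [ALL_BIN]
    missing = [
        (f, k, b)
        for f in families
        for k in kinds
        for b in bins
        if (f, k, b) not in by_stratum and (k, b) not in thin
    ]
    if missing:
        raise ValueError(f"missing (family, kind, bin) cells: {missing}")

    triples: list[SelectionTriple] = []
    for (family, kind, bin_), cell in sorted(by_stratum.items()):
        cell = sorted(cell, key=lambda s: s.grid_index)
        best = select_best(cell)
        opt1, d_opt1 = select_opt1(cell, best, d0=d0)
        opt2_pool = cell
        if family == "vmd" and vmd_opt2_k_floor is not None:
            filtered = [s for s in cell if int(s.config["K"]) >= vmd_opt2_k_floor]
            if filtered:
                opt2_pool = filtered
        opt2, front = select_opt2(opt2_pool)
        triples.append(
            SelectionTriple(
                family=family,
                kind=kind,
                bin=bin_,
                best=best,
                opt1=opt1,
                opt2=opt2,
                d_opt1=d_opt1,
                pareto_set=[s.config for s in front],
            )
        )
    return triples


def selection_table(triples: list[SelectionTriple]) -> pd.DataFrame:
    """Flat report table (one row per stratum) mirroring the benchmark layout."""
    rows = []
    for t in triples:
        rows.append(
            {
                "family": t.family,
                "kind": t.kind,
                "bin": t.bin,
                "n": t.best.n,
                "best": t.best.config.label,
                "best_rrmse": t.best.mean_rrmse,
                "best_sd_rrmse": t.best.sd_rrmse,
                "best_pcc": t.best.mean_pcc,
                "best_tdec": t.best.mean_tdec,
                "opt1": t.opt1.config.label,
                "opt1_rrmse": t.opt1.mean_rrmse,
                "opt1_tdec": t.opt1.mean_tdec,
                "d_opt1": t.d_opt1,
                "opt2": t.opt2.config.label,
                "opt2_rrmse": t.opt2.mean_rrmse,
                "opt2_tdec": t.opt2.mean_tdec,
            }
        )
    return pd.DataFrame(rows)
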