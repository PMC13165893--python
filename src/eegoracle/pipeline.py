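"""End-to-end benchmark pipeline: synth -> decompose -> oracle -> select ->
shrink -> compare, reproducible from one integer seed.

Every stage is a plain function over in-memory objects; ``run_all`` wires
them together and writes plain-text reports (CSV/JSON) plus a manifest with
the configuration and per-file checksums.  Given a fixed seed, all outputs
except wall-clock latency columns are identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import rank_report, run_comparison
from .decomp import FAMILIES, MethodConfig, enumerate_grid, timed_decompose
from .mixture import BenchmarkConfig, Epoch, assign_bin, build_benchmark, noisy_baseline_rrmse
from .oracle import evaluate_epoch
from .selection import D0_DEFAULT, VMD_OPT2_K_FLOOR, SelectionTriple, run_selection, selection_table
from .shrinkage import baseline_bin_table, evaluate_baseline
from .signal_bank import synth_eeg, synth_emg, synth_eog

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "make_pools", "synthesize", "evaluate_grid", "run_all"]

_FAMILY_CODE = {f: i for i, f in enumerate(FAMILIES)}


@dataclass
class RunConfig:
    """Run-level knobs; defaults reproduce the benchmark design constants."""

    seed: int = 0
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    pool_sizes: dict = field(default_factory=lambda: {"eeg": 200, "eog": 100, "emg": 100})
    families: tuple[str, ...] = FAMILIES
    #: None = full grids; an int keeps every n-th grid point
    grid_stride: int | None = None
    #: explicit per-family grid-point indices; overrides grid_stride
    grid_indices: dict | None = None
    d0: float = D0_DEFAULT
    vmd_opt2_k_floor: int | None = VMD_OPT2_K_FLOOR
    shrinkage: bool = True

    def grids(self) -> dict[str, list[MethodConfig]]:
        out = {}
        for family in self.families:
            grid = enumerate_grid(family)
            if self.grid_indices and family in self.grid_indices:
                grid = [grid[i] for i in self.grid_indices[family]]
            elif self.grid_stride:
                grid = grid[:: self.grid_stride]
            out[family] = grid
        return out

    @classmethod
    def smoke(cls, seed: int = 0) -> "RunConfig":
        """Small end-to-end configuration: 60 epochs, 2 configs per family."""
        return cls(
            seed=seed,
            benchmark=BenchmarkConfig(n_eog=20, n_emg=20, n_mixed=20),
            pool_sizes={"eeg": 30, "eog": 20, "emg": 20},
            # cheap, spread-out grid points (CEEMDAN kept at its smallest NR)
            grid_indices={"vmd": [0, 8], "ssa": [4, 15], "dwt": [0, 16], "ceemdan": [0, 10]},
        )


def make_pools(config: RunConfig) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return {
        "eeg": synth_eeg(rng, config.pool_sizes["eeg"]),
        "eog": synth_eog(rng, config.pool_sizes["eog"]),
        "emg": synth_emg(rng, config.pool_sizes["emg"]),
    }


def synthesize(config: RunConfig) -> list[Epoch]:
    """Exemplar pools + mixture benchmark from the run seed."""
    pools = make_pools(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return build_benchmark(pools, config.benchmark, rng)


def evaluate_grid(
    epochs: list[Epoch],
    grids: dict[str, list[MethodConfig]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-epoch oracle results over every (family, config) grid point.

    CEEMDAN noise ensembles are seeded per (epoch, config), so the table is
    reproducible epoch-by-epoch regardless of evaluation order.
    """
    rows = []
    for family, grid in grids.items():
        for gi, cfg in enumerate(grid):
            for ei, epoch in enumerate(epochs):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, _FAMILY_CODE[family], gi, ei])
                )
                cs = timed_decompose(epoch.Y, cfg, rng=rng)
                res = evaluate_epoch(epoch, cs)
                rows.append(
                    {
                        "epoch_id": epoch.epoch_id,
                        "kind": epoch.kind,
                        "bin": assign_bin(epoch),
                        "family": family,
                        "config_label": cfg.label,
                        "rrmse": res.rrmse,
                        "pcc": res.pcc,
                        "t_dec": cs.t_dec,
                        "recon_gap": cs.recon_gap,
                        "baseline_rrmse": noisy_baseline_rrmse(epoch),
                    }
                )
    return pd.DataFrame(rows)


def opt1_per_epoch(results: pd.DataFrame, triples: list[SelectionTriple]) -> pd.DataFrame:
    """Per-epoch rows restricted to each stratum's Opt1 config (per family)."""
    opt1 = {(t.family, t.kind, t.bin): t.opt1.config.label for t in triples}
    mask = results.apply(
        lambda r: opt1.get((r["family"], r["kind"], r["bin"])) == r["config_label"], axis=1
    )
    return results[mask].copy()


def _epoch_meta(epochs: list[Epoch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "epoch_id": e.epoch_id,
                "kind": e.kind,
                "Z_eog": e.Z_eog,
                "Z_emg": e.Z_emg,
                "Z_tot": e.Z_tot,
                "share_r": e.share_r,
                "pattern": e.pattern,
                "bin": assign_bin(e),
                "baseline_rrmse": noisy_baseline_rrmse(e),
            }
            for e in epochs
        ]
    )


def save_epochs(epochs: list[Epoch], out_dir: Path) -> list[Path]:
    """Epoch store: metadata CSV + one CSV matrix per vector field (rows = epochs)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [out_dir / "epochs_meta.csv"]
    _epoch_meta(epochs).to_csv(paths[0], index=False)
    for name, attr in [("Y", "Y"), ("X", "X"), ("N_eog", "N_eog_scaled"), ("N_emg", "N_emg_scaled")]:
        p = out_dir / f"epochs_{name}.csv"
        np.savetxt(p, np.vstack([getattr(e, attr) for e in epochs]), delimiter=",")
        paths.append(p)
    return paths


def load_epochs(out_dir: Path) -> list[Epoch]:
    meta = pd.read_csv(out_dir / "epochs_meta.csv")
    mats = {
        name: np.loadtxt(out_dir / f"epochs_{name}.csv", delimiter=",", ndmin=2)
        for name in ("Y", "X", "N_eog", "N_emg")
    }
    epochs = []
    for i, row in meta.iterrows():
        epochs.append(
            Epoch(
                Y=mats["Y"][i],
                X=mats["X"][i],
                N_eog_scaled=mats["N_eog"][i],
                N_emg_scaled=mats["N_emg"][i],
                Z_eog=row["Z_eog"],
                Z_emg=row["Z_emg"],
                Z_tot=row["Z_tot"],
                kind=row["kind"],
                epoch_id=row["epoch_id"],
                share_r=row["share_r"],
                pattern=None if pd.isna(row["pattern"]) else row["pattern"],
            )
        )
    return epochs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write all reports under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/6: synthesizing benchmark (%d epochs)", config.benchmark.n_total)
    epochs = synthesize(config)
    written = save_epochs(epochs, out_dir / "epochs")

    logger.info("stage 2/6: decomposition + oracle over grids")
    results = evaluate_grid(epochs, config.grids(), seed=config.seed)
    results_path = out_dir / "per_epoch_results.csv"
    results.to_csv(results_path, index=False)
    written.append(results_path)

    logger.info("stage 3/6: Best/Opt1/Opt2 selection")
    triples = run_selection(results, d0=config.d0, vmd_opt2_k_floor=config.vmd_opt2_k_floor)
    sel_path = out_dir / "selection.csv"
    selection_table(triples).to_csv(sel_path, index=False)
    written.append(sel_path)

    if config.shrinkage:
        logger.info("stage 4/6: wavelet-shrinkage baseline")
        shrink = evaluate_baseline(epochs)
        for name, df in [("shrinkage_per_epoch", shrink), ("shrinkage_bins", baseline_bin_table(shrink))]:
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)

    logger.info("stage 5/6: inter-method comparison at bin-wise Opt1")
    rank_tables, paired = run_comparison(opt1_per_epoch(results, triples))
    rank_path = out_dir / "rank_tables.csv"
    rank_report(rank_tables).to_csv(rank_path, index=False)
    paired_path = out_dir / "paired_stats.csv"
    pd.DataFrame([dataclasses.asdict(s) for s in paired]).to_csv(paired_path, index=False)
    written.extend([rank_path, paired_path])

    logger.info("stage 6/6: manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "benchmark": dataclasses.asdict(config.benchmark),
            "pool_sizes": config.pool_sizes,
            "families": list(config.families),
            "grid_stride": config.grid_stride,
            "d0": config.d0,
            "vmd_opt2_k_floor": config.vmd_opt2_k_floor,
        },
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in written},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
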