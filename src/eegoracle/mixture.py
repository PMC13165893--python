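"""Benchmark synthesis: NSR-controlled mixtures of clean EEG with EOG/EMG.

Every benchmark epoch is a linear mixture

    Y = X + lambda_eog * N_eog + lambda_emg * N_emg

where the gains are set so that the noise-to-signal ratio of each active
artifact modality,

    Z = 10 * log10(lambda^2 * mean(N^2) / mean(X^2))   [dB],

hits a target drawn uniformly from [-10, 10] dB.  Mixed epochs draw a total
NSR Z_tot and split its linear power q_tot = 10^(Z_tot/10) between EOG and
EMG via a random ocular share r in [0, 1].  An absent modality is stored as
an exact zero vector with the floor label -10 dB.

The unprocessed baseline error of a single-artifact epoch follows the exact
mapping RRMSE_noisy = 10^(Z/20), which the suite verifies to 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_bank import Exemplar

__all__ = [
    "Epoch",
    "BenchmarkConfig",
    "BIN_LABELS",
    "ALL_BIN",
    "NSR_FLOOR_DB",
    "gain_for_nsr",
    "split_total",
    "sample_share",
    "build_benchmark",
    "assign_bin",
    "noisy_baseline_rrmse",
]

NSR_FLOOR_DB = -10.0
KINDS = ("eog", "emg", "mixed")
SHARE_PATTERNS = ("uniform", "increasing", "decreasing")

# Half-open NSR bins, top bin closed, plus the pooled range.
_BIN_EDGES = (-10.0, -5.0, 0.0, 5.0, 10.0)
BIN_LABELS = ("[-10,-5)", "[-5,0)", "[0,5)", "[5,10]")
ALL_BIN = "ALL"


@dataclass
class Epoch:
    """One noisy 2 s segment with its clean reference and scaled artifact parts."""

    Y: np.ndarray
    X: np.ndarray
    N_eog_scaled: np.ndarray
    N_emg_scaled: np.ndarray
    Z_eog: float
    Z_emg: float
    Z_tot: float
    kind: str
    epoch_id: str
    share_r: float = float("nan")
    pattern: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        for name in ("Y", "X", "N_eog_scaled", "N_emg_scaled"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def T(self) -> int:
        return self.Y.size


@dataclass
class BenchmarkConfig:
    """Design constants of the synthetic benchmark (defaults = study design)."""

    n_eog: int = 1250
    n_emg: int = 1250
    n_mixed: int = 2000
    nsr_low_db: float = -10.0
    nsr_high_db: float = 10.0
    floor_db: float = NSR_FLOOR_DB
    #: if True, the "absent" modality of single-artifact epochs is mixed in at
    #: the floor NSR instead of being exactly zero.
    floor_active: bool = False

    @property
    def n_total(self) -> int:
        return self.n_eog + self.n_emg + self.n_mixed


def gain_for_nsr(Z_db: float, X: np.ndarray, N: np.ndarray) -> float:
    """Gain lambda such that mixing ``lambda * N`` into ``X`` yields NSR ``Z_db``."""
    px = float(np.mean(np.asarray(X, dtype=float) ** 2))
    pn = float(np.mean(np.asarray(N, dtype=float) ** 2))
    if px <= 0:
        raise ValueError("clean reference has zero power")
    if pn <= 0:
        raise ValueError("artifact exemplar has zero power")
    return float(np.sqrt(10.0 ** (Z_db / 10.0) * px / pn))


def split_total(Z_tot_db: float, r: float) -> tuple[float, float]:
    """Split total linear NSR power ``q_tot = 10^(Z_tot/10)`` by ocular share ``r``."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"share r must lie in [0, 1], got {r}")
    q_tot = 10.0 ** (Z_tot_db / 10.0)
    return r * q_tot, (1.0 - r) * q_tot


def sample_share(pattern: str, Z_tot_db: float, rng: np.random.Generator) -> float:
    """Draw an ocular share r in [0, 1].

    ``uniform`` draws U(0,1); ``increasing`` draws Beta(1+4*z, 1+4*(1-z)) with
    z = (Z_tot+10)/20 so the expected share grows with total NSR;
    ``decreasing`` mirrors it (z -> 1-z).
    """
    if pattern not in SHARE_PATTERNS:
        raise ValueError(f"unknown share pattern {pattern!r}; expected one of {SHARE_PATTERNS}")
    if pattern == "uniform":
        return float(rng.uniform())
    z = (Z_tot_db + 10.0) / 20.0
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"Z_tot={Z_tot_db} dB outside [-10, 10]")
    if pattern == "decreasing":
        z = 1.0 - z
    return float(rng.beta(1.0 + 4.0 * z, 1.0 + 4.0 * (1.0 - z)))


def _measured_nsr_db(scaled_N: np.ndarray, X: np.ndarray) -> float:
    return 10.0 * np.log10(np.mean(scaled_N**2) / np.mean(X**2))


def _pick(pool: list[Exemplar], rng: np.random.Generator) -> np.ndarray:
    return pool[int(rng.integers(len(pool)))].samples


def build_benchmark(
    pools: dict[str, list[Exemplar]],
    config: BenchmarkConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[Epoch]:
    """Build the full benchmark (default 1250 EOG + 1250 EMG + 2000 mixed epochs).

    Exemplars are drawn with replacement, independently for the clean reference
    and each artifact.  Mixed epochs are allocated as evenly as possible to the
    three share patterns (667/667/666 for the default 2000).
    """
    config = config or BenchmarkConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    for cls in ("eeg", "eog", "emg"):
        needed = {"eeg": True, "eog": config.n_eog + config.n_mixed > 0,
                  "emg": config.n_emg + config.n_mixed > 0}[cls]
        if needed and not pools.get(cls):
            raise ValueError(f"empty exemplar pool for class {cls!r}")

    epochs: list[Epoch] = []
    counter = 0

    def single(kind: str, n: int) -> None:
        nonlocal counter
        art_cls = kind
        other_cls = "emg" if kind == "eog" else "eog"
        for _ in range(n):
            X = _pick(pools["eeg"], rng)
            N = _pick(pools[art_cls], rng)
            Z = float(rng.uniform(config.nsr_low_db, config.nsr_high_db))
            scaled = gain_for_nsr(Z, X, N) * N
            if config.floor_active:
                N_other = _pick(pools[other_cls], rng)
                other_scaled = gain_for_nsr(config.floor_db, X, N_other) * N_other
            else:
                other_scaled = np.zeros_like(X)
            parts = {art_cls: scaled, other_cls: other_scaled}
            z_labels = {art_cls: Z, other_cls: config.floor_db}
            epochs.append(
                Epoch(
                    Y=X + parts["eog"] + parts["emg"],
                    X=X,
                    N_eog_scaled=parts["eog"],
                    N_emg_scaled=parts["emg"],
                    Z_eog=z_labels["eog"],
                    Z_emg=z_labels["emg"],
                    Z_tot=Z,
                    kind=kind,
                    epoch_id=f"ep-{counter:05d}",
                )
            )
            counter += 1

    single("eog", config.n_eog)
    single("emg", config.n_emg)

    base, rem = divmod(config.n_mixed, len(SHARE_PATTERNS))
    pattern_counts = [base + (1 if i < rem else 0) for i in range(len(SHARE_PATTERNS))]
    for pattern, n_pat in zip(SHARE_PATTERNS, pattern_counts):
        for _ in range(n_pat):
            X = _pick(pools["eeg"], rng)
            N_eog = _pick(pools["eog"], rng)
            N_emg = _pick(pools["emg"], rng)
            Z_tot = float(rng.uniform(config.nsr_low_db, config.nsr_high_db))
            r = sample_share(pattern, Z_tot, rng)
            q_eog, q_emg = split_total(Z_tot, r)
            px = np.mean(X**2)
            eog_scaled = (np.sqrt(q_eog * px / np.mean(N_eog**2)) * N_eog
                          if q_eog > 0 else np.zeros_like(X))
            emg_scaled = (np.sqrt(q_emg * px / np.mean(N_emg**2)) * N_emg
                          if q_emg > 0 else np.zeros_like(X))
            epochs.append(
                Epoch(
                    Y=X + eog_scaled + emg_scaled,
                    X=X,
                    N_eog_scaled=eog_scaled,
                    N_emg_scaled=emg_scaled,
                    Z_eog=10.0 * np.log10(q_eog) if q_eog > 0 else config.floor_db,
                    Z_emg=10.0 * np.log10(q_emg) if q_emg > 0 else config.floor_db,
                    Z_tot=Z_tot,
                    kind="mixed",
                    epoch_id=f"ep-{counter:05d}",
                    share_r=r,
                    pattern=pattern,
                )
            )
            counter += 1
    return epochs


def binning_axis(epoch: Epoch) -> float:
    """The NSR label an epoch is binned on: Z_eog / Z_emg / Z_tot by kind."""
    return {"eog": epoch.Z_eog, "emg": epoch.Z_emg, "mixed": epoch.Z_tot}[epoch.kind]


def assign_bin(epoch: Epoch) -> str:
    """Deterministic NSR bin label from the kind-appropriate Z axis."""
    z = binning_axis(epoch)
    if not _BIN_EDGES[0] <= z <= _BIN_EDGES[-1]:
        raise ValueError(f"NSR {z} dB outside the benchmark range [-10, 10]")
    for lo, hi, label in zip(_BIN_EDGES[:-1], _BIN_EDGES[1:], BIN_LABELS):
        if lo <= z < hi:
            return label
    return BIN_LABELS[-1]  # z == 10 exactly: top bin is closed


def noisy_baseline_rrmse(epoch: Epoch) -> float:
    """Relative error of the unprocessed observation: ||X - Y|| / ||X||."""
    nx = np.linalg.norm(epoch.X)
    if nx == 0:
        raise ValueError("clean reference has zero norm")
    return float(np.linalg.norm(epoch.X - epoch.Y) / nx)
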