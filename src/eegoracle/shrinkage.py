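"""Practical wavelet-shrinkage baseline: depth-6 DWT, universal soft threshold.

Unlike the oracle, this is a deployable denoiser: it never sees the clean
reference.  The epoch is decomposed to depth 6, every detail sub-band
(levels 1-6) is soft-thresholded with the single universal threshold

    t = sigma_hat * sqrt(2 * ln N),     sigma_hat = MAD(d1) / 0.6745,

where d1 are the finest-scale detail coefficients and N the signal length,
and the approximation band passes through untouched.  The same RRMSE/PCC
metrics as the oracle quantify how much of the oracle's headroom a standard
selector realizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .mixture import Epoch, assign_bin
from .oracle import pcc as _pcc
from .oracle import rrmse as _rrmse

__all__ = [
    "ShrinkageConfig",
    "universal_threshold",
    "soft_threshold",
    "shrink_denoise",
    "evaluate_baseline",
    "SHRINKAGE_WAVELETS",
]

SHRINKAGE_WAVELETS = ("sym4", "db4", "coif3")
_MAD_TO_SIGMA = 0.6745  # Gaussian consistency constant


@dataclass(frozen=True)
class ShrinkageConfig:
    wName: str = "sym4"
    level: int = 6
    #: estimate sigma per detail level instead of once from the finest level
    per_level_sigma: bool = False

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("shrinkage level must be >= 1")


def _wavedec(y: np.ndarray, wName: str, level: int) -> list[np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(y, pywt.Wavelet(wName), mode="periodization", level=level)


def universal_threshold(y: np.ndarray, wName: str, level: int = 6) -> float:
    """sigma_hat * sqrt(2 ln N) with sigma_hat from the finest detail band."""
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("signal too short for thresholding")
    d1 = _wavedec(y, wName, level)[-1]
    sigma = float(np.median(np.abs(d1))) / _MAD_TO_SIGMA
    return sigma * np.sqrt(2.0 * np.log(y.size))


def soft_threshold(coeffs: np.ndarray, t: float) -> np.ndarray:
    """sign(c) * max(|c| - t, 0), elementwise."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    c = np.asarray(coeffs, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - t, 0.0)


def shrink_denoise(
    Y: np.ndarray,
    config: ShrinkageConfig = ShrinkageConfig(),
    threshold: float | None = None,
) -> np.ndarray:
    """Soft-threshold all detail levels, keep the approximation, invert.

    ``threshold`` overrides the universal rule (0 makes the transform an
    identity up to reconstruction round-off).
    """
    Y = np.asarray(Y, dtype=float)
    coeffs = _wavedec(Y, config.wName, config.level)
    approx, details = coeffs[0], coeffs[1:]
    if threshold is not None:
        out_details = [soft_threshold(d, threshold) for d in details]
    elif config.per_level_sigma:
        out_details = [
            soft_threshold(
                d, float(np.median(np.abs(d))) / _MAD_TO_SIGMA * np.sqrt(2.0 * np.log(Y.size))
            )
            for d in details
        ]
    else:
        t = universal_threshold(Y, config.wName, config.level)
        out_details = [soft_threshold(d, t) for d in details]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.waverec([approx] + out_details, pywt.Wavelet(config.wName), mode="periodization")
    return rec[: Y.size]


def evaluate_baseline(
    epochs: list[Epoch],
    wavelets: tuple[str, ...] = SHRINKAGE_WAVELETS,
    level: int = 6,
) -> pd.DataFrame:
    """Per-epoch, per-wavelet shrinkage RRMSE/PCC table (with NSR bin labels)."""
    rows = []
    for epoch in epochs:
        bin_ = assign_bin(epoch)
        for wName in wavelets:
            x_hat = shrink_denoise(epoch.Y, ShrinkageConfig(wName=wName, level=level))
            rows.append(
                {
                    "epoch_id": epoch.epoch_id,
                    "kind": epoch.kind,
                    "bin": bin_,
                    "wavelet": wName,
                    "rrmse": _rrmse(epoch.X, x_hat),
                    "pcc": _pcc(epoch.X, x_hat),
                }
            )
    return pd.DataFrame(rows)


def baseline_bin_table(per_epoch: pd.DataFrame) -> pd.DataFrame:
    """Bin-wise mean RRMSE/PCC per wavelet plus the best-by-RRMSE wavelet."""
    grouped = (
        per_epoch.groupby(["kind", "bin", "wavelet"])
        .agg(n=("rrmse", "size"), mean_rrmse=("rrmse", "mean"), mean_pcc=("pcc", "mean"))
        .reset_index()
    )
    best = (
        grouped.loc[grouped.groupby(["kind", "bin"])["mean_rrmse"].idxmin()]
        .rename(columns={"wavelet": "best_wavelet"})[["kind", "bin", "best_wavelet"]]
    )
    return grouped.merge(best, on=["kind", "bin"])
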