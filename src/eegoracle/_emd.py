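"""Empirical mode decomposition and its noise-assisted ensemble variant.

``emd`` sifts a signal into intrinsic mode functions (IMFs) using cubic-spline
upper/lower envelopes through the local extrema, with mirrored boundary
extrema and a Cauchy-type stopping criterion on successive sift iterates.

``ceemdan`` implements the complete-ensemble scheme with adaptive noise: at
every stage the first IMF is extracted from the current residual perturbed by
a scaled IMF of white-noise realizations, and the stage IMF is the ensemble
mean.  Because each residual is defined by exact subtraction of the stage
IMF, the decomposition satisfies  x = sum(IMFs) + final residual  to machine
precision regardless of ensemble size.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["emd", "ceemdan"]

_SD_TOL = 0.2
_MAX_SIFT = 12


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapse)."""
    d = np.diff(x)
    # replace exact zeros in the slope with the previous nonzero sign
    s = np.sign(d)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.diff(s)
    idx = np.nonzero(turn)[0] + 1
    maxima = idx[turn[idx - 1] < 0]
    minima = idx[turn[idx - 1] > 0]
    return maxima, minima


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the cubic-spline extrema envelopes, or None if too few extrema."""
    n = x.size
    maxima, minima = _extrema(x)
    if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 3:
        return None

    t = np.arange(n, dtype=float)

    def _extend(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # mirror up to two extrema across each endpoint
        k = min(2, idx.size)
        left_t = -idx[:k][::-1].astype(float)
        right_t = 2.0 * (n - 1) - idx[-k:][::-1].astype(float)
        tt = np.concatenate([left_t, idx.astype(float), right_t])
        vv = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
        # mirrored knots can coincide with originals when an extremum sits at
        # the boundary; keep strictly increasing knots only
        keep = np.concatenate([[True], np.diff(tt) > 0])
        return tt[keep], vv[keep]

    tmax, vmax = _extend(maxima)
    tmin, vmin = _extend(minima)
    if tmax.size < 2 or tmin.size < 2:
        return None
    upper = CubicSpline(tmax, vmax, bc_type="natural")(t)
    lower = CubicSpline(tmin, vmin, bc_type="natural")(t)
    return 0.5 * (upper + lower)


def _sift(x: np.ndarray, max_sift: int = _MAX_SIFT, sd_tol: float = _SD_TOL) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when ``x`` carries no oscillation."""
    h = x
    for _ in range(max_sift):
        m = _envelope_mean(h)
        if m is None:
            return None if h is x else h
        h_new = h - m
        denom = float(np.sum(h**2))
        if denom > 0 and float(np.sum((h_new - h) ** 2)) / denom < sd_tol:
            return h_new
        h = h_new
    return h


def emd(x: np.ndarray, max_imf: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``x`` into up to ``max_imf`` IMFs plus the final residual."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("signal too short for sifting")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imf:
        imf = _sift(residual)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
        mx, mn = _extrema(residual)
        if mx.size + mn.size < 3:
            break
    return imfs, residual


def ceemdan(
    x: np.ndarray,
    nstd: float,
    nr: int,
    max_imf: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Complete-ensemble EMD with adaptive noise.

    Parameters
    ----------
    nstd : relative amplitude of the added white noise (fraction of the
        current residual's standard deviation; stage 0 uses the signal's).
    nr : number of noise realizations averaged per stage.
    max_imf : cap on the number of extracted IMFs.

    Returns a (K_eff x T) array of IMFs with the final residual as the last
    row, summing to ``x`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if nstd <= 0:
        raise ValueError("nstd must be > 0")
    if nr < 1 or max_imf < 1:
        raise ValueError("nr and max_imf must be >= 1")
    scale = float(np.std(x))
    if scale == 0:
        raise ValueError("constant signal has no oscillatory content")
    s = x / scale

    noise = [rng.standard_normal(x.size) for _ in range(nr)]
    noise_imfs = [emd(w, max_imf)[0] for w in noise]

    imfs: list[np.ndarray] = []
    residual = s.copy()
    while len(imfs) < max_imf:
        stage = len(imfs)
        beta = nstd * float(np.std(residual))
        acc = np.zeros_like(s)
        used = 0
        for w, w_imfs in zip(noise, noise_imfs):
            if stage == 0:
                perturbed = residual + nstd * w
            else:
                if stage - 1 >= len(w_imfs):
                    continue  # this realization's noise has no IMF at this depth
                perturbed = residual + beta * w_imfs[stage - 1]
            imf = _sift(perturbed)
            if imf is None:
                continue
            acc += imf
            used += 1
        if used == 0:
            break
        imfs.append(acc / used)
        residual = residual - imfs[-1]
        mx, mn = _extrema(residual)
        if mx.size + mn.size < 3:
            break

    components = np.vstack(imfs + [residual]) if imfs else residual[None, :]
    return components * scale
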