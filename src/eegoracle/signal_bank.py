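"""Exemplar epochs: clean EEG, ocular (EOG) and myogenic (EMG) activity.

The benchmark operates on 2 s single-channel epochs at 125 Hz (T = 250
samples).  Exemplars come either from the package's own parameterized
surrogate generators, or from an external numeric-array container such as
the EEGdenoiseNet dataset (2 s epochs at 256 Hz, one epoch per row).

Surrogate generators encode spectral *contracts*, not physiological claims:

* clean EEG  — 1/f-shaped background plus 1-3 narrowband oscillations with
  center frequencies in the 4-30 Hz range;
* EOG        — 1-2 smooth blink-like raised-cosine transients of 200-400 ms
  plus slow drift, so that spectral power concentrates below 8 Hz;
* EMG        — band-passed Gaussian noise (~15-60 Hz) with amplitude-
  modulated bursts, so that spectral power concentrates above 15 Hz.

All exemplars are normalized to unit mean power; mixture gains downstream
fully determine relative power, so exemplar scale is a free choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "Exemplar",
    "resample_epoch",
    "load_dataset_exemplars",
    "synth_eeg",
    "synth_eog",
    "synth_emg",
    "FS_DEFAULT",
    "DURATION_DEFAULT",
    "T_DEFAULT",
]

FS_DEFAULT = 125.0
DURATION_DEFAULT = 2.0
T_DEFAULT = 250

_CLASSES = ("eeg", "eog", "emg")
_SOURCES = ("synthetic", "dataset")


@dataclass(frozen=True)
class Exemplar:
    """One single-channel epoch with class and provenance labels."""

    samples: np.ndarray
    fs: float
    cls: str
    id: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError(f"exemplar samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"exemplar {self.id!r} contains non-finite samples")
        if self.cls not in _CLASSES:
            raise ValueError(f"cls must be one of {_CLASSES}, got {self.cls!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}, got {self.source!r}")
        if float(np.mean(samples**2)) <= 0.0:
            raise ValueError(f"exemplar {self.id!r} has zero mean power (degenerate)")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def mean_power(self) -> float:
        return float(np.mean(self.samples**2))


def resample_epoch(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample ``x`` from ``fs_in`` to ``fs_out`` with polyphase FIR anti-aliasing.

    The rational ratio fs_out/fs_in is resolved exactly (e.g. 125/256), so a
    512-sample epoch at 256 Hz becomes exactly 250 samples at 125 Hz.  Equal
    rates return the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("resample_epoch expects a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("resample_epoch: input contains non-finite values")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    y = sps.resample_poly(x, up, down)
    n_expected = int(round(x.size * fs_out / fs_in))
    if y.size != n_expected:  # resample_poly uses ceil; trim/pad defensively
        y = y[:n_expected] if y.size > n_expected else np.pad(y, (0, n_expected - y.size))
    return y


def _load_matrix(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path)
    if suffix in (".csv", ".txt"):
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    if suffix == ".mat":
        try:
            from scipy.io import loadmat

            mat = loadmat(path)
            arrays = {k: v for k, v in mat.items() if not k.startswith("__")}
        except NotImplementedError:  # MAT v7.3 is an HDF5 container
            import h5py

            with h5py.File(path, "r") as f:
                arrays = {k: np.asarray(f[k]) for k in f.keys()}
        if len(arrays) != 1:
            raise ValueError(
                f"{path}: expected exactly one data variable, found {sorted(arrays)}"
            )
        return np.asarray(next(iter(arrays.values())))
    raise ValueError(f"{path}: unsupported container (expected .mat, .npy or .csv)")


def load_dataset_exemplars(
    path: str | Path,
    cls: str,
    fs_in: float = 256.0,
    fs_out: float = FS_DEFAULT,
) -> list[Exemplar]:
    """Load dataset epochs (rows of an ``n_epochs x n_samples`` matrix).

    Supports MAT (v5 and v7.3/HDF5), NPY and CSV containers; every row is
    resampled to ``fs_out`` and wrapped as a dataset-sourced :class:`Exemplar`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset container not found: {path}")
    data = _load_matrix(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a 2-D (n_epochs x n_samples) matrix, got shape {data.shape}"
        )
    exemplars = []
    for i, row in enumerate(np.asarray(data, dtype=float)):
        samples = resample_epoch(row, fs_in, fs_out)
        exemplars.append(
            Exemplar(samples=samples, fs=fs_out, cls=cls, id=f"{cls}-ds-{i:05d}", source="dataset")
        )
    return exemplars


def _normalize_power(x: np.ndarray) -> np.ndarray:
    power = np.mean(x**2)
    if power <= 0:
        raise ValueError("cannot normalize a zero-power epoch")
    return x / np.sqrt(power)


def _one_over_f_background(rng: np.random.Generator, n: int, fs: float, exponent: float = 1.0) -> np.ndarray:
    """Gaussian background with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spectrum[0] = 0.0
    return np.fft.irfft(spectrum, n=n)


def synth_eeg(
    rng: np.random.Generator,
    n: int,
    fs: float = FS_DEFAULT,
    duration_s: float = DURATION_DEFAULT,
) -> list[Exemplar]:
    """Generate ``n`` clean-EEG-like surrogate epochs, unit mean power each."""
    if n < 1:
        raise ValueError("n must be >= 1")
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    out = []
    for i in range(n):
        x = _one_over_f_background(rng, n_samples, fs)
        x = _normalize_power(x)
        n_osc = int(rng.integers(1, 4))
        for _ in range(n_osc):
            f0 = rng.uniform(4.0, 30.0)
            amp = rng.uniform(0.4, 1.2)
            phase = rng.uniform(0.0, 2 * np.pi)
            x = x + amp * np.sin(2 * np.pi * f0 * t + phase)
        out.append(
            Exemplar(samples=_normalize_power(x), fs=fs, cls="eeg", id=f"eeg-syn-{i:05d}")
        )
    return out


def _raised_cosine_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Hann-shaped bump of total duration ``width`` seconds centered at ``center``."""
    arg = (t - center) / width
    bump = np.where(np.abs(arg) <= 0.5, 0.5 * (1.0 + np.cos(2 * np.pi * arg)), 0.0)
    return bump


def synth_eog(
    rng: np.random.Generator,
    n: int,
    fs: float = FS_DEFAULT,
    duration_s: float = DURATION_DEFAULT,
    bump_width_range: tuple[float, float] = (0.2, 0.4),
) -> list[Exemplar]:
    """Generate blink-like ocular epochs: 1-2 smooth transients plus slow drift.

    Ensemble contract: spectral power is dominated by the sub-8 Hz band.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = bump_width_range
    if lo <= 0 or hi < lo:
        raise ValueError("bump widths must be positive with lo <= hi")
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    out = []
    for i in range(n):
        x = np.zeros(n_samples)
        n_bumps = int(rng.integers(1, 3))
        for _ in range(n_bumps):
            width = rng.uniform(lo, hi)
            center = rng.uniform(0.6 * width, duration_s - 0.6 * width)
            polarity = rng.choice([-1.0, 1.0])
            amp = rng.uniform(0.8, 1.5)
            x = x + polarity * amp * _raised_cosine_bump(t, center, width)
        # slow drift well below the blink band
        f_drift = rng.uniform(0.3, 1.2)
        x = x + rng.uniform(0.1, 0.3) * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        out.append(
            Exemplar(samples=_normalize_power(x), fs=fs, cls="eog", id=f"eog-syn-{i:05d}")
        )
    return out


def synth_emg(
    rng: np.random.Generator,
    n: int,
    fs: float = FS_DEFAULT,
    duration_s: float = DURATION_DEFAULT,
    passband_hz: tuple[float, float] = (15.0, 60.0),
) -> list[Exemplar]:
    """Generate broadband myogenic epochs: band-passed noise with burst envelopes.

    Ensemble contract: spectral centroid above 20 Hz.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    nyq = fs / 2.0
    lo, hi = passband_hz
    sos = sps.butter(4, [lo / nyq, min(hi, 0.98 * nyq) / nyq], btype="bandpass", output="sos")
    out = []
    for i in range(n):
        noise = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        envelope = np.full(n_samples, 0.3)
        n_bursts = int(rng.integers(1, 4))
        for _ in range(n_bursts):
            width = rng.uniform(0.2, 0.6)
            center = rng.uniform(0.3 * width, duration_s - 0.3 * width)
            envelope = envelope + rng.uniform(0.8, 1.6) * _raised_cosine_bump(t, center, width)
        out.append(
            Exemplar(samples=_normalize_power(noise * envelope), fs=fs, cls="emg", id=f"emg-syn-{i:05d}")
        )
    return out
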