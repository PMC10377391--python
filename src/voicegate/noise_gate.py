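"""Spectral noise gate: per-bin statistics, threshold, mask, smoothing.

The gate distinguishes signal from noise cell-by-cell in the dB
magnitude spectrogram.  For every frequency bin the mean and standard
deviation of the magnitude over time are computed; the gate threshold
for that bin is ``mean + n_std * std`` where ``n_std`` is the exposed
noise-sensitivity knob.  Cells strictly above their bin threshold are
flagged as signal (1), everything else as noise (0).  The binary mask is
then smoothed with a separable unit-sum triangular kernel across both
frequency and time to avoid abrupt gain jumps, and applied as a soft
gain to the complex spectrogram (phase untouched).

Noise statistics are estimated from the clip itself by default; a
separate noise-profile clip may be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .spectral import Spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyStats",
    "NoiseMask",
    "select_noise_frames",
    "frequency_statistics",
    "compute_mask",
    "smooth_mask",
    "apply_mask",
]


@dataclass
class FrequencyStats:
    """Per-bin magnitude statistics and the derived gate threshold (dB)."""

    mean_db: np.ndarray
    std_db: np.ndarray
    threshold_db: np.ndarray
    n_std: float

    def __post_init__(self) -> None:
        if np.any(self.std_db < 0):
            raise ValueError("std_db must be non-negative")
        if not np.allclose(self.threshold_db, self.mean_db + self.n_std * self.std_db):
            raise ValueError("threshold_db must equal mean_db + n_std * std_db")


@dataclass
class NoiseMask:
    """Binary noise-to-signal mask (1 = signal, 0 = noise) and its smoothed form."""

    binary: np.ndarray
    smoothed: np.ndarray | None = None
    smoothing_kernel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.binary)
        if not np.isin(b, (0.0, 1.0)).all():
            raise ValueError("binary mask entries must be 0 or 1")
        if self.smoothed is not None:
            s = np.asarray(self.smoothed)
            if s.shape != b.shape:
                raise ValueError("smoothed mask shape mismatch")
            if s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValueError("smoothed mask must lie in [0, 1]")


def select_noise_frames(s: Spectrogram, quantile: float = 0.2) -> np.ndarray:
    """Indices of the noise-dominated (quietest) frames of a spectrogram.

    The gate needs noise statistics.  Without a separate noise-profile
    clip they are estimated from the clip itself: frames whose broadband
    energy falls at or below the given quantile of per-frame energies —
    the inter-word pauses and breaks of running speech — are taken as
    the noise profile.  At least one frame is always returned.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    energy = (np.abs(s.values) ** 2).sum(axis=0)
    cutoff = np.quantile(energy, quantile)
    idx = np.flatnonzero(energy <= cutoff)
    if idx.size == 0:  # pragma: no cover - quantile guarantees nonempty
        idx = np.array([int(np.argmin(energy))])
    return idx


def frequency_statistics(D: np.ndarray, n_std: float = 1.5) -> FrequencyStats:
    """Mean / population-std of each frequency bin over time, plus threshold.

    Parameters
    ----------
    D : ndarray (bins x frames)
        dB magnitude matrix, finite.
    n_std : float
        Sensitivity multiplier; the per-bin threshold is
        ``mean + n_std * std``.
    """
    D = np.asarray(D, dtype=np.float64)
    if not np.all(np.isfinite(D)):
        raise ValueError("dB matrix contains non-finite values")
    if n_std < 0:
        raise ValueError("n_std must be >= 0")
    if D.shape[1] == 1:
        logger.warning("single-frame spectrogram: per-bin std defined as 0")
    mean = D.mean(axis=1)
    std = D.std(axis=1)  # population std (ddof=0); 0 for single frame
    return FrequencyStats(mean, std, mean + n_std * std, n_std)


def compute_mask(D: np.ndarray, fs: FrequencyStats) -> NoiseMask:
    """Binary noise-to-signal mask: 1 where D strictly exceeds the threshold.

    Ties go to noise, which makes the all-constant spectrogram (std = 0,
    every cell equal to its threshold) deterministically all-noise.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.shape[0] != fs.threshold_db.shape[0]:
        raise ValueError("bin count mismatch between matrix and statistics")
    binary = (D > fs.threshold_db[:, None]).astype(np.float64)
    return NoiseMask(binary=binary)


def _triangular(n: int) -> np.ndarray:
    """Symmetric triangular ramp of length 2n-1: 1, 2, ..., n, ..., 2, 1."""
    return np.concatenate([np.arange(1, n + 1), np.arange(n - 1, 0, -1)]).astype(float)


def smoothing_kernel(n_freq: int, n_time: int) -> np.ndarray:
    """Separable unit-sum triangular kernel of extents (n_freq, n_time)."""
    k = np.outer(_triangular(n_freq), _triangular(n_time))
    return k / k.sum()


def smooth_mask(m: NoiseMask, n_freq: int = 4, n_time: int = 8) -> NoiseMask:
    """Smooth the binary mask with a 2-D triangular filter ("same" size, zero pad).

    The kernel has unit sum, so interior plateaus of the binary mask are
    preserved exactly and all outputs stay within [0, 1].
    """
    if n_freq < 1 or n_time < 1:
        raise ValueError("kernel extents must be >= 1")
    kern = smoothing_kernel(n_freq, n_time)
    if kern.shape[0] > m.binary.shape[0] or kern.shape[1] > m.binary.shape[1]:
        raise ValueError(
            f"smoothing kernel {kern.shape} larger than mask {m.binary.shape}"
        )
    sm = convolve2d(m.binary, kern, mode="same", boundary="fill")
    sm = np.clip(sm, 0.0, 1.0)  # guard accumulation round-off
    return NoiseMask(binary=m.binary, smoothed=sm, smoothing_kernel=(n_freq, n_time))


def apply_mask(
    s: Spectrogram, m: NoiseMask, prop_decrease: float = 1.0
) -> Spectrogram:
    """Attenuate noise cells of a complex spectrogram by the smoothed mask.

    The gain is ``1 - prop_decrease * (1 - smoothed)``: pure-noise cells
    (smoothed = 0) are scaled by ``1 - prop_decrease`` and pure-signal
    cells pass unchanged.  Phase is preserved; the gate never amplifies.
    """
    if not 0.0 <= prop_decrease <= 1.0:
        raise ValueError("prop_decrease must be in [0, 1]")
    if m.smoothed is None:
        raise ValueError("mask has not been smoothed; call smooth_mask first")
    if m.smoothed.shape != s.values.shape:
        raise ValueError("mask / spectrogram shape mismatch")
    gain = 1.0 - prop_decrease * (1.0 - m.smoothed)
    return s.with_values(s.values * gain, role_tag="modified")
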