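"""STFT analysis and inverse-STFT synthesis.

The enhancement pipeline works on a one-sided complex spectrogram of the
voice clip.  Analysis uses a Hann window of 2048 samples with a hop of
512 (46 ms / 75 % overlap at 44.1 kHz — a standard speech setting) and
centered reflect padding so that frame ``t`` is centered on sample
``t * hop``.  Synthesis is weighted overlap-add with squared-window
normalization, which is a perfect-reconstruction inverse for any window
satisfying the constant-overlap-add (COLA) condition at the chosen hop.
Phase is carried end-to-end: masking and magnitude substitution modify
only magnitudes and the original phase is reused at inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import get_window

from .audio_io import Waveform

__all__ = ["StftConfig", "Spectrogram", "stft", "istft", "magnitude_db"]


@dataclass(frozen=True)
class StftConfig:
    """Analysis/synthesis parameters for the short-time Fourier transform."""

    window_length: int = 2048
    hop_length: int = 512
    window_kind: str = "hann"
    center_padding: bool = True

    @property
    def fft_length(self) -> int:
        return self.window_length

    @property
    def n_bins(self) -> int:
        return self.fft_length // 2 + 1

    def __post_init__(self) -> None:
        if not (0 < self.hop_length <= self.window_length):
            raise ValueError("require 0 < hop_length <= window_length")

    def window(self) -> np.ndarray:
        # periodic (fftbins) variant: the one that satisfies COLA
        return get_window(self.window_kind, self.window_length, fftbins=True)

    def check_cola(self, tol: float = 1e-10) -> None:
        """Raise unless the squared window overlap-adds to a constant.

        Flatness of sum_m w^2(n - m*hop) away from the edges is the
        condition under which the squared-window overlap-add inverse is
        exact.
        """
        w2 = self.window() ** 2
        n_shifts = 8 * (self.window_length // self.hop_length)
        total = np.zeros(self.window_length + n_shifts * self.hop_length)
        for m in range(n_shifts + 1):
            start = m * self.hop_length
            total[start : start + self.window_length] += w2
        interior = total[self.window_length : -self.window_length]
        if interior.size == 0 or np.ptp(interior) > tol * np.max(interior):
            raise ValueError(
                f"window {self.window_kind!r} (len {self.window_length}) does not "
                f"satisfy COLA at hop {self.hop_length}"
            )


@dataclass
class Spectrogram:
    """One-sided complex time-frequency matrix with its analysis parameters.

    ``role_tag`` tracks the pipeline stage the matrix represents:
    ``raw`` (analysis output), ``signal`` (the gate's input), ``modified``
    (after mask application) or ``clean`` (after NMF reconstruction).
    """

    values: np.ndarray
    config: StftConfig
    sample_rate: int
    role_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be 2-D (bins x frames)")
        if self.values.shape[0] != self.config.n_bins:
            raise ValueError(
                f"expected {self.config.n_bins} bins, got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite entries")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, role_tag: str) -> "Spectrogram":
        return Spectrogram(values, self.config, self.sample_rate, role_tag)


def _frame_starts(n_padded: int, cfg: StftConfig) -> np.ndarray:
    n_frames = 1 + (n_padded - cfg.window_length) // cfg.hop_length
    return np.arange(n_frames) * cfg.hop_length


def _pad(x: np.ndarray, cfg: StftConfig) -> np.ndarray:
    half = cfg.window_length // 2
    if cfg.center_padding:
        if x.size < 2:
            # reflect padding needs >= 2 samples; fall back to edge values
            x = np.pad(x, (half, half), mode="edge")
        else:
            x = np.pad(x, (half, half), mode="reflect")
    # right-pad with zeros so an integer number of frames covers the tail
    n_frames = int(np.ceil(max(x.size - cfg.window_length, 0) / cfg.hop_length)) + 1
    need = (n_frames - 1) * cfg.hop_length + cfg.window_length
    if need > x.size:
        x = np.pad(x, (0, need - x.size))
    return x


def stft(w: Waveform, cfg: StftConfig | None = None) -> Spectrogram:
    """One-sided STFT of a waveform.

    With ``center_padding`` (the default) the clip is reflect-padded by
    half a window on each side so frame ``t`` is centered on sample
    ``t * hop``; frame count is ``1 + floor(len / hop)``.

    Raises
    ------
    ValueError
        If the (padded) signal is shorter than one window.
    """
    cfg = cfg or StftConfig()
    if not cfg.center_padding and len(w) < cfg.window_length:
        raise ValueError(
            f"input of {len(w)} samples too short for window {cfg.window_length}"
        )
    x = _pad(w.samples, cfg)
    starts = _frame_starts(x.size, cfg)
    win = cfg.window()
    frames = np.stack([x[s : s + cfg.window_length] for s in starts])
    spec = sp_fft.rfft(frames * win, n=cfg.fft_length, axis=1).T
    return Spectrogram(spec, cfg, w.sample_rate, role_tag="raw")


def istft(s: Spectrogram, length: int) -> Waveform:
    """Invert a spectrogram by weighted overlap-add.

    Each frame is inverse-transformed, re-windowed, overlap-added, and
    the result divided by the overlap-added squared window — exact for
    COLA-compliant configurations.  The output is truncated or
    zero-padded to ``length`` samples.

    Raises
    ------
    ValueError
        If the configuration does not satisfy COLA.
    """
    cfg = s.config
    cfg.check_cola()
    win = cfg.window()
    frames = sp_fft.irfft(s.values.T, n=cfg.fft_length, axis=1)
    n_padded = (s.n_frames - 1) * cfg.hop_length + cfg.window_length
    num = np.zeros(n_padded)
    den = np.zeros(n_padded)
    for i in range(s.n_frames):
        start = i * cfg.hop_length
        num[start : start + cfg.window_length] += frames[i] * win
        den[start : start + cfg.window_length] += win**2
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    half = cfg.window_length // 2 if cfg.center_padding else 0
    out = out[half:]
    if out.size >= length:
        out = out[:length]
    else:
        out = np.pad(out, (0, length - out.size))
    return Waveform(out, s.sample_rate)


def magnitude_db(s: Spectrogram, floor_eps: float = 1e-10) -> np.ndarray:
    """Magnitude spectrogram in decibels: ``20 log10(|S| + floor_eps)``.

    The additive floor keeps exact zeros finite (0 -> -200 dB at the
    default floor).
    """
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    return 20.0 * np.log10(np.abs(s.values) + floor_eps)
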