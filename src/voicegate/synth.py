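"""Synthetic alaryngeal-like speech fixtures with a clean reference.

Substitution voicing (esophageal / tracheoesophageal) is marked by
aperiodicity, involuntary phonatory breaks and additive noise.  Real
recordings cannot provide a clean ground truth, so this module builds a
source-filter surrogate: a harmonic glottal-like source with
cycle-to-cycle jitter, mixed with source noise at a chosen
harmonics-to-noise ratio, shaped by a cascade of formant resonators, and
interrupted by amplitude-gated phonatory breaks with short raised-cosine
ramps.  The clip is structured as short utterances separated by silent
pauses, emulating the isolated-word material (counting, short test
sentences) used to assess substitution voicing — the inter-word pauses
are where additive background noise is most audible and where a noise
gate earns its keep.  The degraded companion adds stationary background
noise scaled so the clip-level SNR is met exactly; clean and degraded
share one peak normalization gain so they stay sample-aligned and
comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import signal as sp_signal

from .audio_io import Waveform

__all__ = ["SynthSpec", "FixturePair", "generate", "fixture_suite"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic clean/degraded fixture pair.

    ``hnr_db`` is the harmonic-to-noise ratio of the voice source itself
    (aspiration-like noise belongs to the *clean* reference);
    ``snr_db`` scales the stationary background noise added on top to
    form the degraded signal.  ``hnr_db = inf`` disables source noise.
    """

    duration: float = 2.0
    sample_rate: int = 44100
    f0: float = 110.0
    jitter_pct: float = 3.0
    n_harmonics: int | None = None  # default: harmonics up to 4 kHz
    formants: tuple[tuple[float, float], ...] = (
        (500.0, 80.0),
        (1500.0, 120.0),
        (2500.0, 160.0),
    )
    utterance_ms: tuple[float, float] = (250.0, 450.0)
    pause_ms: tuple[float, float] = (350.0, 650.0)
    break_rate: float = 1.0
    break_len_ms: tuple[float, float] = (50.0, 200.0)
    hnr_db: float = 10.0
    snr_db: float = 5.0
    noise_color: str = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.f0 < self.sample_rate / 2:
            raise ValueError("f0 must lie below Nyquist")
        if self.break_len_ms[1] / 1000.0 >= self.duration:
            raise ValueError("phonatory breaks longer than the clip are infeasible")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")

    def harmonic_count(self) -> int:
        if self.n_harmonics is not None:
            return self.n_harmonics
        limit = min(4000.0, 0.45 * self.sample_rate)
        return max(1, int(limit / self.f0))


@dataclass
class FixturePair:
    clean: Waveform
    degraded: Waveform
    spec: SynthSpec

    def spec_json(self) -> str:
        d = asdict(self.spec)
        d["hnr_db"] = None if math.isinf(self.spec.hnr_db) else self.spec.hnr_db
        return json.dumps(d, indent=2)


def _jittered_phase(spec: SynthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative phase of an f0 track perturbed once per glottal cycle."""
    sr = spec.sample_rate
    f0_track = np.empty(n)
    pos = 0
    while pos < n:
        dev = rng.normal(0.0, spec.jitter_pct / 100.0) if spec.jitter_pct > 0 else 0.0
        f_cycle = spec.f0 * max(1.0 + dev, 0.2)
        cycle_len = max(int(round(sr / f_cycle)), 2)
        f0_track[pos : pos + cycle_len] = f_cycle
        pos += cycle_len
    return 2.0 * np.pi * np.cumsum(f0_track[:n]) / sr


def _colored_noise(color: str, n: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    if color == "white":
        return x
    # pink: shape the spectrum by 1/sqrt(f)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    y = np.fft.irfft(spec / np.sqrt(f), n=n)
    return y / max(np.std(y), 1e-12)


def _utterance_gate(spec: SynthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Word/pause envelope: utterances with 10 ms raised-cosine edges.

    Utterance and pause lengths are drawn uniformly from the spec's
    ranges; a ``pause_ms`` upper bound of 0 yields continuous phonation.
    """
    if spec.pause_ms[1] <= 0:
        return np.ones(n)
    sr = spec.sample_rate
    gate = np.zeros(n)
    rl = max(int(0.01 * sr), 1)
    ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, rl)))
    pos = int(rng.uniform(*spec.pause_ms) / 1000.0 * sr) // 2
    while pos < n:
        ulen = int(rng.uniform(*spec.utterance_ms) / 1000.0 * sr)
        end = min(pos + ulen, n)
        gate[pos:end] = 1.0
        if end - pos > 2 * rl:
            gate[pos : pos + rl] = ramp
            gate[end - rl : end] = ramp[::-1]
        pos = end + int(rng.uniform(*spec.pause_ms) / 1000.0 * sr)
    if not gate.any():  # clip shorter than the first pause: keep it voiced
        gate[:] = 1.0
    return gate


def _break_gate(spec: SynthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Amplitude gate: seeded phonatory breaks with 5 ms raised-cosine ramps."""
    gate = np.ones(n)
    if spec.break_rate <= 0:
        return gate
    sr = spec.sample_rate
    n_breaks = rng.poisson(spec.break_rate * spec.duration)
    ramp_len = max(int(0.005 * sr), 1)
    ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, ramp_len)))
    for _ in range(n_breaks):
        dur = rng.uniform(*spec.break_len_ms) / 1000.0
        blen = int(dur * sr)
        if blen + 2 * ramp_len >= n:
            continue
        start = rng.integers(0, n - blen - 2 * ramp_len)
        gate[start : start + ramp_len] *= ramp
        gate[start + ramp_len : start + ramp_len + blen] = 0.0
        gate[start + ramp_len + blen : start + 2 * ramp_len + blen] *= ramp[::-1]
    return gate


def _formant_filter(x: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Cascade of two-pole resonators at the given (center, bandwidth) pairs."""
    sr = spec.sample_rate
    for fc, bw in spec.formants:
        r = math.exp(-math.pi * bw / sr)
        theta = 2.0 * math.pi * fc / sr
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        b = [1.0 - r]  # keep gain moderate
        x = sp_signal.lfilter(b, a, x)
    return x


def generate(spec: SynthSpec) -> FixturePair:
    """Build one clean/degraded fixture pair from a :class:`SynthSpec`.

    The degraded clip equals clean plus background noise scaled so that
    ``10 log10(sum(clean^2) / sum(noise^2))`` equals ``snr_db`` exactly;
    both are then peak-normalized to 0.9 with a single shared gain.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))

    phase = _jittered_phase(spec, n, rng)
    source = np.zeros(n)
    for h in range(1, spec.harmonic_count() + 1):
        source += np.sin(h * phase) / h

    if not math.isinf(spec.hnr_db):
        aspiration = rng.standard_normal(n)
        h_energy = float(np.sum(source**2))
        a_energy = float(np.sum(aspiration**2))
        if a_energy > 0 and h_energy > 0:
            aspiration *= math.sqrt(h_energy / (a_energy * 10 ** (spec.hnr_db / 10.0)))
            source = source + aspiration

    voiced = _formant_filter(source, spec)
    clean = voiced * _utterance_gate(spec, n, rng) * _break_gate(spec, n, rng)

    noise = _colored_noise(spec.noise_color, n, rng)
    c_energy = float(np.sum(clean**2))
    n_energy = float(np.sum(noise**2))
    if c_energy > 0 and n_energy > 0:
        noise *= math.sqrt(c_energy / (n_energy * 10 ** (spec.snr_db / 10.0)))
    degraded = clean + noise

    peak = max(np.abs(clean).max(), np.abs(degraded).max(), 1e-12)
    gain = 0.9 / peak
    return FixturePair(
        clean=Waveform(clean * gain, spec.sample_rate, label="clean"),
        degraded=Waveform(degraded * gain, spec.sample_rate, label="degraded"),
        spec=spec,
    )


def fixture_suite(seed: int = 0) -> list[FixturePair]:
    """The fixed six-fixture evaluation panel.

    SNR in {0, 5, 10} dB crossed with break_rate in {0, 1}, white
    background noise, all other parameters at their defaults; per-pair
    seeds derived deterministically from ``seed``.
    """
    pairs = []
    idx = 0
    for snr in (0.0, 5.0, 10.0):
        for br in (0.0, 1.0):
            pairs.append(
                generate(
                    SynthSpec(
                        snr_db=snr,
                        break_rate=br,
                        noise_color="white",
                        seed=seed + 17 * idx + 1,
                    )
                )
            )
            idx += 1
    return pairs
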