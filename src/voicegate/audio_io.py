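"""Reading and writing mono RIFF/WAV audio.

All pipeline stages operate on a :class:`Waveform`: a float64 sample
sequence normalized to [-1, 1] plus its sample rate.  Integer PCM is
normalized by the type's full-scale magnitude (16-bit: 32768, so -32768
maps exactly to -1.0); IEEE-float WAV is taken as-is.  Multi-channel
files are averaged to mono, since the target recordings are
single-microphone voice clips.
"""

from __future__ import annotations

import logging
import struct
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = ["Waveform", "read_wav", "write_wav"]


@dataclass
class Waveform:
    """A mono audio signal with its sample rate.

    Parameters
    ----------
    samples : ndarray of float64
        Amplitude sequence, finite, nominally within [-1, 1].
    sample_rate : int
        Samples per second (Hz), > 0.
    label : str, optional
        Free-text identifier carried through the pipeline.
    """

    samples: np.ndarray
    sample_rate: int
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("waveform must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


# Full-scale divisor per integer dtype: symmetric convention, the most
# negative code maps exactly to -1.0.
_FULL_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF/WAV file into a normalized mono :class:`Waveform`.

    Integer PCM (8/16/24/32-bit) is divided by its full-scale magnitude;
    IEEE-float data is passed through.  24-bit PCM arrives from the WAV
    reader as int32 (low byte zero) and is normalized by 2^31, which is
    equivalent to dividing the 24-bit code by 2^23.  Multi-channel input
    is averaged to mono with a warning.

    Raises
    ------
    FileNotFoundError
        If `path` does not exist.
    ValueError
        For compressed / non-PCM codecs the WAV reader cannot decode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"unsupported WAV codec in {path}: {exc}") from exc

    orig_dtype = np.dtype(data.dtype)
    if data.ndim == 2:
        logger.warning("averaging %d channels to mono: %s", data.shape[1], path)
        samples = data.astype(np.float64).mean(axis=1)
    else:
        samples = data.astype(np.float64)

    if orig_dtype == np.dtype(np.uint8):
        samples = (samples - 128.0) / 128.0
    elif orig_dtype in _FULL_SCALE:
        samples = samples / _FULL_SCALE[orig_dtype]
    elif orig_dtype.kind == "f":
        pass
    else:  # pragma: no cover - wavfile only yields the dtypes above
        raise ValueError(f"unsupported sample dtype {orig_dtype} in {path}")

    return Waveform(samples, int(rate), label=path.stem)


def write_wav(w: Waveform, path: str | Path, bit_depth: int = 16) -> None:
    """Write a :class:`Waveform` as integer PCM WAV.

    Samples outside [-1, 1] are clipped (count logged).  The
    write -> read round trip is exact to within one quantization step
    (2^-(bit_depth-1)).

    Parameters
    ----------
    bit_depth : {16, 24}
        Output PCM word size.
    """
    if bit_depth not in (16, 24):
        raise ValueError(f"bit_depth must be 16 or 24, got {bit_depth}")
    path = Path(path)

    x = w.samples
    n_clip = int(np.count_nonzero((x < -1.0) | (x > 1.0)))
    if n_clip:
        logger.warning("clipping %d out-of-range samples writing %s", n_clip, path)
        x = np.clip(x, -1.0, 1.0)

    full = 2 ** (bit_depth - 1)
    # round-half-away from zero, clamp the +1.0 edge to full-1
    codes = np.clip(np.round(x * full), -full, full - 1).astype(np.int32)

    if bit_depth == 16:
        wavfile.write(str(path), w.sample_rate, codes.astype(np.int16))
        return

    # 24-bit: pack 3 little-endian bytes per sample via the stdlib wave module
    raw = bytearray()
    for c in codes:
        raw += struct.pack("<i", int(c))[:3]
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(3)
        fh.setframerate(w.sample_rate)
        fh.writeframes(bytes(raw))
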