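"""Audio containers and basic waveform utilities.

The package works on short mono speech tokens (CV syllables, CVC words)
represented as float arrays in [-1, 1]. Files are plain RIFF WAV: 16-bit PCM
on write, 16-bit PCM or float32 accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile


class SilentTokenError(ValueError):
    """Raised when an operation requires a token with nonzero energy."""


@dataclass(frozen=True)
class AudioToken:
    """A mono audio snippet with a text label.

    Samples are dimensionless amplitudes, nominally in [-1, 1]; the sample
    rate is in Hz. Tokens are immutable: manipulations return new tokens.
    """

    samples: np.ndarray
    sample_rate: int
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"token {self.label!r}: samples must be 1-D mono")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"token {self.label!r}: non-finite samples")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"token {self.label!r}: sample_rate must be positive")
        if 1000.0 * samples.size / self.sample_rate < 1.0:
            raise ValueError(f"token {self.label!r}: duration below 1 ms")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "AudioToken":
        return replace(self, samples=samples, label=self.label if label is None else label)


def read_wav(path, label: str = "") -> AudioToken:
    """Read a mono WAV file (16-bit PCM or float32) into an AudioToken."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV is supported")
    if data.dtype == np.int16:
        samples = data / 32767.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioToken(samples=samples, sample_rate=rate, label=label or str(path))


def write_wav(path, token: AudioToken) -> None:
    """Write a token as 16-bit PCM RIFF WAV, clipping at full scale."""
    clipped = np.clip(token.samples, -1.0, 1.0)
    wavfile.write(path, token.sample_rate, np.round(clipped * 32767.0).astype(np.int16))


def rms_equalize(tokens: list[AudioToken], target_rms: float) -> list[AudioToken]:
    """Scale each token so its RMS equals ``target_rms``.

    Pure gain: waveform shape is preserved up to a positive scalar.
    Raises SilentTokenError for any token with zero energy.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    out = []
    for tok in tokens:
        rms = tok.rms
        if rms == 0.0:
            raise SilentTokenError(f"token {tok.label!r} is silent; cannot equalize")
        out.append(tok.with_samples(tok.samples * (target_rms / rms)))
    return out
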