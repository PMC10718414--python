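"""Harmonic analysis/resynthesis vocoder.

This is the backend behind the F0 and vocal-tract-length (VTL) voice
manipulations. It decomposes a voiced token into

* an F0 contour (Hz per analysis frame, 0 for unvoiced frames), and
* a per-frame spectral envelope sampled on a fixed frequency grid,

and resynthesises audio from (possibly modified) versions of both. Voiced
frames are rebuilt by additive synthesis of harmonics whose amplitudes are
read off the envelope; unvoiced frames are rebuilt as envelope-shaped noise
with overlap-add. The model is deliberately minimal — a source-filter
decomposition sufficient for pitch scaling and uniform envelope
frequency-warping — rather than a perceptually tuned codec.

F0 estimation uses the normalized autocorrelation of each windowed frame with
parabolic interpolation of the peak lag, which resolves a flat contour to a
fraction of a Hz at typical speech F0s and sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window


class UnvoicedInputError(ValueError):
    """Raised when a token contains no voiced frames to anchor F0 matching."""


class ResynthesisError(RuntimeError):
    """Raised when resynthesis produces unusable output."""


@dataclass(frozen=True)
class VocoderConfig:
    """Analysis parameters.

    frame_ms / hop_ms set the analysis grid; f0_floor/f0_ceil bound the lag
    search; voicing_threshold is the minimum normalized autocorrelation peak
    for a frame to count as voiced.
    """

    frame_ms: float = 40.0
    hop_ms: float = 10.0
    f0_floor_hz: float = 60.0
    f0_ceil_hz: float = 500.0
    voicing_threshold: float = 0.45
    energy_threshold: float = 0.01  # fraction of token RMS below which a frame is silent
    n_fft: int = 4096


@dataclass(frozen=True)
class VocoderFrames:
    """Analysis product: times, F0 contour and envelope matrix."""

    times_s: np.ndarray        # frame centre times
    f0_hz: np.ndarray          # 0 where unvoiced
    envelope: np.ndarray       # (n_frames, n_freq) linear magnitude
    freqs_hz: np.ndarray       # envelope frequency grid
    sample_rate: int
    n_samples: int

    @property
    def voiced(self) -> np.ndarray:
        return self.f0_hz > 0


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Centre-padded framing; returns (frames, centre sample indices)."""
    half = frame_len // 2
    padded = np.pad(x, (half, half + frame_len))
    centers = np.arange(0, x.size, hop)
    idx = centers[:, None] + np.arange(frame_len)[None, :]
    return padded[idx], centers


def _autocorr_f0(frame: np.ndarray, fs: int, cfg: VocoderConfig) -> float:
    """Single-frame F0 via normalized autocorrelation; 0.0 if unvoiced."""
    frame = frame - frame.mean()
    n = frame.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frame, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return 0.0
    lag_min = int(np.floor(fs / cfg.f0_ceil_hz))
    lag_max = int(np.ceil(fs / cfg.f0_floor_hz))
    lag_max = min(lag_max, n - 2)
    if lag_max <= lag_min + 1:
        return 0.0
    seg = ac[lag_min : lag_max + 1] / ac[0]
    k = int(np.argmax(seg))
    if seg[k] < cfg.voicing_threshold:
        return 0.0
    lag = lag_min + k
    # parabolic interpolation around the peak lag
    if 0 < k < seg.size - 1:
        y0, y1, y2 = seg[k - 1], seg[k], seg[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return float(fs / lag)


def _harmonic_envelope(
    mag: np.ndarray, freqs: np.ndarray, f0: float, win_gain: float
) -> np.ndarray:
    """Envelope from interpolated harmonic peak amplitudes.

    For a voiced frame the spectrum is a comb of harmonics; the envelope is
    the piecewise-linear interpolation (in log magnitude) through the
    amplitude at each harmonic, held constant beyond the first/last one.
    """
    nyq = freqs[-1]
    n_harm = max(1, int(nyq / f0) - 1)
    bin_width = freqs[1] - freqs[0]
    harm_f = f0 * np.arange(1, n_harm + 1)
    harm_a = np.empty(n_harm)
    for i, hf in enumerate(harm_f):
        b = int(round(hf / bin_width))
        lo, hi = max(b - 2, 0), min(b + 3, mag.size)
        harm_a[i] = mag[lo:hi].max()
    harm_a = np.maximum(harm_a * 2.0 / win_gain, 1e-12)  # window-corrected sine amps
    log_env = np.interp(freqs, harm_f, np.log(harm_a))
    return np.exp(log_env)


def _smooth_envelope(mag: np.ndarray, freqs: np.ndarray, smooth_hz: float, win_gain: float) -> np.ndarray:
    """Envelope for unvoiced frames: moving-average smoothed magnitude."""
    bin_width = freqs[1] - freqs[0]
    k = max(1, int(round(smooth_hz / bin_width)))
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    sm = np.convolve(mag, kernel, mode="same")
    return np.maximum(sm * 2.0 / win_gain, 1e-12)


def analyze(samples: np.ndarray, sample_rate: int, cfg: VocoderConfig | None = None) -> VocoderFrames:
    """Decompose a waveform into F0 contour and per-frame spectral envelopes."""
    cfg = cfg or VocoderConfig()
    x = np.asarray(samples, dtype=np.float64)
    fs = int(sample_rate)
    frame_len = int(round(cfg.frame_ms * fs / 1000.0))
    hop = max(1, int(round(cfg.hop_ms * fs / 1000.0)))
    frames, centers = _frame_signal(x, frame_len, hop)
    window = get_window("hann", frame_len, fftbins=True)
    win_gain = float(window.sum())
    freqs = np.fft.rfftfreq(cfg.n_fft, 1.0 / fs)

    overall_rms = np.sqrt(np.mean(x**2)) if x.size else 0.0
    n_frames = frames.shape[0]
    f0 = np.zeros(n_frames)
    env = np.zeros((n_frames, freqs.size))
    for i in range(n_frames):
        fr = frames[i]
        frame_rms = np.sqrt(np.mean(fr**2))
        silent = overall_rms == 0 or frame_rms < cfg.energy_threshold * overall_rms
        if not silent:
            f0[i] = _autocorr_f0(fr, fs, cfg)
        mag = np.abs(np.fft.rfft(fr * window, cfg.n_fft))
        if f0[i] > 0:
            env[i] = _harmonic_envelope(mag, freqs, f0[i], win_gain)
        elif not silent:
            env[i] = _smooth_envelope(mag, freqs, smooth_hz=250.0, win_gain=win_gain)
        # silent frames keep a zero envelope
    return VocoderFrames(
        times_s=centers / fs,
        f0_hz=f0,
        envelope=env,
        freqs_hz=freqs,
        sample_rate=fs,
        n_samples=x.size,
    )


def warp_envelope(frames: VocoderFrames, formant_ratio: float) -> VocoderFrames:
    """Scale the envelope frequency axis by ``formant_ratio``.

    The warped envelope is E'(f) = E(f / ratio): a ratio below 1 moves
    spectral features (formants) down in frequency. Frequencies that map
    beyond Nyquist hold the last envelope value; this mirrors the truncation
    /extension convention of standard envelope-warping practice.
    """
    if not np.isfinite(formant_ratio) or formant_ratio <= 0:
        raise ValueError("formant_ratio must be positive and finite")
    if formant_ratio == 1.0:
        return frames
    src = frames.freqs_hz / formant_ratio
    warped = np.empty_like(frames.envelope)
    for i in range(frames.envelope.shape[0]):
        warped[i] = np.interp(src, frames.freqs_hz, frames.envelope[i])
    return VocoderFrames(
        times_s=frames.times_s,
        f0_hz=frames.f0_hz,
        envelope=warped,
        freqs_hz=frames.freqs_hz,
        sample_rate=frames.sample_rate,
        n_samples=frames.n_samples,
    )


def scale_f0(frames: VocoderFrames, factor: float) -> VocoderFrames:
    """Multiply the F0 contour of voiced frames by ``factor``."""
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError("F0 scale factor must be positive and finite")
    f0 = frames.f0_hz * factor
    return VocoderFrames(
        times_s=frames.times_s,
        f0_hz=f0,
        envelope=frames.envelope,
        freqs_hz=frames.freqs_hz,
        sample_rate=frames.sample_rate,
        n_samples=frames.n_samples,
    )


def synthesize(frames: VocoderFrames, cfg: VocoderConfig | None = None, noise_seed: int = 0) -> np.ndarray:
    """Rebuild a waveform from F0 contour + envelopes.

    Voiced regions: additive harmonic synthesis with per-sample phase
    accumulation (phase of harmonic k is 2*pi*k*cumsum(f0)/fs), harmonic
    amplitudes linearly interpolated between frames. Unvoiced regions:
    white noise spectrally shaped by the frame envelope, overlap-added.
    Output length equals the analysed length exactly.
    """
    cfg = cfg or VocoderConfig()
    fs = frames.sample_rate
    n = frames.n_samples
    t_frames = frames.times_s
    nyq = fs / 2.0

    # per-sample F0 (0 in unvoiced spans), linear interpolation within voiced runs
    sample_t = np.arange(n) / fs
    f0_s = np.interp(sample_t, t_frames, frames.f0_hz)
    voiced_s = np.interp(sample_t, t_frames, (frames.f0_hz > 0).astype(float)) >= 0.5
    f0_s = np.where(voiced_s, np.maximum(f0_s, cfg.f0_floor_hz * 0.5), 0.0)

    out = np.zeros(n)
    if voiced_s.any():
        f0_pos = np.where(f0_s > 0, f0_s, np.nan)
        f0_min = np.nanmin(f0_pos)
        n_harm = max(1, int(nyq / f0_min))
        phase_base = 2.0 * np.pi * np.cumsum(f0_s) / fs
        # harmonic amplitudes at frame resolution, then upsample to samples
        k = np.arange(1, n_harm + 1)
        harm_amp_frames = np.zeros((t_frames.size, n_harm))
        for i in range(t_frames.size):
            if frames.f0_hz[i] <= 0:
                continue
            hf = k * frames.f0_hz[i]
            amps = np.interp(hf, frames.freqs_hz, frames.envelope[i])
            amps[hf >= nyq] = 0.0
            harm_amp_frames[i] = amps
        voiced_sum = np.zeros(n)
        for j in range(n_harm):
            amp_s = np.interp(sample_t, t_frames, harm_amp_frames[:, j])
            voiced_sum += amp_s * np.sin((j + 1) * phase_base)
        out += np.where(voiced_s, voiced_sum, 0.0)

    unvoiced_frames = (~(frames.f0_hz > 0)) & (frames.envelope.max(axis=1) > 1e-11)
    if unvoiced_frames.any():
        rng = np.random.default_rng(noise_seed)
        frame_len = int(round(cfg.frame_ms * fs / 1000.0))
        window = get_window("hann", frame_len, fftbins=True)
        hop = max(1, int(round(cfg.hop_ms * fs / 1000.0)))
        half = frame_len // 2
        noise_out = np.zeros(n + 2 * frame_len)
        norm = np.zeros(n + 2 * frame_len)
        nfreq = np.fft.rfftfreq(frame_len, 1.0 / fs)
        for i in np.flatnonzero(unvoiced_frames):
            shape = np.interp(nfreq, frames.freqs_hz, frames.envelope[i])
            noise = rng.standard_normal(frame_len)
            spec = np.fft.rfft(noise * window)
            shaped = np.fft.irfft(spec * shape / np.sqrt(frame_len), frame_len)
            # frame i is centred on original sample i*hop
            start = i * hop - half + frame_len  # +frame_len: left pad of the OLA buffer
            noise_out[start : start + frame_len] += shaped * window
            norm[start : start + frame_len] += window**2
        norm[norm < 1e-8] = 1.0
        out += (noise_out / norm)[frame_len : frame_len + n]

    if not np.all(np.isfinite(out)):
        raise ResynthesisError("non-finite samples produced during synthesis")
    peak = np.max(np.abs(out)) if out.size else 0.0
    if peak > 1.0:
        out = out / peak
    return out
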