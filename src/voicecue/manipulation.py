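"""F0 and vocal-tract-length (VTL) voice manipulations in semitone units.

A voice condition is a pair (ΔF0, ΔVTL) of semitone offsets relative to a
reference voice. ΔF0 rescales the pitch contour so that its summary statistic
over voiced frames lands on ``reference_f0 * 2**(ΔF0/12)``. ΔVTL uniformly
scales the spectral-envelope frequency axis by ``2**(-ΔVTL/12)``: lengthening
the vocal tract (positive ΔVTL) moves formants down in frequency. F0 is
applied first, then VTL, and the unmodified (0, 0) condition still passes
through full analysis/resynthesis so that every condition shares the same
vocoder artefacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .audio import AudioToken
from .vocoder import (
    ResynthesisError,
    UnvoicedInputError,
    VocoderConfig,
    analyze,
    scale_f0,
    synthesize,
    warp_envelope,
)

__all__ = [
    "VoiceManipulation",
    "ReferenceVoiceSpec",
    "semitone_to_ratio",
    "ratio_to_semitones",
    "vtl_to_formant_ratio",
    "apply_manipulation",
    "extract_f0_contour",
    "estimate_envelope_peak_hz",
    "estimate_formant_shift_ratio",
]


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def semitone_to_ratio(st: float) -> float:
    """Convert a semitone offset to a frequency ratio: 2**(st/12)."""
    return 2.0 ** (_require_finite(st, "st") / 12.0)


def ratio_to_semitones(r: float) -> float:
    """Convert a frequency ratio to semitones: 12*log2(r)."""
    r = _require_finite(r, "r")
    if r <= 0:
        raise ValueError(f"ratio must be positive, got {r!r}")
    return 12.0 * math.log2(r)


def vtl_to_formant_ratio(delta_vtl_st: float) -> float:
    """Formant-frequency scale factor for a VTL change in semitones.

    A positive VTL change (longer tract) shifts formants DOWN, so the factor
    is 2**(-ΔVTL/12): below 1 for lengthening, above 1 for shortening.
    """
    return 2.0 ** (-_require_finite(delta_vtl_st, "delta_vtl_st") / 12.0)


@dataclass(frozen=True)
class VoiceManipulation:
    """A (ΔF0, ΔVTL) semitone pair defining one voice condition."""

    delta_f0_st: float = 0.0
    delta_vtl_st: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(self.delta_f0_st, "delta_f0_st")
        _require_finite(self.delta_vtl_st, "delta_vtl_st")

    def to_json(self) -> str:
        return json.dumps({"delta_f0_st": self.delta_f0_st, "delta_vtl_st": self.delta_vtl_st})

    @classmethod
    def from_json(cls, text: str) -> "VoiceManipulation":
        obj = json.loads(text)
        return cls(delta_f0_st=obj["delta_f0_st"], delta_vtl_st=obj["delta_vtl_st"])


@dataclass(frozen=True)
class ReferenceVoiceSpec:
    """The reference voice all manipulations are relative to.

    ``reference_f0_hz`` defaults to 242 Hz (a typical adult female voice);
    ``f0_match_statistic`` selects whether the mean or median of the voiced
    F0 contour is matched to the reference.
    """

    reference_f0_hz: float = 242.0
    f0_match_statistic: str = "mean"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.reference_f0_hz) and self.reference_f0_hz > 0):
            raise ValueError("reference_f0_hz must be positive and finite")
        if self.f0_match_statistic not in ("mean", "median"):
            raise ValueError("f0_match_statistic must be 'mean' or 'median'")

    def contour_statistic(self, voiced_f0_hz: np.ndarray) -> float:
        fn = np.mean if self.f0_match_statistic == "mean" else np.median
        return float(fn(voiced_f0_hz))


def apply_manipulation(
    token: AudioToken,
    manip: VoiceManipulation,
    ref: ReferenceVoiceSpec | None = None,
    cfg: VocoderConfig | None = None,
) -> AudioToken:
    """Apply a (ΔF0, ΔVTL) manipulation to a token via analysis/resynthesis.

    The output F0 contour is the input contour multiplicatively rescaled so
    its matching statistic over voiced frames equals
    ``ref.reference_f0_hz * 2**(ΔF0/12)``; the spectral envelope is
    frequency-scaled by ``vtl_to_formant_ratio(ΔVTL)``. Sample rate and
    duration are preserved.

    Raises UnvoicedInputError if no voiced frames are found, and
    ResynthesisError (tagged with the token label) if synthesis fails.
    """
    ref = ref or ReferenceVoiceSpec()
    frames = analyze(token.samples, token.sample_rate, cfg)
    voiced = frames.voiced
    if not voiced.any():
        raise UnvoicedInputError(f"token {token.label!r}: no voiced frames for F0 matching")
    current = ref.contour_statistic(frames.f0_hz[voiced])
    target = ref.reference_f0_hz * semitone_to_ratio(manip.delta_f0_st)
    frames = scale_f0(frames, target / current)
    frames = warp_envelope(frames, vtl_to_formant_ratio(manip.delta_vtl_st))
    try:
        samples = synthesize(frames, cfg)
    except ResynthesisError as exc:
        raise ResynthesisError(f"token {token.label!r}: {exc}") from exc
    label = f"{token.label}|f0{manip.delta_f0_st:+g}st_vtl{manip.delta_vtl_st:+g}st"
    return AudioToken(samples=samples, sample_rate=token.sample_rate, label=label)


def extract_f0_contour(token: AudioToken, cfg: VocoderConfig | None = None) -> np.ndarray:
    """Voiced-frame F0 values (Hz) of a token, in frame order."""
    frames = analyze(token.samples, token.sample_rate, cfg)
    return frames.f0_hz[frames.voiced]


def estimate_envelope_peak_hz(
    token: AudioToken,
    fmin_hz: float = 200.0,
    fmax_hz: float = 2500.0,
    cfg: VocoderConfig | None = None,
) -> float:
    """Estimate the dominant spectral-envelope peak (≈ first formant) in Hz.

    Averages the log envelope over voiced frames, samples it at the harmonics
    of the median F0 within [fmin, fmax], and refines the peak location by
    parabolic interpolation over the three neighbouring harmonic points.
    Harmonic sampling avoids being fooled by inter-harmonic interpolation
    detail; the parabola recovers sub-harmonic-spacing resolution because a
    formant resonance is smooth on that scale.
    """
    frames = analyze(token.samples, token.sample_rate, cfg)
    voiced = frames.voiced
    if not voiced.any():
        raise UnvoicedInputError(f"token {token.label!r}: no voiced frames")
    log_env = np.log(np.maximum(frames.envelope[voiced], 1e-12)).mean(axis=0)
    f0 = float(np.median(frames.f0_hz[voiced]))
    harm_f = np.arange(1, int(frames.freqs_hz[-1] / f0)) * f0
    harm_f = harm_f[(harm_f >= fmin_hz) & (harm_f <= fmax_hz)]
    if harm_f.size < 3:
        raise ValueError("search band too narrow for the token's harmonic spacing")
    harm_v = np.interp(harm_f, frames.freqs_hz, log_env)
    k = int(np.argmax(harm_v))
    if k == 0 or k == harm_v.size - 1:
        return float(harm_f[k])
    y0, y1, y2 = harm_v[k - 1], harm_v[k], harm_v[k + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(harm_f[k] + offset * f0)


def _mean_log_envelope(token: AudioToken, cfg: VocoderConfig | None):
    frames = analyze(token.samples, token.sample_rate, cfg)
    voiced = frames.voiced
    if not voiced.any():
        raise UnvoicedInputError(f"token {token.label!r}: no voiced frames")
    return frames.freqs_hz, np.log(np.maximum(frames.envelope[voiced], 1e-12)).mean(axis=0)


def estimate_formant_shift_ratio(
    before: AudioToken,
    after: AudioToken,
    fmin_hz: float = 300.0,
    fmax_hz: float = 4000.0,
    max_shift_st: float = 15.0,
    cfg: VocoderConfig | None = None,
) -> float:
    """Estimate the uniform spectral-envelope frequency scaling between two tokens.

    A vocal-tract-length change multiplies every envelope frequency by one
    factor, i.e. translates the log-frequency envelope. The factor is
    recovered by cross-correlating the two tokens' voiced-average log
    envelopes on a log2-frequency grid and parabolic-interpolating the
    correlation peak — robust where a single-peak measure is confounded by
    neighbouring formants. Returns after/before frequency ratio (< 1 when
    formants moved down).
    """
    fa, env_a = _mean_log_envelope(before, cfg)
    fb, env_b = _mean_log_envelope(after, cfg)
    step = 0.005  # log2-frequency grid resolution (~0.06 st)
    grid = np.arange(np.log2(fmin_hz), np.log2(fmax_hz), step)
    a = np.interp(grid, np.log2(fa[1:]), env_a[1:])
    b = np.interp(grid, np.log2(fb[1:]), env_b[1:])
    max_lag = int(round((max_shift_st / 12.0) / step))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: a.size - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: b.size + lag]
        # Pearson correlation of the overlap: each window keeps its own mean,
        # otherwise the steep spectral tilt drags the peak toward zero lag
        x = x - x.mean()
        y = y - y.mean()
        corr[i] = np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y))
    k = int(np.argmax(corr))
    lag = float(lags[k])
    if 0 < k < corr.size - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    return float(2.0 ** (lag * step))
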