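"""Synthetic speech-token generator.

Stands in for recorded syllable corpora: tokens are built by source-filter
synthesis — a glottal-like harmonic source (amplitudes rolling off at
roughly -6 dB/octave) passed through a cascade of second-order formant
resonators — so they are voiced, formant-bearing, and fully seeded. The
downstream algorithms (F0 extraction, envelope warping, staircases) only
require those properties; no attempt is made at English phonetic fidelity,
and labels are cosmetic.

CV syllables are a consonant-like murmur gliding into a steady vowel;
durations are drawn uniformly from the 142-200 ms range typical of clipped
consonant-vowel tokens. Triplets concatenate three distinct inventory
syllables into one CVCVCV stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .audio import AudioToken

__all__ = [
    "SyllableSpec",
    "TripletStimulus",
    "synth_vowel",
    "generate_cv_inventory",
    "make_triplet",
    "gender_word_inventory",
]

DEFAULT_SAMPLE_RATE = 44_100

# (F1, F2, F3) targets in Hz, female-typical ranges; F1 < F2 < F3 throughout
VOWEL_FORMANTS: dict[str, tuple[float, float, float]] = {
    "i": (310.0, 2790.0, 3310.0),
    "e": (560.0, 2320.0, 2950.0),
    "a": (850.0, 1220.0, 2810.0),
    "o": (450.0, 800.0, 2830.0),
    "u": (370.0, 950.0, 2670.0),
}
# murmur-like voiced consonant onsets (formants of the closure portion)
CONSONANT_FORMANTS: dict[str, tuple[float, float, float]] = {
    "b": (250.0, 700.0, 2300.0),
    "d": (280.0, 1700.0, 2600.0),
    "g": (270.0, 1300.0, 2400.0),
    "m": (250.0, 1100.0, 2100.0),
    "n": (270.0, 1500.0, 2500.0),
    "l": (330.0, 1200.0, 2800.0),
}
FORMANT_BANDWIDTHS = (90.0, 110.0, 170.0)


@dataclass(frozen=True)
class SyllableSpec:
    """Parametric description of one CV syllable."""

    consonant_id: str
    vowel_id: str
    duration_ms: float
    f0_hz: float

    def __post_init__(self) -> None:
        if not (142.0 <= self.duration_ms <= 200.0):
            raise ValueError("CV duration must lie in [142, 200] ms")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        f1, f2, f3 = VOWEL_FORMANTS[self.vowel_id]
        if not (f1 < f2 < f3):
            raise ValueError("formant targets must be strictly increasing")

    @property
    def label(self) -> str:
        return f"{self.consonant_id}{self.vowel_id}"


@dataclass(frozen=True)
class TripletStimulus:
    """Three concatenated CV syllables forming one CVCVCV stimulus."""

    syllables: tuple[SyllableSpec, SyllableSpec, SyllableSpec]
    audio: AudioToken
    text: str

    def __post_init__(self) -> None:
        if len(self.syllables) != 3:
            raise ValueError("a triplet needs exactly 3 syllables")


def _resonator_sos(freq: float, bw: float, fs: int) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    # unity gain at the resonance frequency
    gain = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)
    return np.array([[gain, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r]])


def _harmonic_source(n: int, f0_hz: float | np.ndarray, fs: int) -> np.ndarray:
    """Periodic glottal-like source: harmonics with ~-6 dB/oct roll-off."""
    f0 = np.broadcast_to(np.asarray(f0_hz, dtype=float), (n,))
    phase = 2.0 * np.pi * np.cumsum(f0) / fs
    n_harm = int(fs / 2.0 / float(np.max(f0))) - 1
    out = np.zeros(n)
    for k in range(1, max(2, n_harm + 1)):
        out += np.sin(k * phase) / k
    return out


def _formant_filter(source: np.ndarray, formants, fs: int) -> np.ndarray:
    out = source
    for freq, bw in zip(formants, FORMANT_BANDWIDTHS):
        out = sp_signal.sosfilt(_resonator_sos(freq, bw, fs), out)
    return out


def _edge_ramp(x: np.ndarray, fs: int, ramp_ms: float = 10.0) -> np.ndarray:
    k = min(int(fs * ramp_ms / 1000.0), x.size // 2)
    if k > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / k))
        x = x.copy()
        x[:k] *= ramp
        x[-k:] *= ramp[::-1]
    return x


def synth_vowel(
    vowel_id: str = "a",
    duration_ms: float = 300.0,
    f0_hz: float = 200.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    label: str | None = None,
) -> AudioToken:
    """Synthesise a steady vowel with flat F0 — the basic test fixture."""
    fs = sample_rate
    n = int(round(duration_ms * fs / 1000.0))
    x = _formant_filter(_harmonic_source(n, f0_hz, fs), VOWEL_FORMANTS[vowel_id], fs)
    x = _edge_ramp(x, fs)
    x = 0.3 * x / np.max(np.abs(x))
    return AudioToken(samples=x, sample_rate=fs, label=label or f"vowel-{vowel_id}-{f0_hz:g}Hz")


def synth_syllable(spec: SyllableSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> AudioToken:
    """Synthesise a CV syllable: consonant murmur gliding into the vowel."""
    fs = sample_rate
    n = int(round(spec.duration_ms * fs / 1000.0))
    n_cons = int(0.3 * n)
    cf = CONSONANT_FORMANTS[spec.consonant_id]
    vf = VOWEL_FORMANTS[spec.vowel_id]
    source = _harmonic_source(n, spec.f0_hz, fs)
    # formant glide over the consonant portion, steady vowel afterwards
    glide = np.concatenate([np.linspace(0.0, 1.0, n_cons), np.ones(n - n_cons)])
    # two-segment approximation: filter separately and crossfade
    cons = _formant_filter(source, cf, fs) * 0.6
    vow = _formant_filter(source, vf, fs)
    x = cons * (1.0 - glide) + vow * glide
    x = _edge_ramp(x, fs)
    x = 0.3 * x / np.max(np.abs(x))
    return AudioToken(samples=x, sample_rate=fs, label=spec.label)


def generate_cv_inventory(
    n: int, seed: int, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> list[AudioToken]:
    """Generate ``n`` distinct seeded CV tokens with durations in [142, 200] ms."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    consonants = sorted(CONSONANT_FORMANTS)
    vowels = sorted(VOWEL_FORMANTS)
    tokens = []
    for i in range(n):
        spec = SyllableSpec(
            consonant_id=consonants[int(rng.integers(len(consonants)))],
            vowel_id=vowels[int(rng.integers(len(vowels)))],
            duration_ms=float(rng.uniform(142.0, 200.0)),
            f0_hz=float(rng.uniform(220.0, 270.0)),
        )
        tok = synth_syllable(spec, sample_rate)
        tokens.append(tok.with_samples(tok.samples, label=f"{spec.label}{i:03d}"))
    return tokens


def make_triplet(inventory: list[AudioToken], seed: int) -> TripletStimulus:
    """Concatenate three distinct seeded draws from the inventory."""
    if len(inventory) < 3:
        raise ValueError("inventory must contain at least 3 tokens")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(inventory), size=3, replace=False)
    chosen = [inventory[i] for i in idx]
    fs = chosen[0].sample_rate
    if any(t.sample_rate != fs for t in chosen):
        raise ValueError("inventory tokens must share one sample rate")
    audio = AudioToken(
        samples=np.concatenate([t.samples for t in chosen]),
        sample_rate=fs,
        label="-".join(t.label for t in chosen),
    )
    specs = tuple(
        SyllableSpec(
            consonant_id=t.label[0],
            vowel_id=t.label[1],
            duration_ms=t.duration_ms,
            f0_hz=242.0,
        )
        for t in chosen
    )
    return TripletStimulus(syllables=specs, audio=audio, text="-".join(t.label[:2] for t in chosen))


GENDER_WORDS = ("bike", "pool", "watch", "hat")
_WORD_VOWEL = {"bike": "a", "pool": "u", "watch": "o", "hat": "e"}
_WORD_CONSONANT = {"bike": "b", "pool": "l", "watch": "d", "hat": "g"}


def gender_word_inventory(sample_rate: int = DEFAULT_SAMPLE_RATE) -> list[AudioToken]:
    """The four fixed CVC-like test words for the gender-categorisation task."""
    tokens = []
    for word in GENDER_WORDS:
        fs = sample_rate
        n = int(round(0.35 * fs))
        source = _harmonic_source(n, 242.0, fs)
        onset = _formant_filter(source, CONSONANT_FORMANTS[_WORD_CONSONANT[word]], fs) * 0.6
        nucleus = _formant_filter(source, VOWEL_FORMANTS[_WORD_VOWEL[word]], fs)
        w = np.linspace(0.0, 1.0, n)
        shape = np.minimum(w / 0.25, 1.0) * np.minimum((1.0 - w) / 0.25, 1.0)
        x = (onset * (1.0 - np.minimum(w / 0.3, 1.0)) + nucleus * np.minimum(w / 0.3, 1.0)) * shape
        x = _edge_ramp(x, fs)
        x = 0.3 * x / np.max(np.abs(x))
        tokens.append(AudioToken(samples=x, sample_rate=fs, label=word))
    return tokens
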