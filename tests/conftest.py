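import numpy as np
import pytest

from voicecue import synth_vowel
from voicecue.stimuli import generate_cv_inventory


@pytest.fixture(scope="session")
def flat_vowel():
    """A 300 ms synthetic /a/ with flat 200 Hz F0 — the canonical vocoder probe."""
    return synth_vowel("a", duration_ms=300.0, f0_hz=200.0)


@pytest.fixture(scope="session")
def low_vowel():
    """A low-pitched vowel (110 Hz): dense harmonic sampling of the envelope."""
    return synth_vowel("a", duration_ms=300.0, f0_hz=110.0)


@pytest.fixture(scope="session")
def cv_inventory():
    """A small seeded CV inventory shared across tests (cheap to build once)."""
    return generate_cv_inventory(12, seed=11)


class ScriptedObserver:
    """Deterministic observer that replays a fixed correct/incorrect pattern."""

    def __init__(self, pattern):
        self.pattern = list(pattern)
        self.i = 0

    def respond_odd_one_out(self, level_st, odd_interval, rng):
        correct = self.pattern[self.i % len(self.pattern)]
        self.i += 1
        if correct:
            return odd_interval
        return next(k for k in (1, 2, 3) if k != odd_interval)


@pytest.fixture
def scripted_observer_factory():
    return ScriptedObserver
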