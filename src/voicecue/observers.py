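"""Simulated listeners.

Two kinds of synthetic participants replace human listeners:

* ``SimulatedObserver`` — an odd-one-out listener for the 3AFC JND task.
  Its probability of a correct response follows a standard psychophysical
  model: chance floor gamma = 1/3 (three alternatives), lapse rate lambda,
  and a logistic discrimination function F of the cue difference. F is
  logistic in log2 of the semitone magnitude, because discriminability of
  pitch/VTL offsets is ratio-scaled: p(|L|) = 1/3 + (2/3 - lambda) * F.
  At |L| = threshold (lambda = 0) the observer is at 2/3 correct, the
  midpoint between chance and perfect.

* ``GenderResponder`` — a binary categoriser whose log-odds of answering
  "male" is linear in the normalised voice cues (deltaF0, deltaVTL), the
  generative counterpart of the logistic cue-weight analysis model.

Both are deliberately simple: no fatigue, learning, or sequential effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SimulatedObserver",
    "GenderResponder",
    "sample_participant_panel",
]

CHANCE_3AFC = 1.0 / 3.0


@dataclass(frozen=True)
class SimulatedObserver:
    """Psychometric odd-one-out listener for the 3AFC staircase task.

    threshold_st is the semitone magnitude of the psychometric midpoint,
    slope the logistic steepness in log2-semitone units, lapse_rate the
    probability of a stimulus-independent random lapse. ``shape`` selects
    a logistic (default) or Weibull discrimination function.
    """

    threshold_st: float
    slope: float = 3.0
    lapse_rate: float = 0.02
    shape: str = "logistic"

    def __post_init__(self) -> None:
        if self.threshold_st <= 0:
            raise ValueError("threshold_st must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.shape not in ("logistic", "weibull"):
            raise ValueError("shape must be 'logistic' or 'weibull'")

    def discrimination(self, level_st) -> np.ndarray:
        """F(|level|): 0 at tiny differences, 1 at huge ones, 1/2 at threshold."""
        mag = np.abs(np.asarray(level_st, dtype=float))
        with np.errstate(divide="ignore"):
            x = np.log2(np.where(mag > 0, mag, np.finfo(float).tiny))
        if self.shape == "logistic":
            f = expit(self.slope * (x - np.log2(self.threshold_st)))
        else:
            # Weibull in ratio space with the same midpoint
            ratio = 2.0 ** (x - np.log2(self.threshold_st))
            f = 1.0 - 0.5 ** (ratio**self.slope)
        return np.where(mag > 0, f, 0.0)

    def p_correct(self, level_st) -> np.ndarray:
        """P(correct) = 1/3 + (2/3 - lambda) * F(|level|); in [1/3, 1 - 2*lambda/3]."""
        f = self.discrimination(level_st)
        return CHANCE_3AFC + (1.0 - CHANCE_3AFC - self.lapse_rate) * f

    def respond_odd_one_out(self, level_st: float, odd_interval: int, rng) -> int:
        """Pick an interval: the odd one with P(correct), else one of the
        two wrong intervals with equal probability."""
        rng = np.random.default_rng(rng)
        if rng.random() < float(self.p_correct(level_st)):
            return int(odd_interval)
        wrong = [i for i in (1, 2, 3) if i != odd_interval]
        return int(wrong[rng.integers(2)])


@dataclass(frozen=True)
class GenderResponder:
    """Binary voice-gender categoriser, linear in normalised cues on the
    log-odds scale: logit P(male) = beta0 + beta_f0*dF0 + beta_vtl*dVTL."""

    beta0: float = 0.0
    beta_f0: float = 0.0
    beta_vtl: float = 0.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_f0", "beta_vtl"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def p_male(self, dF0_norm: float, dVTL_norm: float) -> float:
        return float(expit(self.beta0 + self.beta_f0 * dF0_norm + self.beta_vtl * dVTL_norm))

    def respond_gender(self, dF0_norm: float, dVTL_norm: float, rng) -> str:
        rng = np.random.default_rng(rng)
        return "male" if rng.random() < self.p_male(dF0_norm, dVTL_norm) else "female"


def sample_participant_panel(
    n: int,
    mean_beta0: float = 0.0,
    mean_beta_f0: float = 4.0,
    mean_beta_vtl: float = 4.0,
    sd_beta0: float = 0.0,
    sd_beta_f0: float = 0.0,
    sd_beta_vtl: float = 0.0,
    seed=None,
) -> list[GenderResponder]:
    """Draw ``n`` gender responders from a normal population of betas.

    With all SDs zero every responder equals the population means. Seeded
    and deterministic.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    for name, sd in (("sd_beta0", sd_beta0), ("sd_beta_f0", sd_beta_f0), ("sd_beta_vtl", sd_beta_vtl)):
        if sd < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n):
        panel.append(
            GenderResponder(
                beta0=mean_beta0 + sd_beta0 * rng.standard_normal(),
                beta_f0=mean_beta_f0 + sd_beta_f0 * rng.standard_normal(),
                beta_vtl=mean_beta_vtl + sd_beta_vtl * rng.standard_normal(),
                participant_id=f"p{i + 1:03d}",
            )
        )
    return panel
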