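"""Adaptive 3I-3AFC 2-down-1-up staircase for voice-cue JND estimation.

One run adaptively tracks the smallest F0 or VTL difference (in semitones,
relative to a reference voice) a listener can detect in an odd-one-out task
with three intervals. The transformed up-down rule — step down after two
consecutive correct responses, step up after one error — converges on the
stimulus level yielding 70.7 % correct (p such that p**2 = 0.5).

Rules implemented per run:

* the tracked level starts at a signed semitone offset (the sign is the run
  direction and never flips; the adaptive variable is the magnitude);
* the step starts at 2 st and shrinks by a factor of sqrt(2) on every
  down-step; up-steps leave it unchanged;
* a reversal is a change of direction of the track: an error after at least
  two correct responses, or two consecutive correct responses after at least
  one error; the magnitude logged is the level at which the direction change
  occurred (before the reversing step is applied);
* the run ends at 15 consecutive errors, at 150 trials, or at 8 reversals —
  whichever happens first (in that order of precedence). Only the last case
  defines a JND: the mean magnitude of the last six reversals.

Training runs use a fixed 3-st step and a fixed small trial count, and
produce no JND.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "RunResult",
    "Termination",
    "StaircaseError",
    "InsufficientReversalsError",
    "update",
    "check_termination",
    "compute_jnd",
    "run_staircase",
    "run_session",
    "EncouragementState",
    "encouragement_decision",
    "RUN_DIRECTIONS",
]

# the four test-run directions: cue and signed starting level in semitones
RUN_DIRECTIONS: dict[str, tuple[str, float]] = {
    "f0-": ("f0", -12.0),
    "f0+": ("f0", +5.0),
    "vtl+": ("vtl", +3.8),
    "vtl-": ("vtl", -7.0),
}


class StaircaseError(RuntimeError):
    """Raised on protocol misuse, e.g. updating a terminated run."""


class InsufficientReversalsError(ValueError):
    """Raised when a JND is requested from too few reversals."""


class Termination(str, Enum):
    REVERSALS = "reversals"
    MAX_TRIALS = "max_trials"
    CONSECUTIVE_INCORRECT = "consecutive_incorrect"


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive run; defaults are the standard battery values."""

    start_level_st: float = -12.0
    initial_step_st: float = 2.0
    step_shrink_factor: float = math.sqrt(2.0)
    training_step_st: float = 3.0
    n_down: int = 2
    n_up: int = 1
    max_trials: int = 150
    max_consecutive_incorrect: int = 15
    target_reversals: int = 8
    jnd_reversals: int = 6
    # guards where the protocol is silent: magnitude cap after up-steps and a
    # step-size floor against floating-point underflow
    level_cap_factor: float = 1.5
    min_step_st: float = 0.05
    # When the sqrt(2) shrink is applied. "per_reversal" (default) shrinks at
    # each direction change of the track. The alternative "per_down_step"
    # shrinks on every down-step; under that schedule the total possible
    # descent is the geometric sum initial_step/(1 - 1/shrink) ≈ 6.83 st, so
    # a track starting 12 st out stalls far above a small threshold — kept
    # only as a comparison variant.
    step_schedule: str = "per_reversal"

    def __post_init__(self) -> None:
        counts = (
            self.n_down, self.n_up, self.max_trials,
            self.max_consecutive_incorrect, self.target_reversals, self.jnd_reversals,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all staircase counts must be >= 1")
        if self.jnd_reversals > self.target_reversals:
            raise ValueError("jnd_reversals cannot exceed target_reversals")
        if self.initial_step_st <= 0:
            raise ValueError("initial_step_st must be positive")
        if self.step_shrink_factor <= 1:
            raise ValueError("step_shrink_factor must exceed 1")
        if self.start_level_st == 0:
            raise ValueError("start_level_st must be nonzero (its sign is the run direction)")
        if self.step_schedule not in ("per_reversal", "per_down_step"):
            raise ValueError("step_schedule must be 'per_reversal' or 'per_down_step'")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    level_st: float
    odd_interval: int
    response_interval: int
    correct: bool
    was_reversal: bool

    def __post_init__(self) -> None:
        if self.correct != (self.response_interval == self.odd_interval):
            raise ValueError("correct flag inconsistent with intervals")


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of a run; ``update`` returns the successor state."""

    level_st: float
    step_st: float
    trial_index: int = 0
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    any_incorrect_since_reversal: bool = False
    last_move: str | None = None  # 'down' | 'up' | None
    reversal_levels: tuple[float, ...] = ()
    history: tuple[TrialRecord, ...] = ()
    clamp_events: int = 0
    terminated: Termination | None = None

    @property
    def sign(self) -> float:
        return math.copysign(1.0, self.level_st)

    @property
    def magnitude(self) -> float:
        return abs(self.level_st)


def new_state(cfg: StaircaseConfig, training: bool = False) -> StaircaseState:
    step = cfg.training_step_st if training else cfg.initial_step_st
    return StaircaseState(level_st=cfg.start_level_st, step_st=step)


def update(
    state: StaircaseState,
    correct: bool,
    cfg: StaircaseConfig,
    training: bool = False,
) -> StaircaseState:
    """Advance the staircase by one scored trial.

    Applies the 2-down-1-up level rule, the sqrt(2) step shrinkage on
    down-steps (frozen during training), reversal detection, and the level
    cap/floor guards. Termination is NOT evaluated here; compose with
    ``check_termination``.
    """
    if state.terminated is not None:
        raise StaircaseError("cannot update a terminated staircase")
    sign = state.sign
    mag = state.magnitude
    step = state.step_st
    n_rev = len(state.reversal_levels)
    reversal_level: float | None = None
    clamp = state.clamp_events

    def shrunk(s: float) -> float:
        return max(s / cfg.step_shrink_factor, cfg.min_step_st)

    if correct:
        cc = state.consecutive_correct + 1
        ci = 0
        if cc >= cfg.n_down:
            # down-step; a reversal if the previous move was up
            if state.last_move == "up":
                reversal_level = mag
            if not training and cfg.step_schedule == "per_reversal" and reversal_level is not None:
                step = shrunk(step)
            new_mag = mag - step
            if new_mag <= 0:
                # approach zero geometrically instead of crossing it
                new_mag = mag / 2.0
            mag = new_mag
            if not training and cfg.step_schedule == "per_down_step":
                step = shrunk(step)
            cc = 0
            last_move = "down"
        else:
            last_move = state.last_move
    else:
        cc = 0
        ci = state.consecutive_incorrect + 1
        # up-step; a reversal if the previous move was down
        if state.last_move == "down":
            reversal_level = mag
        if not training and cfg.step_schedule == "per_reversal" and reversal_level is not None:
            step = shrunk(step)
        mag = mag + step
        cap = cfg.level_cap_factor * abs(cfg.start_level_st)
        if mag > cap:
            mag = cap
            clamp += 1
        last_move = "up"

    reversals = state.reversal_levels
    if reversal_level is not None:
        reversals = reversals + (reversal_level,)
    return replace(
        state,
        level_st=sign * mag,
        step_st=step,
        trial_index=state.trial_index + 1,
        consecutive_correct=cc,
        consecutive_incorrect=ci,
        last_move=last_move,
        reversal_levels=reversals,
        clamp_events=clamp,
    )


def check_termination(state: StaircaseState, cfg: StaircaseConfig) -> Termination | None:
    """First satisfied stopping rule, or None.

    Precedence: consecutive errors, then trial budget, then reversal target.
    """
    if state.consecutive_incorrect >= cfg.max_consecutive_incorrect:
        return Termination.CONSECUTIVE_INCORRECT
    if state.trial_index >= cfg.max_trials:
        return Termination.MAX_TRIALS
    if len(state.reversal_levels) >= cfg.target_reversals:
        return Termination.REVERSALS
    return None


def compute_jnd(reversal_levels, cfg: StaircaseConfig) -> float:
    """JND: arithmetic mean of the magnitudes of the last ``jnd_reversals`` reversals."""
    levels = [abs(x) for x in reversal_levels]
    if len(levels) < cfg.jnd_reversals:
        raise InsufficientReversalsError(
            f"need at least {cfg.jnd_reversals} reversals, got {len(levels)}"
        )
    return float(np.mean(levels[-cfg.jnd_reversals:]))


@dataclass(frozen=True)
class RunResult:
    jnd_st: float | None
    termination: Termination
    n_trials: int
    reversal_levels: tuple[float, ...]
    history: tuple[TrialRecord, ...]
    direction: str = ""
    training: bool = False

    def __post_init__(self) -> None:
        defined = self.termination == Termination.REVERSALS and not self.training
        if defined != (self.jnd_st is not None):
            raise ValueError("jnd_st must be present iff the run ended by reversals")
        if self.jnd_st is not None and self.jnd_st <= 0:
            raise ValueError("jnd_st must be positive")


def run_staircase(
    observer,
    cfg: StaircaseConfig,
    seed,
    direction: str = "",
    training: bool = False,
    n_training_trials: int = 6,
) -> RunResult:
    """Run one full adaptive track against a simulated observer.

    ``observer`` provides ``respond_odd_one_out(level_st, odd_interval, rng)``
    returning an interval in {1, 2, 3}. Each trial's odd interval is uniform
    on {1, 2, 3}. ``seed`` may be an int or a numpy SeedSequence/Generator.
    Training runs stop after ``n_training_trials`` scored trials and report
    the max-trials cause with no JND.
    """
    rng = np.random.default_rng(seed)
    state = new_state(cfg, training=training)
    if training:
        cfg = replace(cfg, max_trials=n_training_trials)
    records = []
    while True:
        odd = int(rng.integers(1, 4))
        presented_level = state.level_st
        response = int(observer.respond_odd_one_out(presented_level, odd, rng))
        correct = response == odd
        prev_reversals = len(state.reversal_levels)
        state = update(state, correct, cfg, training=training)
        records.append(
            TrialRecord(
                trial_index=state.trial_index,
                level_st=presented_level,
                odd_interval=odd,
                response_interval=response,
                correct=correct,
                was_reversal=len(state.reversal_levels) > prev_reversals,
            )
        )
        cause = check_termination(state, cfg)
        if cause is not None:
            state = replace(state, terminated=cause)
            break
    jnd = None
    if cause == Termination.REVERSALS and not training:
        jnd = compute_jnd(state.reversal_levels, cfg)
    return RunResult(
        jnd_st=jnd,
        termination=cause,
        n_trials=state.trial_index,
        reversal_levels=state.reversal_levels,
        history=tuple(records),
        direction=direction,
        training=training,
    )


def run_session(observer, seed, configs: dict[str, StaircaseConfig] | None = None):
    """One Experiment-I session: a 6-trial training run, then the four test
    runs (f0-, f0+, vtl+, vtl-) in seeded-random order.

    ``observer`` is either a single observer used for all cues or a mapping
    {"f0": observer, "vtl": observer}. Returns the list of RunResults,
    training first.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    directions = list(RUN_DIRECTIONS)
    order = [directions[i] for i in order_rng.permutation(len(directions))]

    def obs_for(cue: str):
        return observer[cue] if isinstance(observer, dict) else observer

    results = []
    child_seeds = ss.spawn(len(order) + 1)
    train_cue, train_start = RUN_DIRECTIONS[order[0]]
    train_cfg = StaircaseConfig(start_level_st=train_start)
    results.append(
        run_staircase(
            obs_for(train_cue), train_cfg, child_seeds[0],
            direction=f"training-{order[0]}", training=True,
        )
    )
    for i, d in enumerate(order):
        cue, start = RUN_DIRECTIONS[d]
        cfg = (configs or {}).get(d) or StaircaseConfig(start_level_st=start)
        results.append(run_staircase(obs_for(cue), cfg, child_seeds[i + 1], direction=d))
    return results


@dataclass(frozen=True)
class EncouragementState:
    """Adaptive scheduler for motivational feedback.

    Each trial a uniform draw below the threshold triggers encouragement and
    resets the threshold; an error without encouragement raises the threshold
    by one increment, so struggling listeners are encouraged sooner.
    """

    threshold: float = 0.1
    initial_threshold: float = 0.1
    increment: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.initial_threshold <= 1.0):
            raise ValueError("initial_threshold must be in (0, 1]")
        if self.threshold < self.initial_threshold:
            raise ValueError("threshold cannot fall below its initial value")


def encouragement_decision(
    state: EncouragementState, previous_correct: bool, draw: float
) -> tuple[bool, EncouragementState]:
    """Decide whether to encourage after a trial.

    ``draw`` is a uniform [0, 1) sample. Encourage iff draw < threshold;
    afterwards the threshold resets on encouragement, and otherwise grows by
    the increment if the previous response was incorrect.
    """
    give = draw < state.threshold
    if give:
        new_threshold = state.initial_threshold
    elif not previous_correct:
        new_threshold = min(1.0, state.threshold + state.increment)
    else:
        new_threshold = state.threshold
    return give, replace(state, threshold=new_threshold)
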