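import math

import numpy as np
import pytest
from scipy import stats

from voicecue.observers import SimulatedObserver
from voicecue.staircase import (
    EncouragementState,
    InsufficientReversalsError,
    RUN_DIRECTIONS,
    StaircaseConfig,
    StaircaseError,
    Termination,
    check_termination,
    compute_jnd,
    encouragement_decision,
    new_state,
    run_session,
    run_staircase,
    update,
)

SQRT2 = math.sqrt(2.0)


def reference_trace(pattern, start=-12.0, step=2.0, shrink=SQRT2, n_reversals_stop=8):
    """Independent re-derivation of the track for a fixed correct/incorrect
    pattern: straight-line arithmetic, no shared code with the engine.

    Shrink-at-reversal schedule: when a move reverses the previous direction,
    the level at the turn is logged and the step divides by sqrt(2) before
    the move is applied.
    """
    mag = abs(start)
    reversals = []
    streak = 0
    last = None
    trials = 0
    for correct in pattern * 200:
        trials += 1
        if correct:
            streak += 1
            if streak == 2:
                streak = 0
                if last == "up":
                    reversals.append(mag)
                    step = step / shrink
                mag = mag - step if mag - step > 0 else mag / 2
                last = "down"
        else:
            streak = 0
            if last == "down":
                reversals.append(mag)
                step = step / shrink
            mag = mag + step
            last = "up"
        if len(reversals) >= n_reversals_stop:
            return reversals, trials
    raise AssertionError("pattern never produced enough reversals")


class TestUpdateRule:
    def test_two_correct_step_down_literal_schedule(self):
        # under the literal per-down-step schedule the step shrinks with the move
        cfg = StaircaseConfig(start_level_st=-12.0, step_schedule="per_down_step")
        s = new_state(cfg)
        s = update(s, True, cfg)
        assert s.level_st == -12.0  # one correct is not enough
        s = update(s, True, cfg)
        assert s.level_st == pytest.approx(-10.0)
        assert s.step_st == pytest.approx(2.0 / SQRT2)

    def test_incorrect_after_two_correct_logs_reversal(self):
        cfg = StaircaseConfig(start_level_st=-12.0, step_schedule="per_down_step")
        s = new_state(cfg)
        for _ in range(2):
            s = update(s, True, cfg)
        assert s.magnitude == pytest.approx(10.0)
        step_before = s.step_st
        s = update(s, False, cfg)
        assert s.reversal_levels == (pytest.approx(10.0),)
        assert s.step_st == step_before  # errors never shrink this schedule
        assert s.magnitude == pytest.approx(10.0 + step_before)

    def test_sign_never_flips(self):
        cfg = StaircaseConfig(start_level_st=+5.0)
        s = new_state(cfg)
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = update(s, bool(rng.integers(2)), cfg)
            assert s.level_st > 0

    def test_update_after_termination_raises(self):
        cfg = StaircaseConfig()
        s = new_state(cfg)
        from dataclasses import replace

        s = replace(s, terminated=Termination.MAX_TRIALS)
        with pytest.raises(StaircaseError):
            update(s, True, cfg)

    def test_step_geometric_law_under_literal_schedule(self):
        cfg = StaircaseConfig(start_level_st=-12.0, step_schedule="per_down_step")
        s = new_state(cfg)
        for k in range(1, 6):
            s = update(update(s, True, cfg), True, cfg)
            assert s.step_st == pytest.approx(cfg.initial_step_st / SQRT2**k)

    def test_steps_non_increasing_default_schedule(self):
        cfg = StaircaseConfig(start_level_st=-12.0)
        s = new_state(cfg)
        rng = np.random.default_rng(1)
        prev = s.step_st
        for _ in range(500):
            s = update(s, bool(rng.integers(2)), cfg)
            assert s.step_st <= prev + 1e-12
            prev = s.step_st

    def test_magnitude_stays_positive_many_trials(self):
        # even an endless run of correct pairs can only approach 0 st
        cfg = StaircaseConfig(start_level_st=-12.0)
        s = new_state(cfg)
        rng = np.random.default_rng(2)
        for _ in range(100_000):
            s = update(s, bool(rng.random() < 0.8), cfg)
            assert s.magnitude > 0


class TestTermination:
    def test_consecutive_incorrect_rule(self):
        cfg = StaircaseConfig()
        s = new_state(cfg)
        for i in range(15):
            assert check_termination(s, cfg) is None
            s = update(s, False, cfg)
        assert check_termination(s, cfg) == Termination.CONSECUTIVE_INCORRECT
        assert s.trial_index == 15

    def test_no_rule_satisfied_returns_none(self):
        cfg = StaircaseConfig()
        s = new_state(cfg)
        from dataclasses import replace

        s = replace(s, trial_index=149, reversal_levels=tuple([3.0] * 7))
        assert check_termination(s, cfg) is None

    def test_precedence_consecutive_incorrect_first(self):
        cfg = StaircaseConfig(max_trials=10, max_consecutive_incorrect=10)
        s = new_state(cfg)
        from dataclasses import replace

        s = replace(s, trial_index=10, consecutive_incorrect=10, reversal_levels=tuple([1.0] * 8))
        assert check_termination(s, cfg) == Termination.CONSECUTIVE_INCORRECT


class TestComputeJnd:
    def test_mean_of_last_six(self):
        cfg = StaircaseConfig()
        revs = [6, 5, 4, 3.5, 3, 3.2, 2.9, 3.4]
        assert compute_jnd(revs, cfg) == pytest.approx(np.mean([4, 3.5, 3, 3.2, 2.9, 3.4]))

    def test_constant_reversals(self):
        assert compute_jnd([2.0] * 8, StaircaseConfig()) == pytest.approx(2.0)

    def test_too_few_reversals(self):
        with pytest.raises(InsufficientReversalsError):
            compute_jnd([1, 2, 3, 4, 5], StaircaseConfig())


class TestRunStaircase:
    def test_always_correct_ends_at_trial_budget(self, scripted_observer_factory):
        res = run_staircase(scripted_observer_factory([True]), StaircaseConfig(), seed=0)
        assert res.termination == Termination.MAX_TRIALS
        assert res.n_trials == 150
        assert res.jnd_st is None
        levels = [abs(r.level_st) for r in res.history]
        assert all(b <= a + 1e-12 for a, b in zip(levels, levels[1:]))

    def test_always_incorrect_ends_after_15(self, scripted_observer_factory):
        res = run_staircase(scripted_observer_factory([False]), StaircaseConfig(), seed=0)
        assert res.termination == Termination.CONSECUTIVE_INCORRECT
        assert res.n_trials == 15

    def test_alternating_pattern_matches_hand_trace(self, scripted_observer_factory):
        pattern = [True, True, False]
        res = run_staircase(scripted_observer_factory(pattern), StaircaseConfig(), seed=0)
        expected_revs, expected_trials = reference_trace(pattern)
        assert res.termination == Termination.REVERSALS
        assert len(res.reversal_levels) == 8
        np.testing.assert_allclose(res.reversal_levels, expected_revs, rtol=1e-12)
        assert res.n_trials == expected_trials
        assert res.jnd_st == pytest.approx(np.mean(expected_revs[-6:]))

    def test_termination_trichotomy_and_jnd_definedness(self):
        obs = SimulatedObserver(threshold_st=2.0)
        for seed in range(40):
            res = run_staircase(obs, StaircaseConfig(), seed=seed)
            assert res.termination in set(Termination)
            assert (res.jnd_st is not None) == (res.termination == Termination.REVERSALS)
            if res.jnd_st is not None:
                assert res.jnd_st > 0

    def test_seeded_determinism(self):
        obs = SimulatedObserver(threshold_st=2.0)
        a = run_staircase(obs, StaircaseConfig(), seed=123)
        b = run_staircase(obs, StaircaseConfig(), seed=123)
        assert a.history == b.history


class TestRunSession:
    def test_structure_training_plus_four_runs(self):
        obs = SimulatedObserver(threshold_st=2.0)
        results = run_session(obs, seed=5)
        assert len(results) == 5
        assert results[0].training and results[0].n_trials == 6
        directions = {r.direction for r in results[1:]}
        assert directions == set(RUN_DIRECTIONS)

    def test_training_step_fixed_at_3st(self):
        obs = SimulatedObserver(threshold_st=2.0)
        training = run_session(obs, seed=5)[0]
        moves = np.abs(np.diff([abs(r.level_st) for r in training.history]))
        assert np.all(np.isin(np.round(moves[moves > 0], 9), [3.0]))

    def test_session_determinism(self):
        obs = SimulatedObserver(threshold_st=2.0)
        a = run_session(obs, seed=11)
        b = run_session(obs, seed=11)
        assert [r.history for r in a] == [r.history for r in b]


class TestConvergence:
    def test_two_down_one_up_targets_707(self):
        obs = SimulatedObserver(threshold_st=2.0, slope=3.0, lapse_rate=0.0)
        cfg = StaircaseConfig(start_level_st=-12.0)
        jnds = [run_staircase(obs, cfg, seed=s).jnd_st for s in range(500)]
        jnds = [j for j in jnds if j is not None]
        assert len(jnds) >= 490
        p = float(obs.p_correct(np.mean(jnds)))
        assert p == pytest.approx(0.707, abs=0.02)

    def test_jnd_monotone_in_true_threshold(self):
        thresholds = [0.5, 1.0, 2.0, 4.0, 6.0]
        mean_jnds = []
        for thr in thresholds:
            obs = SimulatedObserver(threshold_st=thr, slope=3.0, lapse_rate=0.0)
            cfg = StaircaseConfig(start_level_st=-12.0)
            jnds = [run_staircase(obs, cfg, seed=s).jnd_st for s in range(200)]
            mean_jnds.append(np.mean([j for j in jnds if j is not None]))
        rho = stats.spearmanr(thresholds, mean_jnds).statistic
        assert rho > 0.95


class TestEncouragement:
    def test_fresh_state_small_draw_triggers(self):
        give, state = encouragement_decision(EncouragementState(), True, draw=0.05)
        assert give and state.threshold == 0.1

    def test_fresh_state_large_draw_no_change_after_correct(self):
        give, state = encouragement_decision(EncouragementState(), True, draw=0.95)
        assert not give and state.threshold == 0.1

    def test_threshold_grows_linearly_with_unrewarded_errors(self):
        state = EncouragementState()
        for k in range(1, 6):
            give, state = encouragement_decision(state, False, draw=0.99)
            assert not give
            assert state.threshold == pytest.approx(0.1 + 0.05 * k)

    def test_reset_after_encouragement(self):
        state = EncouragementState(threshold=0.3)
        give, state = encouragement_decision(state, False, draw=0.2)
        assert give and state.threshold == 0.1

    def test_trigger_rate_matches_fresh_threshold(self):
        rng = np.random.default_rng(7)
        gives = [encouragement_decision(EncouragementState(), True, rng.random())[0] for _ in range(10_000)]
        assert np.mean(gives) == pytest.approx(0.1, abs=0.01)
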