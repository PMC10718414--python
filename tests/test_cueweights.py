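import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voicecue.cueweights import (
    denormalize_cues,
    fit_cue_weights,
    normalize_cues,
    to_berkson_per_st,
)
from voicecue.gender import build_test_block, run_gender_block, trials_to_frame
from voicecue.manipulation import VoiceManipulation
from voicecue.observers import sample_participant_panel


def simulate_panel_trials(n_participants=28, seed=0, **panel_kw):
    panel = sample_participant_panel(n_participants, seed=1234, **panel_kw)
    block = build_test_block(with_audio=False)
    frames = [
        trials_to_frame(run_gender_block(p, block, np.random.SeedSequence(seed, spawn_key=(i,))))
        for i, p in enumerate(panel)
    ]
    return pd.concat(frames, ignore_index=True)


class TestNormalization:
    @pytest.mark.parametrize(
        "manip, expected",
        [
            (VoiceManipulation(0.0, 0.0), (-0.5, -0.5)),
            (VoiceManipulation(-12.0, +3.6), (+0.5, +0.5)),
            (VoiceManipulation(-6.0, +1.8), (0.0, 0.0)),
        ],
    )
    def test_printed_mappings(self, manip, expected):
        cue = normalize_cues(manip)
        assert (cue.dF0_norm, cue.dVTL_norm) == pytest.approx(expected)

    @given(
        st.floats(min_value=-24, max_value=24),
        st.floats(min_value=-12, max_value=12),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_affine_round_trip_exact(self, df0, dvtl):
        manip = VoiceManipulation(df0, dvtl)
        back = denormalize_cues(normalize_cues(manip))
        assert back.delta_f0_st == pytest.approx(df0, abs=1e-12)
        assert back.delta_vtl_st == pytest.approx(dvtl, abs=1e-12)


class TestBerksonConversion:
    def test_f0_unit_identity(self):
        assert to_berkson_per_st(12.0 * math.log(2.0), "F0") == pytest.approx(1.0)

    def test_vtl_unit_identity(self):
        assert to_berkson_per_st(3.6 * math.log(2.0), "VTL") == pytest.approx(1.0)

    def test_zero_maps_to_zero(self):
        assert to_berkson_per_st(0.0, "F0") == 0.0

    def test_rejects_unknown_cue_and_nan(self):
        with pytest.raises(ValueError):
            to_berkson_per_st(1.0, "loudness")
        with pytest.raises(ValueError):
            to_berkson_per_st(float("nan"), "F0")


class TestFit:
    @pytest.mark.parametrize("beta", [2.0, 4.0, 6.0])
    def test_recovers_population_betas(self, beta):
        # recovery is a statement about estimator bias, so it is checked on
        # the fit averaged over replicate panels at the same sample geometry
        fits = [
            fit_cue_weights(
                simulate_panel_trials(
                    mean_beta0=0.5, mean_beta_f0=beta, mean_beta_vtl=beta,
                    seed=100 * int(beta) + rep,
                ),
                method="mixed",
            )
            for rep in range(5)
        ]
        assert np.mean([f.coef_f0_logit for f in fits]) == pytest.approx(beta, rel=0.15)
        assert np.mean([f.coef_vtl_logit for f in fits]) == pytest.approx(beta, rel=0.15)
        assert not any(f.separation_flag for f in fits)

    def test_berkson_weights_consistent_with_logits(self):
        df = simulate_panel_trials(mean_beta_f0=4.0, mean_beta_vtl=4.0, seed=2)
        fit = fit_cue_weights(df)
        assert fit.weight_f0_bk_per_st == pytest.approx(
            fit.coef_f0_logit / (math.log(2) * 12.0)
        )
        assert fit.weight_vtl_bk_per_st == pytest.approx(
            fit.coef_vtl_logit / (math.log(2) * 3.6)
        )

    def test_null_data_centred_on_zero(self):
        df = simulate_panel_trials(mean_beta_f0=0.0, mean_beta_vtl=0.0, seed=3)
        fit = fit_cue_weights(df)
        assert abs(fit.coef_f0_logit) < 0.3
        assert abs(fit.coef_vtl_logit) < 0.3

    def test_all_female_raises_separation_flag(self):
        df = simulate_panel_trials(mean_beta0=-1e3, seed=4)
        assert set(df.response) == {"female"}
        fit = fit_cue_weights(df)
        assert fit.separation_flag

    def test_single_cue_level_is_rank_deficient(self):
        df = simulate_panel_trials(seed=5)
        df["dVTL_norm"] = 0.0
        with pytest.raises(ValueError, match="single level"):
            fit_cue_weights(df)

    def test_fewer_than_two_participants_rejected(self):
        df = simulate_panel_trials(n_participants=2, seed=6)
        solo = df[df.participant_id == df.participant_id.iloc[0]]
        with pytest.raises(ValueError, match="participants"):
            fit_cue_weights(solo)

    def test_two_stage_agrees_with_mixed_at_moderate_effect(self):
        df = simulate_panel_trials(mean_beta_f0=3.0, mean_beta_vtl=3.0, seed=7)
        mixed = fit_cue_weights(df, method="mixed")
        two = fit_cue_weights(df, method="two_stage")
        assert two.coef_f0_logit == pytest.approx(mixed.coef_f0_logit, rel=0.35)

    def test_per_participant_table_shape(self):
        df = simulate_panel_trials(sd_beta_f0=1.0, sd_beta_vtl=1.0, seed=8)
        fit = fit_cue_weights(df)
        assert len(fit.per_participant) == 28
        assert {"coef_f0_logit", "weight_f0_bk_per_st"} <= set(fit.per_participant.columns)

    def test_monotone_in_generating_beta(self):
        estimates = []
        for beta in (1.0, 3.0, 5.0):
            df = simulate_panel_trials(mean_beta_f0=beta, mean_beta_vtl=2.0, seed=10)
            estimates.append(fit_cue_weights(df).weight_f0_bk_per_st)
        assert estimates[0] < estimates[1] < estimates[2]

    def test_deterministic_given_data(self):
        df = simulate_panel_trials(seed=11)
        a = fit_cue_weights(df)
        b = fit_cue_weights(df)
        assert a.coef_f0_logit == b.coef_f0_logit
        assert a.coef_vtl_logit == b.coef_vtl_logit
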