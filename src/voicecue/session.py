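"""End-to-end simulated sessions: training, four JND runs, gender block.

One session reproduces the structure of the full two-experiment battery for
``n_participants`` simulated listeners: a 6-trial training staircase, the
four adaptive JND runs (two F0 directions, two VTL directions) in
per-participant random order, then the 8-stimulus gender training block and
the 36-stimulus gender test block, finishing with the population cue-weight
fit. All artifacts are written as CSV trial logs plus a JSON summary.

Randomness policy: one master seed spawns per-participant seed sequences via
``SeedSequence(master, spawn_key=(participant_index,))``, so adding
participants never perturbs the trials of earlier ones, and a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cueweights import fit_cue_weights
from .gender import build_test_block, build_training_block, run_gender_block, trials_to_frame
from .observers import SimulatedObserver, sample_participant_panel
from .staircase import RUN_DIRECTIONS, StaircaseConfig, run_session as run_staircase_session

__all__ = ["SessionConfig", "run_full_session", "staircase_logs_to_frame"]


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of a full simulated session."""

    seed: int = 0
    n_participants: int = 1
    output_dir: str | Path | None = None
    # JND-task observer population (per-cue thresholds in semitones)
    observer_threshold_f0_st: float = 1.6
    observer_threshold_vtl_st: float = 1.7
    observer_slope: float = 3.0
    observer_lapse_rate: float = 0.02
    # gender-responder population
    responder_mean_beta0: float = 0.5
    responder_mean_beta_f0: float = 4.0
    responder_mean_beta_vtl: float = 4.0
    responder_sd_beta0: float = 0.5
    responder_sd_beta_f0: float = 1.0
    responder_sd_beta_vtl: float = 1.0
    fit_method: str = "mixed"
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        for name in (
            "observer_threshold_f0_st", "observer_threshold_vtl_st",
            "observer_slope",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "SessionConfig":
        obj = json.loads(Path(path).read_text())
        staircase = StaircaseConfig(**obj.pop("staircase", {}))
        try:
            return cls(staircase=staircase, **obj)
        except TypeError as exc:
            raise ValueError(f"invalid session config: {exc}") from exc


def staircase_logs_to_frame(results, participant_id: str) -> pd.DataFrame:
    """Flatten a participant's staircase runs into one trial-log table."""
    rows = []
    for run_idx, res in enumerate(results):
        for rec in res.history:
            rows.append(
                {
                    "participant_id": participant_id,
                    "run_id": run_idx,
                    "direction": res.direction,
                    "training": res.training,
                    "trial": rec.trial_index,
                    "level_st": rec.level_st,
                    "odd_interval": rec.odd_interval,
                    "response": rec.response_interval,
                    "correct": rec.correct,
                    "reversal": rec.was_reversal,
                }
            )
    return pd.DataFrame(rows)


def run_full_session(cfg: SessionConfig) -> dict:
    """Run the complete simulated battery and return the session report.

    The report dict contains per-participant JNDs by direction, the gender
    trial table, and the population cue-weight fit; with ``cfg.output_dir``
    set, CSV logs and a JSON summary are also written there.
    """
    panel = sample_participant_panel(
        cfg.n_participants,
        mean_beta0=cfg.responder_mean_beta0,
        mean_beta_f0=cfg.responder_mean_beta_f0,
        mean_beta_vtl=cfg.responder_mean_beta_vtl,
        sd_beta0=cfg.responder_sd_beta0,
        sd_beta_f0=cfg.responder_sd_beta_f0,
        sd_beta_vtl=cfg.responder_sd_beta_vtl,
        seed=np.random.SeedSequence(cfg.seed, spawn_key=(0xFACE,)),
    )
    gender_test = build_test_block(with_audio=False)
    gender_training = build_training_block(with_audio=False)

    jnd_rows = []
    staircase_logs = []
    gender_frames = []
    for idx, responder in enumerate(panel):
        pid = responder.participant_id
        pseq = np.random.SeedSequence(cfg.seed, spawn_key=(idx,))
        s_stair, s_gtrain, s_gtest = pseq.spawn(3)
        observers = {
            "f0": SimulatedObserver(
                threshold_st=cfg.observer_threshold_f0_st,
                slope=cfg.observer_slope,
                lapse_rate=cfg.observer_lapse_rate,
            ),
            "vtl": SimulatedObserver(
                threshold_st=cfg.observer_threshold_vtl_st,
                slope=cfg.observer_slope,
                lapse_rate=cfg.observer_lapse_rate,
            ),
        }
        configs = {
            d: dataclasses.replace(cfg.staircase, start_level_st=start)
            for d, (_, start) in RUN_DIRECTIONS.items()
        }
        results = run_staircase_session(observers, s_stair, configs=configs)
        staircase_logs.append(staircase_logs_to_frame(results, pid))
        for res in results:
            if not res.training:
                jnd_rows.append(
                    {
                        "participant_id": pid,
                        "direction": res.direction,
                        "jnd_st": res.jnd_st,
                        "termination": res.termination.value,
                        "n_trials": res.n_trials,
                    }
                )
        # gender task: training block responses are collected but not analysed
        run_gender_block(responder, gender_training, s_gtrain)
        gender_frames.append(trials_to_frame(run_gender_block(responder, gender_test, s_gtest)))

    jnd_table = pd.DataFrame(jnd_rows)
    gender_table = pd.concat(gender_frames, ignore_index=True)
    fit = fit_cue_weights(gender_table, method=cfg.fit_method)

    summary = {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "jnd_mean_by_direction": (
            jnd_table.dropna(subset=["jnd_st"]).groupby("direction")["jnd_st"].mean().to_dict()
        ),
        "cue_weight_fit": fit.to_dict(),
    }
    report = {
        "jnd_table": jnd_table,
        "gender_table": gender_table,
        "staircase_log": pd.concat(staircase_logs, ignore_index=True),
        "cue_weight_fit": fit,
        "summary": summary,
    }

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            report["staircase_log"].to_csv(out / "staircase_trials.csv", index=False)
            jnd_table.to_csv(out / "jnd_results.csv", index=False)
            gender_table.to_csv(out / "gender_trials.csv", index=False)
            fit.per_participant.to_csv(out / "cue_weights_per_participant.csv", index=False)
            (out / "session_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        except OSError as exc:
            raise OSError(f"cannot write session outputs to {out}: {exc}") from exc
    return report
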