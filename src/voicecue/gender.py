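"""Voice-gender categorisation task (Experiment II protocol).

Four test words are each rendered in nine voice conditions — the full cross
of ΔF0 ∈ {0, −6, −12} st and ΔVTL ∈ {0, +1.8, +3.6} st relative to the
female reference voice — giving a 36-stimulus test block. Training uses the
same four words at the two perceptual extremes only: the unmodified
reference (0, 0) and the most male-typical condition (−12, +3.6). Stimuli
are RMS-equalised and every condition, including (0, 0), passes through the
resynthesis backend so all share the same vocoder artefacts.

A block run presents each stimulus exactly once in seeded-random order and
records a binary male/female response from a simulated responder driven by
the stimulus's normalised cue values. There is no correctness here: gender
categorisation is a subjective judgement, so the task has no feedback
concept at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioToken, rms_equalize
from .cueweights import normalize_cues
from .manipulation import ReferenceVoiceSpec, VoiceManipulation, apply_manipulation
from .observers import GenderResponder
from .stimuli import GENDER_WORDS, gender_word_inventory

__all__ = [
    "F0_GRID_ST",
    "VTL_GRID_ST",
    "GenderStimulus",
    "CategorisationTrial",
    "build_test_block",
    "build_training_block",
    "run_gender_block",
    "trials_to_frame",
]

F0_GRID_ST = (0.0, -6.0, -12.0)
VTL_GRID_ST = (0.0, +1.8, +3.6)
TRAINING_CONDITIONS = (VoiceManipulation(0.0, 0.0), VoiceManipulation(-12.0, +3.6))
DEFAULT_RMS = 0.05


@dataclass(frozen=True)
class GenderStimulus:
    word: str
    manip: VoiceManipulation
    audio: AudioToken | None = None

    def __post_init__(self) -> None:
        if self.manip.delta_f0_st not in F0_GRID_ST or self.manip.delta_vtl_st not in VTL_GRID_ST:
            raise ValueError(
                f"manipulation {self.manip} outside the task grid "
                f"F0 {F0_GRID_ST} x VTL {VTL_GRID_ST}"
            )


@dataclass(frozen=True)
class CategorisationTrial:
    stimulus: GenderStimulus
    response: str
    participant_id: str
    presentation_index: int

    def __post_init__(self) -> None:
        if self.response not in ("male", "female"):
            raise ValueError("response must be 'male' or 'female'")


def _render(
    words: list[AudioToken],
    conditions: list[VoiceManipulation],
    with_audio: bool,
    ref: ReferenceVoiceSpec,
    target_rms: float,
) -> list[GenderStimulus]:
    if with_audio:
        words = rms_equalize(words, target_rms)
    stimuli = []
    for manip in conditions:
        for word in words:
            audio = None
            if with_audio:
                audio = apply_manipulation(word, manip, ref)
                audio = rms_equalize([audio], target_rms)[0]
            stimuli.append(GenderStimulus(word=word.label, manip=manip, audio=audio))
    return stimuli


def build_test_block(
    words: list[AudioToken] | None = None,
    with_audio: bool = True,
    ref: ReferenceVoiceSpec | None = None,
    target_rms: float = DEFAULT_RMS,
) -> list[GenderStimulus]:
    """The 36-stimulus test block: full 3x3 condition grid x 4 words.

    ``with_audio=False`` skips resynthesis and returns metadata-only stimuli
    (sufficient for response simulation, which depends only on the cues).
    """
    words = words if words is not None else gender_word_inventory()
    if len(words) != len({w.label for w in words}):
        raise ValueError("word inventory has duplicate labels")
    conditions = [VoiceManipulation(f0, vtl) for f0 in F0_GRID_ST for vtl in VTL_GRID_ST]
    return _render(words, conditions, with_audio, ref or ReferenceVoiceSpec(), target_rms)


def build_training_block(
    words: list[AudioToken] | None = None,
    with_audio: bool = True,
    ref: ReferenceVoiceSpec | None = None,
    target_rms: float = DEFAULT_RMS,
) -> list[GenderStimulus]:
    """The 8-stimulus training block: 4 words x the two widest conditions."""
    words = words if words is not None else gender_word_inventory()
    return _render(words, list(TRAINING_CONDITIONS), with_audio, ref or ReferenceVoiceSpec(), target_rms)


def run_gender_block(
    participant: GenderResponder,
    block: list[GenderStimulus],
    seed,
    randomize_response_mapping: bool = True,
) -> list[CategorisationTrial]:
    """Present a block once in seeded-random order and collect categorisations.

    The optional response-mapping randomisation emulates re-assigning the two
    response effectors (e.g. left/right hand) to genders on every trial; it
    consumes randomness but by construction never alters the recorded
    semantic (male/female) response.
    """
    if not block:
        raise ValueError("block must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(block))
    trials = []
    for pos, idx in enumerate(order):
        stim = block[idx]
        cue = normalize_cues(stim.manip)
        if randomize_response_mapping:
            mapping_male_is_left = bool(rng.integers(2))  # noqa: F841 - consumes the draw only
        response = participant.respond_gender(cue.dF0_norm, cue.dVTL_norm, rng)
        trials.append(
            CategorisationTrial(
                stimulus=stim,
                response=response,
                participant_id=participant.participant_id or "p001",
                presentation_index=pos,
            )
        )
    return trials


def trials_to_frame(trials: list[CategorisationTrial]) -> pd.DataFrame:
    """Flatten trials into the tabular trial-log layout used on disk."""
    rows = []
    for t in trials:
        cue = normalize_cues(t.stimulus.manip)
        rows.append(
            {
                "participant_id": t.participant_id,
                "word": t.stimulus.word,
                "delta_f0_st": t.stimulus.manip.delta_f0_st,
                "delta_vtl_st": t.stimulus.manip.delta_vtl_st,
                "dF0_norm": cue.dF0_norm,
                "dVTL_norm": cue.dVTL_norm,
                "response": t.response,
                "presentation_index": t.presentation_index,
            }
        )
    return pd.DataFrame(rows)
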