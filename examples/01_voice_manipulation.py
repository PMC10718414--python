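"""Manipulate F0 and vocal-tract length of a synthetic vowel.

Builds a flat 200 Hz vowel, resynthesises it at the 242 Hz reference voice,
then applies the extreme male-typical manipulation (-12 st F0, +3.6 st VTL)
and measures what actually changed in the audio.
"""

import numpy as np

from voicecue import (
    ReferenceVoiceSpec,
    VoiceManipulation,
    apply_manipulation,
    estimate_formant_shift_ratio,
    extract_f0_contour,
    synth_vowel,
    vtl_to_formant_ratio,
)

vowel = synth_vowel("a", duration_ms=300.0, f0_hz=200.0)
ref = ReferenceVoiceSpec(reference_f0_hz=242.0)

reference = apply_manipulation(vowel, VoiceManipulation(0, 0), ref)
male = apply_manipulation(vowel, VoiceManipulation(-12.0, +3.6), ref)

print(f"input median F0:       {np.median(extract_f0_contour(vowel)):7.2f} Hz")
print(f"reference resynthesis: {np.median(extract_f0_contour(reference)):7.2f} Hz  (target 242)")
print(f"male-typical voice:    {np.median(extract_f0_contour(male)):7.2f} Hz  (target 121, one octave down)")

ratio = estimate_formant_shift_ratio(reference, male)
print(f"formant shift ratio:   {ratio:.4f}  (expected {vtl_to_formant_ratio(3.6):.4f} for +3.6 st VTL)")
print()
print("A ratio below 1 means the spectral envelope moved down in frequency —")
print("the acoustic signature of a longer vocal tract, i.e. a larger talker.")
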