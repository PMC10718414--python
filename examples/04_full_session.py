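"""Run the complete two-experiment battery end to end.

Three simulated participants each complete training, the four adaptive JND
runs, and the gender-categorisation blocks; all trial logs land in
./session_output as CSV plus a JSON summary.
"""

import json

from voicecue import SessionConfig, run_full_session

cfg = SessionConfig(seed=1, n_participants=3, output_dir="session_output")
report = run_full_session(cfg)

print(json.dumps(report["summary"], indent=2, sort_keys=True))
print()
print("jnd_mean_by_direction: mean estimated JND (st) per staircase direction.")
print("cue_weight_fit: population cue weights (Bk/st) from the mixed fit over")
print("all participants' 36 gender trials. Full logs: ./session_output/")
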