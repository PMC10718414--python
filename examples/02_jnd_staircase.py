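"""Estimate a voice-cue JND with the adaptive 2-down-1-up staircase.

A simulated listener with a true threshold of 1.6 st runs the four-direction
battery (two F0 directions, two VTL directions) preceded by a short training
run, exactly as a human participant would.
"""

from voicecue import SimulatedObserver, run_session

observer = SimulatedObserver(threshold_st=1.6, slope=3.0, lapse_rate=0.02)
results = run_session(observer, seed=2024)

print("run        trials  reversals  JND (st)")
for res in results:
    jnd = "   --" if res.jnd_st is None else f"{res.jnd_st:6.3f}"
    name = res.direction.ljust(14)
    print(f"{name}{res.n_trials:5d}  {len(res.reversal_levels):9d}  {jnd}")

print()
print("Each test run converges on the ~70.7%-correct level of the listener's")
print("psychometric function; the JND is the mean of the last six reversal")
print("levels, so values near the generating 1.6 st threshold are expected.")
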