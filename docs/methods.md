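# Methods

This note documents the models implemented in `voicecue`, the defaults and
why they were chosen, the numerical choices that matter, and what the
simulated battery can and cannot say about real listeners.

## Voice manipulations

A voice condition is a pair (ΔF0, ΔVTL) of semitone offsets against a
reference voice. Semitones are 1/12 of an octave: a frequency ratio *r*
equals 12·log₂(r) st. F0 manipulation rescales the extracted pitch contour
multiplicatively so that its summary statistic over voiced frames equals
`reference_f0_hz · 2^(ΔF0/12)`; the reference F0 defaults to 242 Hz, a
typical adult female voice. The matching statistic defaults to the **mean**
of the voiced contour (consistent with mean-based corpus bookkeeping of
female speech averaging ~248 Hz) and can be switched to the median;
unvoiced frames carry F0 = 0 and are excluded.

VTL manipulation is a uniform scaling of the spectral-envelope frequency
axis by `2^(−ΔVTL/12)`: a longer vocal tract (positive ΔVTL) moves all
formants down by that ratio. Envelope warping is implemented as
`E'(f) = E(f / ratio)` with the last envelope value held where the source
frequency exceeds Nyquist. F0 is applied before VTL, and the unmodified
(0, 0) condition still passes through full analysis/resynthesis so that all
conditions share the same vocoder artefacts.

## The harmonic vocoder

The analysis/resynthesis backend is a minimal source-filter vocoder written
on numpy/scipy:

* **F0 tracking** — per-frame normalized autocorrelation (40 ms frames,
  10 ms hop, search band 60–500 Hz) with parabolic interpolation of the peak
  lag; a frame is voiced when the normalized peak exceeds 0.45 and frame
  energy exceeds 1 % of token RMS. On a flat synthetic vowel this resolves
  F0 to well under 0.1 Hz.
* **Envelope** — for voiced frames, harmonic amplitudes are picked from the
  4096-point magnitude spectrum at multiples of the frame F0 and
  interpolated piecewise-linearly in log magnitude; unvoiced frames use a
  250 Hz moving-average smoothed spectrum.
* **Resynthesis** — voiced spans are rebuilt by additive synthesis
  (per-sample phase accumulation of all harmonics below Nyquist, amplitudes
  read off the possibly warped envelope); unvoiced spans as envelope-shaped
  white noise with windowed overlap-add. Output length equals input length
  exactly.

Because the envelope is only observed at harmonics, formant localisation
from a single token is limited to roughly the harmonic spacing. The
measurement helper `estimate_formant_shift_ratio` therefore recovers VTL
scaling by cross-correlating two tokens' log envelopes on a log-frequency
grid (0.005 log₂ units ≈ 0.06 st resolution), using per-window Pearson
normalisation — without it the steep spectral tilt drags the correlation
peak toward zero lag. Verified end-to-end, a +3.6 st VTL change on a 110 Hz
vowel measures 0.8127 against the analytic 0.8123.

## Synthetic stimuli

Tokens are synthesised, not recorded: a periodic glottal-like source
(harmonics rolling off ≈ −6 dB/oct) drives a cascade of three second-order
formant resonators (female-typical formant targets, bandwidths 90/110/170
Hz). CV syllables draw durations uniformly from 142–200 ms and F0 from
220–270 Hz; triplets concatenate three distinct inventory syllables. The
four gender-task words ("bike", "pool", "watch", "hat") are fixed 350 ms
CVC-like tokens. Everything is a pure function of (parameters, seed).

What this emulates: voiced, formant-bearing speech tokens of the right
durations and pitch range. What it does not: English phonetics, speaker
idiosyncrasy, coarticulation, recording-channel effects. Tests passing on
these tokens validate the algorithms, not vocoder quality on real speech.

## Staircase engine

The 3I-3AFC task presents three intervals, one (uniformly random) carrying
the manipulated voice; chance is 1/3. The 2-down-1-up rule decreases the
cue-difference magnitude after two consecutive correct responses and
increases it after one error, converging on p = √0.5 ≈ 70.7 % correct. Runs
start at −12/+5 st (F0) or +3.8/−7.0 st (VTL); the sign is the run
direction and never flips. The initial step is 2 st. Termination, in order
of precedence: 15 consecutive errors, 150 trials, or 8 reversals; only the
last defines a JND (mean magnitude of the last six reversals). A reversal
is an error after ≥ 2 correct responses or two correct responses after
≥ 1 error; the magnitude logged is the level at which the turn occurred,
before the reversing step is applied.

**Step-shrink schedule.** The step divides by √2 **at each reversal of the
track** (`step_schedule="per_reversal"`, the standard transformed up-down
practice). The superficially plausible alternative — shrinking on every
down-step — is kept as `"per_down_step"` for comparison but is degenerate
as a default: its total possible descent is the geometric sum
2/(1 − 1/√2) ≈ 6.83 st, so a track starting 12 st out can never approach a
small threshold (measured convergence ~94 % correct, with frequent
150-trial timeouts). Under the per-reversal schedule the simulated
convergence point sits at 71–73 % correct for thresholds of 1–3 st, which
is the intended operating range. This schedule shrinks the step at
up-reversals too, a mild extension of "the step only adapts with correct
responses"; shrinking at down-reversals only was measured to converge worse
(76–81 %).

Guards where the protocol is silent: the magnitude is capped at 1.5× the
start level after up-steps (unbounded growth is physically meaningless for
VTL; events are counted), a down-step that would cross zero halves the
magnitude instead (the level approaches but never reaches 0 st), and the
step has a 0.05 st floor against floating-point underflow. Training runs
use a fixed 3 st step, six trials, no JND, and the start level of whichever
test run was randomised first.

The encouragement scheduler draws uniform [0, 1) each trial: a draw below
the threshold (initially 0.1) triggers encouragement and resets the
threshold; each error without encouragement raises it by 0.05, so
struggling listeners are encouraged sooner.

## Simulated listeners

The odd-one-out observer responds correctly with
p(|L|) = 1/3 + (2/3 − λ)·F(|L|), where F is logistic in log₂|L| with
midpoint `threshold_st` and slope 3 (log-scaled because pitch/VTL
discrimination is ratio-scaled; a Weibull alternative is available). The
default lapse rate λ = 0.02 and slope 3 are free modelling choices — no
human psychometric slopes are available for this battery — so recovery
tests state their own generative truths. Wrong responses distribute
uniformly over the two remaining intervals.

The gender responder answers "male" with probability
σ(β₀ + β_F0·δF0 + β_VTL·δVTL). Panels draw responder betas from a normal
population; session defaults (β_F0 = β_VTL = 4, SDs 1) put both cue weights
near 0.5 Bk/st for F0 and 1.6 Bk/st for VTL — the right order of magnitude
for normal-hearing adults — while remaining comfortably estimable from
36 trials/listener.

## Cue-weight analysis

Cues are normalised as δF0 = −ΔF0/12 − 0.5 and δVTL = ΔVTL/3.6 − 0.5, an
exact affine map sending the reference voice to (−0.5, −0.5) and the
extreme male-typical condition to (+0.5, +0.5). The primary fit is a
mixed-effects logistic regression — population intercept and slopes plus
participant-level random slope deviations for both cues — via the
variational-Bayes binomial mixed GLM in statsmodels, with an explicit
deterministic starting point (the library's default start is randomised;
fixing it makes the fit a pure function of the data). The model formula in
the source protocol lists only the random-slope term; population-level
fixed effects are included here because population cue weights and
intercept biases are the reported quantities. Two fallbacks exist behind
the `method` flag: a pooled logistic fit and a two-stage per-participant
fit aggregated by means. One-sided or separated data trigger a weakly
ridge-penalised fit (C = 10) and set `separation_flag`.

Slope-to-weight conversion: a logit coefficient is natural-log odds per
full normalised cue range, so Berkson (log₂ odds) units per semitone are
`coef / (ln 2 · span_st)` with span 12 st (F0) or 3.6 st (VTL). The
intercept is reported at the grid midpoint δ = (0, 0) and, via
`intercept_at_reference`, re-expressed at the reference voice
(−0.5, −0.5), where it measures the bias toward hearing the unmodified
voice as female; the underlying convention of the prior literature is not
restated in the source protocol, so this reconstruction is flagged here
deliberately.

At the battery's sample geometry (28 participants × 36 trials) the mixed
fit recovers generating population slopes in [2, 6] within a few percent
when averaged over replicate panels, and is centred on zero under null
data; single panels scatter around the truth with a standard error of
roughly 0.2–0.3 logit units.

## Sessions, seeding, problem sizes

A full session per participant: 6-trial training, the four JND runs in
seeded-random order, the 8-stimulus gender training block, the 36-stimulus
test block, then the population cue-weight fit. One master seed spawns
per-participant sequences via `SeedSequence(master, spawn_key=(index,))`,
so adding participants never changes earlier ones and reruns are
byte-identical.

Simulation sizes used by the test suite and the acceptance script — 500
staircase runs for the convergence estimate, 200 runs per point of the
5-point threshold grid for monotonicity, and 5 replicate panels per effect
size for recovery — were chosen as the smallest sizes at which the
Monte-Carlo error is clearly below the tolerance being checked.

## Known limitations

* The vocoder is built for controllable, measurable manipulations, not
  perceptual quality; it has no aspiration noise model and a crude
  voiced/unvoiced decision.
* Simulated listeners are stationary: no learning, fatigue, attention
  drift, or interface-induced bias, so between-interface comparisons of the
  original human study have no analogue here.
* The 2-down-1-up converged level is a slightly biased estimator of the
  70.7 % point at finite step sizes; at the battery's settings the bias is
  within ±2 percentage points for thresholds in the 1–3 st range and grows
  with the threshold-to-start-level ratio.
* Human results (JNDs, human cue weights, test durations) cannot be
  reproduced by simulation and are out of scope.
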