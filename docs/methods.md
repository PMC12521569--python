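# Methods

`mealphot` implements an analysis pipeline for head-fixed, operant,
tone-cued liquid-diet (Ensure) feeding assays recorded by single-fiber
photometry, together with a synthetic-session generator that reproduces the
assay's trial structure with known ground truth. This note documents the
model assumptions, the tunable parameters, and the numerical conventions,
in the package's own terms.

## Acquisition model and signal reconstruction

A single photodetector samples fluorescence while two excitation LEDs are
time-division multiplexed within a 20 ms cycle: 465 nm (calcium-dependent
signal) on for 6 ms, then 405 nm (isosbestic control) on for 14 ms. The
default raw sampling rate is 1000 samples/s, giving 6 and 14 raw samples
per pulse window. Demultiplexing (`signal.demultiplex`) takes the median of
the raw samples inside each channel's pulse window — one output sample per
cycle, i.e. a 50 Hz trace per channel. The median makes each pulse estimate
robust to a minority of corrupted samples: corrupting fewer than half the
samples in a window moves that pulse's output only within the range of the
original samples. Trailing partial cycles are dropped, never extrapolated.

The 465 nm trace is low-pass filtered at 10 Hz with a 4th-order Butterworth
applied forward-backward (`scipy.signal.filtfilt`). The zero-phase
realisation was chosen so event latencies are not shifted; DC gain is
exactly 1. The 405 nm channel is demultiplexed and stored but feeds no
analysis step — no isosbestic motion correction is applied, and none is
simulated.

## Trials, dF/F and Z units

Each trial spans a 60-s analysis window beginning 10 s before the tone cue
(3000 samples at 50 Hz). A trial is *triggered* when at least one lick
falls in the half-open cue window [cue, cue + 1 s); the boundary lick at
exactly +1 s does not trigger. Only triggered trials enter meal analyses
(they are the trials on which liquid diet was consumed), and a session is
*included* only when at least 30 trials were triggered. Trial windows are
half-open throughout; a sample at exactly the window end is excluded.

Per trial, F0 is the mean fluorescence over the 10 s pre-cue and
dF/F = (F − F0)/F0. The per-trial baseline absorbs slow drift such as
photobleaching, which is why the pipeline applies no explicit bleaching
correction. Rows with F0 ≤ 0 are flagged invalid, set to NaN, and excluded
from all means with logged counts. dF/F is exactly invariant to a
multiplicative gain on the raw signal; an additive detector offset b
rescales each row by F0/(F0 + b) per the formula (tested as an
equivariance, not an invariance).

Z units are per animal: a single mean and standard deviation are fitted to
the concatenation of all analysed dF/F samples from that animal's included
sessions and applied to every session of that animal, so Z values are
comparable across days. Two conventions had to be fixed where reasonable
alternatives exist:

- **SD convention**: population (divide by n). At the sample counts
  involved (10^5–10^6) the difference from the sample convention is
  negligible, but exact tests require one fixed choice.
- **Concatenation domain**: the analysed 60-s windows of triggered trials
  from included sessions (default), with a `full_trace` mode available.
  Whether full traces or trial windows feed the per-animal statistics is a
  genuinely open choice; the trial-window default matches "analysed
  samples" most literally and makes the standardisation contract exact:
  the concatenated analysed samples have mean 0 and SD 1 to 1e-9.

## Meal metrics

All meal metrics operate on the ordered subsequence of triggered trials,
with ordinals 1-based in reported outputs:

- **Meal size** = number of triggered trials; sessions stratify into the
  closed bins 15–29, 30–44, 45–59, 60–74, 75–90 (below 15: unstratified).
- **Early / late phase** = mean windowed response of the first / last 15
  triggered trials. For 15 ≤ n < 30 the two sets overlap; this is flagged
  rather than treated as undefined (the ≥30 inclusion rule makes it rare).
- **Across-meal change (delta_z)** = mean(last 5) − mean(first 5) of the
  peri-licking responses.
- **Mid-meal response** = mean over triggered-trial ordinals 15–29
  inclusive (15 values; defined only for meals of ≥ 29 triggered trials).
- **Window presets**: peri_licking (1–10 s post cue, the default response
  window), peri_licking_short (1–9 s), consumption (0–10 s), extended
  (0–20 s), cue (0–1 s). The source protocol uses all of 1–10, 1–9 and
  0–10 s in different analyses; every output row records which window
  produced it.
- **Lick rates**: cue rate = licks/s in [0, 1); reward rate = licks/s in
  the response window. Locomotion windows default to [−10, 0) pre-cue and
  [1, 10) post-reward (spans not fixed by the protocol; configurable).
- **Baseline variability**: rolling SD of the pre-first-delivery dF/F with
  a 30 s window advanced in 1 s steps (both unstated upstream; chosen to
  average ~270 window placements over a 5-min baseline), summarised by the
  mean of the rolling SDs.
- **Heatmaps**: two-stage unweighted means — all usable triggered trials
  across a mouse's included sessions first, then across mice with equal
  weight regardless of trial counts. Untriggered trials never contribute.

## Cohort statistics

The central model is `value ~ Diet * MealPhase + (1 | Mouse)` (or Condition
in place of Diet with a reference level), fitted by REML via statsmodels
`mixedlm`. Fixed-effect p-values are Wald z tests; the degrees-of-freedom
convention is recorded in the result metadata rather than presented as
exact small-sample inference. Levels observed in fewer than two unique mice
are excluded before fitting and named in the result. Singular or
non-converged fits are returned flagged, never silently refit. ANOVA is
type II via OLS with Tukey HSD pairwise contrasts over factor cells
(two-way designs combine the two factors into cells for the post hoc
family). t-tests are two-tailed; unpaired tests default to the
equal-variance Student form with Welch available by flag; a paired test on
identical samples returns t = 0, p = 1 rather than NaN. Alpha is 0.05
throughout. No multiple-testing correction is applied across distinct
metrics (Tukey adjusts only within an ANOVA family). Session-level and
mouse-level analyses are produced from the same tidy table by explicit
aggregation, never mixed implicitly.

## Synthetic sessions

The generator emulates the assay at one of two fidelity levels: `raw`
synthesises the full multiplexed 1 kHz photodetector stream (so the
demultiplexing path is exercised end to end), while `trace` synthesises
directly at 50 Hz with the noise SD scaled by the measured median-of-6
attenuation factor (0.4629), making the two levels statistically aligned.
Replicate-heavy calibration tests use the trace level; demultiplexing
correctness is established separately against brute-force medians.

**Trial structure.** 5-min baseline, then 60 or 90 trials at a 60-s ITI;
cue at t = 0; a triggered trial delivers 10 × 150 ms pulses with 150 ms
gaps starting at t = 1 s.

**Neural response.** Each triggered trial adds A_k · R(t), where R is the
sum of an indicator-like kernel K(t) = (1 − e^(−t/0.2 s)) e^(−t/1.5 s)
(unit peak; slow-indicator-like scale) over the ten delivery pulse onsets,
normalised so its mean over the 1–10 s response window is exactly 1 — a
trial with programmed amplitude A therefore has a noiseless window-mean
response of exactly A, which is what makes closed-form recovery targets
possible. The amplitude ramps linearly over the *triggered*-trial ordinal
from `a_early` to `a_late`, saturating at `satiation_capacity` trials — the
simplest monotone satiation model. Per-animal heterogeneity is an additive
amplitude offset (SD `mouse_effect_sd`, default 0.2), which acts as the
random intercept the mixed models estimate.

**Behavior.** Licking vigor decays with consumption:
v_m = vigor0 · exp(−m/vigor_decline_tau) with m the triggered count so far,
jittered per session by a lognormal factor (SD 0.25, matching the large
session-to-session meal-size spread seen in such assays). The trigger
probability is max(trigger_floor, 1 − e^(−v)) — the probability of at least
one lick in the 1-s cue window under Poisson licking at rate v — so meal
termination emerges when vigor collapses. Cue-window and reward-window
(1–10 s) licks are Poisson at rate v; sparse exploratory licks occur
elsewhere. Running speed is smoothed nonnegative noise scaled per group.

**Group presets.** NCD-like (lean): a_early 0.1 → a_late 0.9 over 50
trials, vigor0 5 licks/s decaying with tau 40 trials (meals ≈ 70 of 90).
HFD-like (obese): 0.7 → 0.8 over 15 trials, vigor0 4 with tau 30 (meals
≈ 50–55 of 90), reduced locomotion. These reproduce the qualitative
phenomenology the pipeline is built to quantify: weak-then-growing
responses with large meals in lean animals; strong, flat responses with
premature satiation in obese animals.

**Fluorescence and noise.** F(t) = f0 · e^(−t/bleach_tau) · (1 + dF/F(t))
plus additive Gaussian detector noise per raw sample. `bleach_tau` defaults
to 20000 s (~25% decline over a 95-min session, a realistic bleaching
magnitude; a much faster constant would inflate late-meal dF/F noise
several-fold, which real recordings do not show). The default raw noise SD
(3.05 with f0 = 1) is derived from the attenuation chain so that the
post-filter dF/F sample SD is ≈ 1:
noise_sd = 1 / (0.4629 [median of 6] × 0.6056 [zero-phase Butterworth
noise gain] × 1.169 [session-mean baseline-decay factor for additive noise
over the bleaching baseline]). With unit sample SD, per-animal Z units
approximately coincide with dF/F units, so programmed amplitudes are
"Z-equivalent" and recovery targets can be stated in Z.

**Seeding.** One master seed; per-mouse and per-session generators derive
from it with fixed spawn keys (group, mouse, session), so any session is
reproducible in isolation and whole cohorts are byte-identical across
reruns.

**What the generator does not emulate.** Motion artifacts and
hemodynamic contamination (hence nothing for an isosbestic correction to
remove), shot-noise scaling of detector noise with intensity, indicator
nonlinearity and saturation, untriggered-trial neural responses, hormonal
state, within-trial vigor structure, and sex differences (sex is carried as
metadata only). Passing recovery tests therefore demonstrates that the
pipeline measures what it claims on signals with this generative structure
— not that the biological effect sizes are realistic beyond the programmed
phenomenology.

## Problem sizes in the test suite

The acceptance suite runs the recovery analysis on 100 replicate cohorts of
40 sessions (8 mice × 5 sessions, 90 trials) with a programmed late−early
effect of exactly 0.5 (a_early 0.1, a_late 0.85, capacity 21: early15 =
a_e + 0.75·7/21, late15 = a_l for meals ≥ 36 trials), and the null
calibration on 500 cohorts of 2 × 6 mice × 2 sessions at 60 trials with a
flat amplitude profile. These sizes keep each replicate's sampling error
far below the stated ±0.1 tolerance while the suite stays desk-scale; the
replicate loops use trace-level simulation with the isosbestic channel
disabled (it feeds no analysed quantity).

## Known limitations

- Mixed-model p-values use the Wald z approximation; with very few mice
  they are mildly anticonservative compared to small-sample df corrections.
- Z invariance under raw-signal changes holds exactly for gain; an additive
  detector offset propagates through dF/F as a per-trial rescaling
  (F0-dependent) and is therefore an equivariance, not an invariance. The
  standardisation step itself is exactly invariant to affine maps of its
  input samples.
- The satiation ramp and vigor model are deliberately minimal calibration
  mechanisms, not biological claims; only their monotone structure
  (amplitude growth with consumption, vigor decline, emergent meal
  termination) is relied on by tests.
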