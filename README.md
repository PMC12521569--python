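# mealphot

Analysis of head-fixed, operant, tone-cued feeding assays recorded with
single-fiber photometry — for labs that track how feeding-evoked activity
in a neural population (e.g. a hypothalamic satiety population expressing a
calcium indicator) evolves within a meal, and how that evolution differs
between cohorts such as lean (normal chow diet, NCD) and diet-induced obese
(high-fat diet, HFD) mice.

The pipeline goes from the raw acquisition to cohort statistics:

1. **Demultiplexing** — the photodetector stream is time-division
   multiplexed (465 nm signal LED on 6 ms, 405 nm isosbestic LED on 14 ms
   per 20 ms cycle); the per-pulse median yields a 50 Hz trace per channel,
   and the signal channel is low-pass filtered at 10 Hz (zero-phase
   4th-order Butterworth).
2. **Trials** — each tone cue opens a 1-s operant window; a lick *triggers*
   liquid-diet delivery. Trials are cut into 60-s windows starting 10 s
   pre-cue; per trial F₀ = mean pre-cue fluorescence and
   ΔF/F₀ = (F − F₀)/F₀. Only triggered trials are analysed; sessions with
   fewer than 30 triggered trials are excluded.
3. **Z units** — one mean/SD per animal, fitted to the concatenation of
   that animal's analysed samples across sessions, so Z values compare
   across days.
4. **Meal metrics** — meal size (number of triggered trials), early/late
   phase means (first/last 15 triggered trials) of the peri-licking
   response (1–10 s post cue), ΔZ = mean(last 5) − mean(first 5), mid-meal
   response (triggered ordinals 15–29), meal-size strata (15–29 … 75–90),
   cue/reward lick rates, rolling-SD baseline variability, two-stage
   heatmap averages.
5. **Statistics** — linear mixed-effects models
   `Value ~ Diet × MealPhase + (1|Mouse)` (REML, random intercept per
   mouse), ANOVA with Tukey HSD, paired/unpaired t-tests, Pearson
   correlations.

Because raw in vivo recordings for this assay are not publicly deposited,
the package ships a synthetic-session generator (`mealphot.simgen`) that
emulates the trial structure (5-min baseline; 60 or 90 trials at 60-s ITI;
10 × 150 ms delivery pulses from t = 1 s), satiation-driven decline in lick
vigor and trigger probability, and diet-group-dependent response-amplitude
dynamics — with full ground truth recorded, so every stage is testable
against known effects.

## Worked example

```python
import numpy as np
from mealphot import (SimConfig, simulate_cohort, analyze_cohort,
                      cohort_metrics, phase_table, fit_lme, ModelSpec)

cfg = SimConfig(n_mice=3, sessions_per_mouse=3, n_trials=90, seed=42)
cohort = simulate_cohort(cfg)                    # NCD-like + HFD-like groups
analyses, zstats = analyze_cohort(cohort.sessions)
metrics = cohort_metrics(analyses)
inc = metrics[metrics.included]
print(inc.groupby("diet")[["n_triggered", "early_mean", "late_mean",
                           "delta_z"]].mean().round(3))

res = fit_lme(phase_table(metrics),
              ModelSpec(fixed=("Diet", "MealPhase"),
                        reference_levels={"Diet": "NCD"}))
inter = next(t for t in res.p_values if ":" in t)
print(f"diet x phase interaction p = {res.p_values[inter]:.2e}")
```

prints

```
      n_triggered  early_mean  late_mean  delta_z
diet
HFD        58.222       0.482      0.564    0.137
NCD        74.111       0.093      0.736    0.720
```

```
diet x phase interaction p = 2.26e-72
```

Read: the lean-like group eats ~74 of 90 trials and its feeding-evoked
response grows across the meal (early 0.09 → late 0.74 Z, a large positive
ΔZ), while the obese-like group terminates its meal earlier (~58 trials)
and is already strongly responsive from the first trials with essentially
no growth — the diet-by-meal-phase interaction the mixed model tests.
(Z units here ≈ ΔF/F units because the generator's noise is calibrated so
the per-animal SD of analysed samples is ≈ 1.)

The same stages are scriptable from a shell:

```bash
mealphot run --out demo_out --seed 7     # simulate -> analyze -> stats
mealphot report --out demo_out
```

## Layout

- `mealphot.signal` — pulse schedule, demultiplexing, filtering, Z stats
- `mealphot.trials` — trial tables, segmentation, ΔF/F, inclusion
- `mealphot.metrics` — meal metrics, heatmaps, correlations
- `mealphot.stats` — LME / ANOVA + Tukey / t-tests
- `mealphot.simgen` — synthetic cohorts with ground truth
- `mealphot.pipeline`, `mealphot.cli` — end-to-end orchestration
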