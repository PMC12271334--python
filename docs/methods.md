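# Methods

`ppgv` implements an idiographic (one-model-per-person) analysis of
postprandial glucose (PPG) excursions from continuous glucose monitor (CGM)
traces combined with self-logged meals and glucose-lowering medication. This
note documents the outcome definition, the feature sets, the modeling and
comparison procedure, the synthetic cohort the tests run on, and the design
choices made where the design was genuinely open.

## Outcome: per-meal excursion labels

For each logged meal the 2-hour **incremental area under the curve** (iAUC,
mg/dL·min) is computed from the CGM trace:

- the anchor glucose G₀ is the reading nearest the meal time within ±20 min
  (no anchor → the meal is unusable, never scored 0);
- the integrand is max(G(t) − G₀, 0) on [t_meal, t_meal + 120 min]
  (positive-part convention, standard in the glycemic-response literature),
  integrated by the trapezoid rule over the readings in the window; when a
  reading exists beyond the window end, the boundary value at exactly
  +120 min is linearly interpolated so the integral always covers the full
  window;
- a window with fewer than 5 readings, or whose readings span less than
  100 of the 120 minutes, is unusable. These thresholds tolerate one missed
  15-min reading while rejecting gap-ridden windows; both are exposed in
  `RunConfig`.

A meal is an **excursion** (label 1) when its iAUC strictly exceeds the
expanding mean of all of that participant's previous iAUCs — each person is
their own rolling baseline. Ties are label 0 ("higher" means strictly
higher). The first usable meal has no prior baseline and is never labeled.
Meals closer than 2 h apart each get an iAUC over their own window (overlap
permitted; no de-overlapping rule is imposed).

Cohort filters: participants enter modeling with ≥20 labeled observations
(a participant with exactly 20 is included — the threshold is a minimum)
and at least one observation of each class. Exclusions are logged with
reasons (`no_ppg`, `insufficient_obs`, `no_variability`).

## Feature sets

Two schemas per participant:

- **low burden** — passively derivable only: hour of day, day of week, day
  of month, month, whole days in study, meal slot (breakfast 05–10, lunch
  11–15, dinner 16–22, other), ate-in-last-8h/24h indicators, and the
  previous usable excursion label.
- **high burden** — the same plus manual-logging features: grams for each
  of the 7 food groups (staples, vegetables, fruits, animal foods, dairy,
  legumes/nuts/seeds, sweets) and the total, each as current-meal grams,
  8-h and 24-h historical sums, and any-eaten binaries; and per
  medication class (basal, intermediate, bolus insulin; non-insulin
  agents): an active flag and active-dose sum over the class's
  pharmacodynamic window — basal/intermediate (2 h, 24 h], bolus
  (15 min, 4 h], non-insulin (0 h, 6 h] after the dose — plus plain 8-h and
  24-h dose sums. Window indicators plus dose sums are this package's
  reading of "time-varying medication features"; dose-weighted decay curves
  would be an alternative.

All lag windows are strictly historical (events at or after the meal time
are never read). Missing gram fields and the structurally missing first
previous-excursion lag are median-imputed, with the median fit on the
chronological training portion only, and carry a missingness indicator
column. Indicator columns are always emitted for imputable features rather
than dropped when constant: whether a column is constant can depend on
test-portion rows, and making the trained feature set depend on test data
would be leakage. Constant columns cost nothing — the booster never splits
on them.

## Per-person models

Each participant × schema gets a binary XGBoost classifier
(`binary:logistic`, exact tree method, single thread, fixed seed):

- chronological 70/30 split (first ⌊0.7·n⌋ rows train; with the 20-row
  minimum this guarantees ≥14 training and ≥6 test rows);
- hyperparameters by grid search, scored with 4-fold rolling-origin
  (expanding window) CV on the training rows: the training block is cut
  into 5 contiguous near-equal parts (earlier parts absorb the remainder);
  fold j fits on parts 1..j and validates on part j+1;
- the default grid is n_rounds {50,100,150} × eta {0, 1e-4, 1e-3, 0.01,
  0.015} × max_depth {1,2,3} × gamma {−0.5, 0, 0.5} × colsample_bytree
  {0.5, 1, 2} × min_child_weight {1,2} × subsample {1}. Two printed values
  are outside XGBoost's legal domain and are sanitized before fitting:
  gamma −0.5 → 0 and colsample_bytree 2 → 1 (duplicates collapse, leaving
  360 legal points). eta = 0 is legal (a constant booster) and is retained;
  it never wins on informative data;
- fold score: F1 of the positive class at threshold 0.5. A fold whose
  validation block has no positive label or draws no positive prediction
  scores undefined and drops out of that grid point's mean (undefined is
  never coerced to 0). Ties in mean CV F1 prefer the simplest model: fewer
  rounds, then shallower trees, then larger eta;
- if every fold of every point is undefined the participant falls back to
  a flagged majority-class predictor;
- `FAST_GRID` (n_rounds {50,150} × eta 0.015 × depth {1,3}) is a 4-point
  subset of the sanitized grid used by the tests, the analysis scripts and
  the acceptance script; the full grid runs in well under a minute per
  participant per schema on one CPU.

## Evaluation and burden comparison

Test-set precision, recall and F1 propagate undefined values (precision is
undefined with no positive prediction; F1 is undefined when either
component is). The best-of-two model per person takes the larger defined
F1; exact ties are recorded as ties (and profiled with the high-burden fit,
the richer feature set); both-undefined participants are incomparable and
excluded from best-model summaries.

Participants with both F1s defined are grouped by the sign of
(F1_low − F1_high), and a paired two-sided Wilcoxon signed-rank test is run
within each non-tie subgroup. The statistic uses the normal approximation
with a 0.5 continuity correction toward the null mean, average ranks for
tied absolute differences, the tie-corrected variance, and drops zero
differences — the implementation is in `ppgv.evaluation` because a Z value
is reported, which `scipy.stats.wilcoxon` does not expose; scipy and an
exact sign-enumeration oracle serve as independent cross-checks in the
tests. **Caveat, printed with every report:** testing within a subgroup
selected by the sign of the tested difference is circular; these p-values
describe the subgroup, never the cohort. The procedure is replicated as
specified for fidelity; with all positive differences the maximum
attainable |Z| is about 4.2 at n = 23, which bounds what this statistic can
report at that subgroup size.

## Vulnerability profiles

For each participant's best model, per-feature **total gain** (loss
reduction attributed to splits on that feature) is normalized to percent of
the summed gain, then aggregated into categories (staples, vegetable
intake, …, hour of the day, previous PPG excursion; missingness indicators
inherit their base feature's category). Features absent from all splits get
0%; a fallback model yields a flagged all-zero profile. A parallel profile
from mean |SHAP| per feature (XGBoost's built-in TreeSHAP) is emitted
alongside, never instead: gain is a global training-time quantity, SHAP a
per-prediction one, and "mean absolute importance across data points" only
has a literal meaning for the latter. Cohort summaries report per-category
mean/min/max percent, share counts (participants with a nonzero share),
top-k categories, and a distinctness check for identical rankings.

## Synthetic cohort

The generator produces participants with known excursion drivers so that
recovery can be tested end to end:

- **CGM trace** = personal fasting baseline (drawn uniformly from 120–180
  mg/dL) + a 24-h circadian sinusoid (default amplitude 10 mg/dL, minimum
  near 03:00) + one response pulse per meal + Gaussian sensor noise
  (default SD 4 mg/dL), sampled every 15 min for 14 days and clipped to a
  physiologic range.
- **Pulse**: piecewise linear, 0 → peak at 45 min → 0 at 180 min; its 2-h
  area is available in closed form (230·H/3 for peak height H), which the
  iAUC oracle tests use. Peak height is Σ over driver categories of
  weight × standardized exposure: grams/100 for food groups and the total,
  and a late-evening risk-window indicator (meal hour ≥ 18 by default) for
  the hour-of-day driver. When any medication class is inside its action
  window at meal time (the same windows the feature module uses), the
  height is multiplied by (1 − med_suppression).
- **Meals**: three daily slots (≈07:30, 12:00, 18:30, jitter SD 40 min)
  plus an afternoon snack with probability 0.23, giving ≈3.23 meals/day.
  Meal timestamps are rounded to the CGM grid, emulating the coarse clock
  resolution of self-logged meals; a side effect is that the piecewise
  linear pulse has its kinks on sampling points, so the trapezoid rule is
  exact on noise-free traces. Grams per group are drawn per meal with
  group-specific presence probabilities and lognormal amounts calibrated
  so daily totals land near 222 g staples, 156 g vegetables, 145 g animal
  foods, 82 g dairy, 31 g fruits, 9 g legumes/nuts/seeds, 1.5 g sweets.
  Each group's portion alternates between a light (×0.45) and a generous
  (×1.55) state in a two-state Markov chain with persistence 0.65 —
  portion sizes in real logs are strongly bimodal (a congee breakfast vs a
  rice-heavy dinner), and dietary routine persists across meals, which is
  exactly what makes the previous-excursion lag informative for the
  low-burden model.
- **Medication** (emitted when suppression is active): a morning
  non-insulin dose with probability 0.6/day and a pre-dinner bolus with
  probability 0.5/day, so medication activity varies across meals and is
  learnable.
- **Scenarios** mix individual kinds: `mixed` (40% staples-driven, 30%
  evening-timing-driven, 20% medication-masked, 10% noise-only) for the
  main analysis; `single_driver` (one dominant driver per person, weight
  ratio ≥ 5:1, rotating staples / vegetables / animal foods / hour-of-day)
  for driver-recovery checks. Per-participant seeds derive from the master
  seed via `SeedSequence`, so cohorts are reproducible to the byte.

What the generator does **not** emulate: glucose–insulin physiology (no
ODEs, no insulin kinetics beyond the action-window damping), free-text meal
descriptions (it emits structured grams directly, bypassing the food
lexicon), irregular CGM wear gaps beyond optional uniform dropout, and any
between-person correlation structure. Passing recovery tests therefore
shows the pipeline recovers drivers *of the kind it assumes* — additive,
meal-locked, with the stated pulse shape — not that real dietary drivers
are recoverable at these rates.

## Problem sizes and numerics

The analysis scripts and the acceptance script use a 30-person mixed cohort,
a 50-person single-driver cohort and the 4-point fast grid; these sizes give
stable medians while keeping a full run in the order of a minute. Unit
conversion uses 18.018 (mg/dL per mmol/L); unit auto-detection treats a
median below 30 as mmol/L (the physiologic ranges do not overlap).
Determinism contract: fixed seeds everywhere, single-threaded exact-method
boosters, stable sorts with insertion-order tie-breaks; two runs with the
same config produce byte-identical CSVs.

## Known limitations

- The expanding-mean baseline drifts early in a participant's record, so
  the implied "big meal" threshold differs slightly between the training
  and test periods; per-person F1 reflects that, as it would on real data.
- The printed hyperparameter grid's learning rates are very small
  (≤ 0.015); with ≤150 rounds the boosters move probabilities only
  modestly away from 0.5, and sign(margin) does most of the work at the
  0.5 threshold.
- Gain-based importance is attributed to single features; correlated
  features (e.g. staples grams and total grams) compete for splits, so
  category shares — not exact percentages — are the meaningful unit.
- The normal-approximation signed-rank p is accurate to ~0.02 for the
  moderate-tail patterns that arise here, but the exact distribution at
  n ≤ 12 has large atoms and the approximation can exceed that error in
  deep tails; for very small subgroups an exact test would be preferable.
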