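# Methods

## Problem and model

The task is supervised binary classification: given the 12 hours of
continuous glucose monitoring (CGM), pump-logged insulin delivery and
self-monitored blood glucose (SMBG) preceding a blood-ketone measurement,
predict whether that measurement is elevated (≥ 0.6 mmol/L). Prediction
points are ketone checks, which in closed-loop practice are prompted by
sustained hyperglycemia; the classifier therefore discriminates *which*
hyperglycemic episodes carry metabolic decompensation, not *when* to
sample.

The learner is an XGBoost gradient-boosted tree ensemble. Trees natively
consume the missing marker (NaN) used for absent SMBG features, capture
the nonlinear interactions between glucose level, glucose dynamics and
insulin deprivation, and are robust to the heterogeneous feature scales
(mg/dL, insulin units, ratios, hours).

### Windowing and eligibility

Windows are half-open on the left and closed on the right: (t − 12 h, t]
and (t − 6 h, t]; insulin is split into (t − 6 h, t] and (t − 12 h, t − 6 h].
Right-closure keeps the reading nearest the ketone check inside the
window, so the "latest" glucose feature is well defined; the sample
exactly 12 h earlier is excluded. Eligibility requires (a) ≥ 72 CGM
readings in the 12-h window, (b) CGM wear fraction ≥ 0.5, and (c) ≥ 1
insulin record in the window. At 5-minute sampling (a) and (b) coincide
(72 = 0.5 × 144); both are checked independently so coarser grids degrade
safely. SMBG is never required. Duplicate timestamps within a stream keep
the last record (device overwrite semantics). No sample after t ever
enters a window (no look-ahead). An optional `min_gap_h` drops ketone
checks closer than a given gap to the previously kept check, for
sensitivity analyses on overlapping windows; the default keeps all.

### Features

The 26 predictors and their fixed column order are declared in
`ketopred.features.FEATURE_COLUMNS`; this is the model contract. Choices
that were genuinely open and how they were resolved:

- `decrease_ratio` divides the count of decreasing consecutive pairs by
  the series length n (not n − 1), keeping the ratio in [0, 1).
- `mean_decrease` is reported as a positive magnitude (mean absolute drop
  over decreasing pairs; 0 if none decrease).
- "Time above 300 mg/dL" is a fraction of available readings (strictly
  > 300), not absolute minutes, making it robust to wear-time differences.
- `hour_of_day` is the integer hour (0–23) of the ketone check — the time
  at which a prediction would fire — encoded as a plain integer, not
  cyclically; trees split ordinal encodings adequately.
- SMBG features are the SMBG latest/max/min within 12 h; all three are
  NaN when no fingerstick falls in the window. NaN flows to the learner
  unimputed.
- Standard deviations use the sample (n − 1) denominator; a single-sample
  series has SD 0 by convention.
- Insulin sums use exactly-rounded summation (`math.fsum`), so a sum is
  bit-identical regardless of record storage order.

### Cross-validation and tuning

Folds are 5-fold label-stratified at the sample level, shuffled under a
fixed seed (default 2024); each fold's event count is within one of the
perfectly stratified allocation. A single CV loop serves both
hyperparameter selection (grid argmax of mean validation ROC-AUC, ties
broken by fewer estimators, then shallower depth, then lower learning
rate) and performance reporting. Selecting and reporting on the same
folds carries optimism; this is documented rather than hidden, and
`grid_search` can be nested inside an outer split when an unbiased
estimate is needed. An optional patient-grouped mode
(`StratifiedGroupKFold`) keeps each patient inside one fold, which is the
appropriate design when patients contribute many correlated windows.

The full grid has 3⁶ = 729 settings and is expensive; the `fast` grid is
the single point (learning rate 0.1, 100 estimators, depth 8, min child
weight 1, subsample 1.0, γ 1) and is the default for end-to-end runs and
for the acceptance computation.

### Metrics and importance

ROC-AUC is the Mann–Whitney concordance probability (ties counted half);
PR-AUC is average precision, whose chance level equals event prevalence —
the informative baseline at ~20 % prevalence. Both are computed per fold
on validation predictions and summarized as mean ± SD across folds
(scikit-learn implementations behind the package's metric functions;
independent brute-force oracles live in the test suite). Shapley
attributions use exact TreeSHAP as implemented inside XGBoost
(`pred_contribs=True`), evaluated on each fold's validation rows only to
avoid optimistic training-row attribution, aggregated as mean |SHAP| per
feature and averaged across folds. The feature-subset comparison
(insulin-only: 6 sums; SMBG-only: 3; current glucose: the single
`cgm12_latest`; CGM-6h: 8 stats + hour of day; CGM-12h: 8 stats;
combined: 26) shares one fold assignment per subgroup so the comparison
is paired. The pediatric sensitivity mode repeats the loop on rows with
age < 18 years.

## The synthetic cohort generator

No closed-loop trial dataset of this kind is publicly deposited, so the
package generates cohorts whose streams have the statistical structure
the analysis assumes. Per patient, glucose on a 5-minute grid is a
per-patient baseline (≈ N(150, 18) mg/dL) plus an 18 mg/dL diurnal
sinusoid, three daily meal excursions (lognormal height, median
65 mg/dL), and i.i.d. 12 mg/dL sensor noise, clipped to the 40–400 mg/dL
reporting range. Each scheduled CGM sample is independently dropped with
probability `dropout_prob` (default 0.08) to emulate wear-time gaps.

Elevated ketones arise from two episode types with Poisson arrivals:

- **Infusion failures** (default 0.15/day, ≈ 4 h): basal deliveries are
  zeroed, glucose ramps at 20 mg/dL/h, and a latent ketone level rises at
  0.11 mmol/L/h (per-episode lognormal jitter, σ = 0.3), both relaxing
  exponentially after the episode (glucose τ ≈ 70 min, ketones
  τ ≈ 180 min).
- **Sick-day (illness) episodes** (0.05/day, longer): the same glucose
  and ketone dynamics, but insulin delivery is logged as usual — so a
  substantial share of events leaves no signature in the pump log, which
  is what keeps CGM the dominant information source, as observed in real
  closed-loop cohorts.

A ketone check fires at the first recorded CGM reading above 300 mg/dL in
any 4-h span (refractory trigger), and the meter is read after a random
10–70-minute patient delay; the measurement is the latent level plus
N(0, 0.05) meter noise floored at 0. The delay means episode-driven ramps
keep climbing past the threshold while transient post-meal spikes fall
back, giving the latest CGM value genuine discriminative content. The
insulin log contains 30-minute basal aliquots (per-patient rate
≈ N(0.8, 0.2) U/h), meal boluses (≈ 5 U, lognormal jitter) and 1.5-U
closed-loop correction boluses commanded at CGM > 260 mg/dL (3-h
refractory), logged even during failures since the controller still
commands them. SMBG fingersticks arrive at 1.5/day.

Defaults were calibrated once, as part of the generator's design, so that
the reference cohort (200 patients × 90 days) yields roughly 2,200–2,500
eligible windows with ≈ 20 % elevated — the event-imbalance regime this
style of analysis faces — and were then frozen. Time is integer minutes
from a cohort epoch, avoiding timezone/DST ambiguity. Each patient draws
from an independent child stream of the master seed (`SeedSequence.spawn`),
so cohorts are bit-reproducible and patient order is immaterial.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no physiological glucose–insulin ODE
coupling (insulin amounts do not feed back into glucose), no carbohydrate
counting, exercise, stress or sensor-compression artifacts, no
autocorrelated CGM error, no behavioral non-adherence beyond the check
delay, and no demographic structure beyond a pediatric/adult age mix.
Synthetic results demonstrate that the pipeline recovers a planted
mechanism under realistic sampling, imbalance and missingness; they say
nothing about the effect sizes achievable on trial data.

## Numerical and degenerate-input choices

Empty or too-short glucose series raise degenerate-input errors rather
than returning sentinels (an eligible window cannot be that short).
Single-class training folds and single-class metric inputs raise
immediately with the fold named. XGBoost runs single-threaded
(`n_jobs=1`, `tree_method="hist"`) so predictions are bit-reproducible
across runs on any machine. Grid-search ties are broken deterministically
(see above). Probabilities are validated to [0, 1] by construction of the
logistic objective.

## Problem sizes used in the shipped computations

The acceptance computation runs the reference conditions (200 patients,
90 days, ≈ 2,200 eligible windows) with the `fast` grid — chosen as the
package's standard demonstration scale, large enough for stable fold
estimates and a well-populated pediatric subgroup. Unit and property
tests use 8–40-patient cohorts; the formula oracles check 1,000 windows
of the reference cohort.

## Known limitations

- The single-loop CV protocol reports selection-optimistic scores by
  design (it mirrors the analysis it reimplements); use nested search for
  honest generalization estimates.
- Sample-level stratification lets one patient span folds; with many
  windows per patient this leaks patient identity. The grouped mode
  exists precisely to quantify that effect on synthetic cohorts.
- The ketone trigger-and-refractory scheme is a stand-in for real
  patient behavior, which is sparser and more selective; absolute window
  counts per patient are not calibrated to any trial.
- PR-AUC at low event counts has high fold-to-fold variance; the reported
  SD across 5 folds understates full sampling uncertainty.
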