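# Methods

This note records the modelling assumptions, the design choices made
where the design was genuinely open, the synthetic-data generator's
scope, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Time and table conventions

Time is integer minutes since ICU admission (minute 0 = admission).
All windows are half-open `[a, b)`. Tables are CSV with mandatory
headers and empty fields for missing values; a vitals record is unique
per (patient, minute). Vital channels: HR (bpm), SBP/MBP/DBP (mmHg),
RR (breaths/min), SpO2 (%). SpO2 is carried through IO and filtering
but is not an explanatory variable and does not participate in the
stability gates.

## Noise filtering

Artifact rejection is purely range-based and row-atomic: if any present
vital in a one-minute record falls outside its plausibility range
(HR 20–250, SBP 30–300, MBP 20–250, DBP 10–200, RR 2–60, SpO2 50–100),
or the pressure ordering DBP ≤ MBP ≤ SBP fails while all three
pressures are present, the whole record is excluded and logged with the
violated rule. Missing fields alone never trigger exclusion — gaps are
handled by the coverage gates downstream. The ranges are configurable
(`NoiseRuleSet`); they are standard physiological plausibility bounds,
not estimates of any particular monitor's artifact spectrum. The filter
is idempotent and monotone in the ranges (widening never removes more),
both property-tested.

## Baseline establishment

Candidate windows `[s, s+60)` are scanned from s = 0 in 20-min steps.
Per gated vital (HR, SBP, MBP, DBP, RR), in order:

1. **Coverage** — at least 90 % of the 60 minutes present (inclusive
   gate). Interior gaps are linearly interpolated; leading/trailing
   gaps take the nearest present value (`np.interp` semantics).
2. **Friedman gate** — the hour is split into three chronological
   20-min segments; a Friedman rank test uses the segments as
   treatments and the within-segment minute positions (1–20) as blocks,
   the only blocking structure available within a single hour of one
   patient. `p < α` (default α = 0.05, configurable) marks instability.
   The statistic is the tie-corrected chi-square form; a window with no
   rank variation (e.g. constant) is defined to have statistic 0,
   p = 1. The implementation is verified exactly against an
   independent brute-force rank computation and against the reference
   scipy routine on tie-free inputs.
3. **CV gate** — sample SD divided by mean must not exceed a per-vital
   threshold (HR/SBP/MBP/DBP 0.10, RR 0.20, SpO2 0.02; boundary
   inclusive). These defaults are conservative stand-ins and fully
   configurable; a positive mean is a precondition (physiological
   signals).

The first window at which every gated vital passes all three gates is
accepted; the per-vital baseline is the mean of the final five minutes
of the accepted (interpolated) window — the window-final value of the
5-min moving average — and is treated as a constant reference level
thereafter. `established_at` is the end of that window, and no pain
index is defined before it; a patient with under an hour of data never
establishes. Every failed attempt is logged as (window start, reason ∈
coverage/friedman/cv).

The anchor choice deserves a note: a 5-point mean carries a standard
error of noise_sd/√5, so recovery of a true baseline is intrinsically a
±2 SE statement at the ~95 % level; averaging the whole accepted hour
would be far tighter but is the other admissible reading of "moving
average during this period", and the scalar-anchor reading was chosen
and kept. The anchor span is configurable.

## Features and label

Per assessment at minute t (only if t ≥ `established_at`): window
`[t−60, t)`, coverage strictly greater than 90 % (the baseline gate is
inclusive at 90 %; the feature gate is strict — both conventions are
deliberate and tested at the 54/60 vs 55/60 boundary). Per vital, five
summaries of d(u) = v(u) − b_v: value at t, deviation at t, trapezoidal
area above baseline (59 trapezoids over 60 points, unit·min), area
below, and mean deviation. `area_above − area_below` equals the signed
trapezoidal integral (conservation), and all five are invariant to a
common shift of series and baseline (translation equivariance); both
are property-tested, and every emitted row is checked against an
independent Riemann/trapezoid recomputation at 1e-9.

Context variables: sex, age stratified 20–44 / 45–64 / 65+ (ages below
20 are outside the population and rejected), and the RASS score —
taken from the assessment itself or the nearest RASS within ±60 min,
else the row is dropped and logged. Label: CPOT ≥ 3 positive, ≤ 2
negative. The per-minute scoring path recomputes the same features at
arbitrary display minutes; it interpolates gaps over the whole stream
rather than per window, which differs from the per-assessment path only
in how window-edge gaps borrow values from just outside the window.

## Class balancing (ADASYN)

ADASYN is implemented in-package: for each minority (positive) point,
K = 5 nearest neighbours are found in the standardized continuous
feature subspace; the synthesis budget per point is proportional to the
fraction of majority neighbours (uniform if that density is zero
everywhere); each synthetic point is `x_i + λ(x_z − x_i)` with λ ~
U(0,1) and x_z one of the point's K nearest *minority* neighbours, so
every synthetic point lies on a segment between two real positives
(geometrically tested). One-hot and ordinal fields are copied from the
seed point — interpolating categorical codes is meaningless. The target
is approximate balance (β = 1). A single positive example degenerates
to duplication; zero positives is an error.

Oversampling is applied inside training folds only. Every CV fold
records a structural audit (original-train count, synthetic count,
validation size, validation-rows-all-original), asserted in the tests:
no synthetic row is ever scored in validation.

## Model fitting and evaluation

`PainIndexModel.fit()` grid-searches `n_estimators × max_depth` by
inner cross-validated AUROC on training data (a single-cell grid skips
the inner CV) and refits the best cell on the full training data after
oversampling. The default grid is {5, 10, 17, 25, 50} × {6, 10, 14,
18}; the single-point grid at the reference optimum (17, 14) is the
documented fast path (`ModelConfig.reference_point()`). Cross-validation
splits by patient by default (assessment-level splitting is retained as
an option for fidelity experiments); per-repeat AUROC pools the
out-of-fold predictions of that repeat, and repeated CV reports
mean ± SD over repeats (SD absent for a single repeat). Folds whose
validation part is single-class are skipped with a warning. All
randomness flows from explicit seeds; identical config + seed
reproduces identical results, tested.

AUROC is the pairwise concordance probability with ties counted ½
(equivalently trapezoidal ROC integration), cross-checked exactly
against a brute-force pairwise oracle. Operating-point metrics default
to the Youden threshold, a standard choice where no operating point is
mandated. Bands: low
0.5–0.7, moderate 0.7–0.8, high ≥ 0.8 (0.7 → moderate, 0.8 → high).
The harmonic mean of sensitivity and specificity is 2ab/(a+b).

## Treatment-response analysis

For each fentanyl bolus at t₀ with dose in [25, 100] µg: pre-CPOT is
the last assessment in `[t₀−120, t₀]`, post-CPOT the first in
`(t₀, t₀+120]` (the 120-min search span is a stated
convention of this package). Improvement means pre − post ≥ 1. Boluses lacking
either CPOT, lacking a defined pain index at t₀ or t₀+60, or with
another analgesic charted within the ±60-min window are excluded and
logged. Outputs: per-group per-minute median/quartile trajectories,
within-group paired t (two-sided and one-sided for a *drop* — the
directional analgesic hypothesis) with Wilcoxon alongside, and Welch +
Mann-Whitney between groups at t₀+60 (the instantaneous minute, not an
average). The continuous-outcome group comparison is done with t/rank
tests; an exact test on frequencies is not applicable to means and was
not imitated.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes; its defaults
are the study conditions of the test suite, chosen once on physiological
plausibility, not fitted to any dataset.

Per patient: true baselines drawn from population means/SDs (HR 80±10,
SBP 122±12, DBP 62±8, RR 16±2.5, SpO2 97±1); MBP is derived per minute
as DBP + pulse-pressure/3 with pulse pressure floored at 5 mmHg, which
makes DBP ≤ MBP ≤ SBP structural. Signal = baseline + admission drift
+ noise + pain effect:

* **Admission drift** — exponentially decaying offset (HR +18 bpm,
  SBP +22, DBP +10, RR +5, SpO2 −2 at admission; half-life 10 min),
  guaranteeing the unstable-then-stable trajectory the baseline search
  assumes.
* **Noise** — stationary AR(1) per minute with marginal SDs HR 3,
  SBP 5, DBP 3.5, RR 1.5, SpO2 0.6. The default AR coefficient is 0:
  measurement noise is modelled white, with serial structure carried by
  drift and episodes; positive correlation is available via
  `ar1_coefficient` (its marginal SD is preserved). The MBP `noise_sd`
  entry (2.9) is the realized SD implied by the derived-channel
  construction, kept consistent for tolerance bookkeeping.
* **Pain episodes** — Poisson arrivals (0.05/h) after minute 120
  (admissions arrive under residual anaesthesia/analgo-sedation;
  configurable), trapezoidal severity with 3-min ramps, duration
  U(20, 45) min — deliberately shorter than the 60-min stability window
  so a plateau can never span a whole candidate window undetected —
  and lognormal amplitude (σ = 0.3). Vital shift per unit severity:
  HR +8, SBP +10, DBP +5, RR +3, SpO2 0 (not an explanatory variable).
* **CPOT** — `clamp(round(2·severity + ε), 0, 8)` with observer noise
  ε uniform on {−1, 0, 1}; the simplest monotone map with noise. The
  severity scale is calibrated by bisection on the exact expected
  positive fraction at the realized assessment severities, so the
  cohort hits `target_positive_rate` (default 3.3 %) in expectation.
* **Assessments** — scheduled every 480 min, plus one within 5 min of
  each episode onset, plus a follow-up 60 min after each bolus.
  RASS is a slowly switching categorical chain (switch ~1/180 per min)
  with marginal mass concentrated at 0 and negative values; CAM-ICU is
  generated (~22 % positive) but unused by the model.
* **Boluses** — at pain-positive assessments with probability 0.5
  (dose ∈ {25, 50, 75, 100} µg, ≥ 120 min apart). Responders
  (probability 0.3) have severity multiplied by 0.5^(Δt/30) for 180 min
  — ≤ 0.5 of its value within 60 min; non-responders are unchanged.
  Responder flags are ground truth, never inputs.
* **Corruption** — artifact minutes (1 %) carry out-of-range spikes or
  a violated pressure ordering, every one removable by the default
  rules (round-trip tested); dropout minutes (1 %) are absent entirely.
  Arterial-line/ECG-derived channels chart nearly every minute, hence
  the low rates; both configurable.

Determinism: all randomness derives from one `SeedSequence`; identical
config and seed give byte-identical cohorts.

**Treatment-response experiments** use a deliberate configuration:
episode durations 240–420 min so that *untreated* pain persists across
the ±60-min bolus window (with short episodes, natural resolution
mimics treatment response and no null holds); positive rate 0.10 and
bolus probability 1.0 for adequate bolus counts at desk scale; and —
essentially — the scoring model is trained on a *disjoint* cohort, so
the treatment-response patients play no part in model derivation. Scoring a cohort with a forest trained on it lets deep trees
reproduce the memorized labels of the triggering and follow-up
assessments, and the "response" then tracks observer noise; this
resubstitution artifact is real and the held-out design removes it.

## What passing tests do and do not show

The generator reproduces the *assumed structure*: per-patient baselines
behind decaying instability, jointly elevated HR/BP/RR during pain,
sparse noisy CPOT observation, responder dynamics. It does not emulate
real ICU phenomena such as sedation-vitals coupling, circadian rhythm,
interventions other than fentanyl boluses, monitor-specific artifact
morphology, HRV (deliberately out of scope), or drifting baselines
later in the stay (baselines are established once, never updated).
Passing tests therefore demonstrate correctness and statistical sanity
of the pipeline under its own assumptions — recovery of known ground
truth, nominal error rates, chance-level behaviour on null cohorts —
not clinical performance; real-data accuracy figures cannot be
reproduced from synthetic cohorts.

Problem sizes in the test suite (200–500 patients × 2 days, 10-fold CV
with 2–3 repeats) were chosen as the smallest cohorts at which the
studied effects are comfortably resolved.

## Numerical notes and edge cases

* Friedman with all blocks fully tied → statistic 0, p 1 (stable).
* CV gate at exactly the threshold → stable; coverage at exactly 90 % →
  accepted in the baseline module, rejected in the feature module.
* Grid-search ties resolve to the first cell in grid order.
* Pain-index probabilities are exactly the forest's class-1 vote
  fractions, in [0, 1] by construction and asserted contractually.
* PPV/NPV with empty denominators are reported absent (NaN), as is the
  CV SD of a single repeat.
* Vitals are written with one decimal; round-tripping a cohort through
  CSV is exact at that precision.
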