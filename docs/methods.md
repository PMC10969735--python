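# Methods

## Sway quantification

A trial is a uniformly sampled time series of a marker's sagittal-plane
displacement in centimeters (header `time_s,ap_cm,vert_cm`). Validation
requires strictly increasing times with spacing uniform to 1% relative
tolerance, at least two samples, and finite values; the sampling rate is
inferred from the median inter-sample interval, with a declared manifest
rate overriding it (warning above 1% mismatch). Traces are trimmed to
the half-open window [t₀, t₀ + 20 s); shorter traces pass through with a
logged warning.

Each trial becomes one scalar. The protocol behind the data does not fix
the scalar, so the default is the anteroposterior **path length**
Σᵢ|xᵢ₊₁ − xᵢ| — the standard stabilometric magnitude — because it is
ratio-scaled, which the index formulas require; `range` (max − min) and
`rms_deviation` are selectable. Only the anteroposterior coordinate
enters the scalar; the vertical coordinate is carried but unused. Traces
are assumed to be calibrated centimeters; a `cm_per_pixel` factor
rescales pixel exports.

Trial aggregation: trial 1 is familiarization and is discarded; the mean
of trials 2–3 represents the condition. By default a missing
non-familiarization trial is an error; `allow_single_trial` downgrades
it to a warning and uses the lone available trial.

## Sensory participation indexes

SOM = C2/C1, VIS = C4/C1, VEST = C5/C1, VP = (C3+C6)/(C2+C5), computed
per participant × marker. The formulas are often printed ×100; published
cohort tables, however, report magnitudes of order 1, so the default
reporting scale is `ratio` with `x100` selectable — the algebra is
identical up to the constant. Denominators at or below `denom_epsilon`
(10⁻⁹ cm) raise a degenerate-profile error naming the participant;
participants with incomplete or degenerate profiles are excluded
listwise within marker, each exclusion logged.

## Inference chain

All rank statistics are implemented directly on mid-ranks (average ranks
for ties). With n participants × k = 4 indexes, rᵢⱼ the within-block
rank, Rⱼ the rank sums, A = Σrᵢⱼ² and C = nk(k+1)²/4:

* **Friedman omnibus** Q = (k−1) Σⱼ (Rⱼ − n(k+1)/2)² / (A − C),
  referred to χ² with k−1 df. This is the tie-corrected form used by
  mainstream statistical software (default; the uncorrected classic
  formula is available). A fully tied matrix returns Q = 0, p = 1. The
  χ² approximation is adequate at n = 27; its empirical size at
  α = 0.05 is checked by simulation in the acceptance suite.
* **Conover post hoc** on all six index pairs:
  t = (Rₐ − R_b) / √(2n(A−C)(1 − Q/(n(k−1)))/((n−1)(k−1))), with
  (n−1)(k−1) df, two-sided. Algebraically this equals Fisher's LSD from
  the two-way (block + treatment) ANOVA of the within-block ranks — the
  test suite exploits that identity as an independent oracle. Post hoc
  results are reported only when the omnibus p < α (default 0.05),
  matching the protocol's gatekeeping; `always_posthoc` overrides.
  P-values are unadjusted by default (matching common practice for this
  design); Holm step-down is available.
* **Spearman's rho**: Pearson correlation of mid-ranks; two-sided p from
  the t approximation with n−2 df; |rho| = 1 returns p = 0; a constant
  input returns rho = 0, p = 1 with a warning.
* **Descriptives**: median and IQR (Q3 − Q1) under linear interpolation
  of order statistics (quantile type 7), stated here because published
  IQR conventions are rarely declared.

## PBS scoring

Items 1, 2, 3, 6, 7, 8 score the best of up to three attempts; items 9
and 14 the mean of exactly three (fractional totals are kept — no
rounding convention is invented); the remaining items allow one attempt.
Totals lie in [0, 56]. Attempt counts and score ranges are validated.

## Synthetic cohort generator

The generator defines the study conditions for every test:

* **Sway process**: xₜ₊Δ = xₜ(1 − λΔ) + σ_c √Δ ε, x₀ = 0, a discrete
  Ornstein–Uhlenbeck-style recursion (stability requires λΔ < 1).
  Defaults: λ = 1 s⁻¹, 25 Hz, 20 s, baseline σ = 0.05 cm. Every path
  scales linearly in σ_c, so expected path length is proportional to
  the condition multiplier and index ratios recover multiplier ratios —
  a clean parameter-recovery surface. This is a declared stand-in for
  recorded sway, not a physiological model.
* **Condition multipliers** (C1..C6) = 1.0, 0.7, 3.5, 2.1, 2.0, 9.5,
  solved from published malleolus index medians treated as ratio-scale
  targets (SOM ≈ 0.7, VIS ≈ 2.1, VEST ≈ 2.0, VP ≈ 4.8).
* **Heterogeneity**: participant overall scale is lognormal (σ_log
  0.15). A pure per-marker scale factor cancels in every index ratio
  and cannot produce cross-marker agreement, so the generator instead
  draws per-participant per-condition lognormal effects (σ_log 0.3)
  shared by both markers, plus marker-specific per-condition deviations
  (σ_log 0.3). With these defaults the expected cross-marker index
  correlation is ≈ 2σ²/(4σ² + trial noise) ≈ 0.5, matching published
  agreement, and index medians spread realistically while remaining
  centered on the multiplier ratios (condition effects are
  median-neutral by symmetry).
* **PBS totals**: mean 50.44, sd 2.74; generated as
  mean + slope·z(VEST_malleolus) + noise with slope = ρ·sd and noise
  sd = sd·√(1−ρ²), target ρ = −0.45, clamped to [0, 56] (logged). The
  malleolus vestibular index is the driver; the mastoid association is
  inherited through cross-marker agreement and therefore attenuated.
  Totals are then decomposed into legal item attempt records (quantizing
  to the scale's native 1/3 resolution), so the written PBS CSV rescoring
  reproduces them.
* **Seeding**: one root seed; per-participant streams come from
  `numpy.random.SeedSequence(entropy=root, spawn_key=(p,))` with a fixed
  draw order (scale, condition effects, marker deviations, innovations);
  the PBS noise stream uses spawn key (2¹⁶,). Cohorts are bitwise
  reproducible from (config, seed).

What the generator does **not** emulate: non-stationarity and drift in
real sway, frequency structure beyond first-order mean reversion,
head-vs-ankle biomechanics (markers differ only through latent scales),
tracking artifacts, and any discreteness of video-derived displacement.
Passing tests therefore demonstrate correctness of the pipeline's
algebra and inference on data with the assumed structure, not validity
of the protocol on real recordings.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 cohorts of n = 27 (ordering, correlation
recovery), 500 trials per condition (multiplier recovery), and 2000
null matrices (Friedman size); these sizes put Monte-Carlo error well
inside the asserted tolerances while keeping the default suite fast.
Ranking uses a stable mergesort; the Conover standard error clips the
1 − Q/(n(k−1)) factor at 0 (perfect concordance maps to ±∞ statistics
rather than NaN); report JSON carries no timestamps so identical inputs
give byte-identical reports.

## Known limitations

* The post hoc t statistics' sign convention follows rank-sum
  differences (lower-sway treatment gets the smaller rank sum); compare
  absolute values against published tables that do not state signs.
* The file-based pipeline loads one trace at a time; memory stays flat
  but very large cohorts pay file-system overhead.
* PBS item records generated from a target total are one of many valid
  decompositions; only the total is meaningful.
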