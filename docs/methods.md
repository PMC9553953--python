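# Methods

## The generative model

The synthetic cohort emulates a two-genotype longitudinal design: `n_wt` = 16
and `n_sod1` = 24 littermates (sex balanced; sex is carried through all
tables but has no programmed effect), tested on the string-pulling task twice
weekly over weeks 9–18, weighed weekly, with independent cross-sectional
histology cohorts (6 animals per genotype per week) at weeks 7, 11, 15, 19.

A behavioral session value for animal *i*, metric *m*, week *w* is

    y = μ_m + a_i − δ_m(w)·[genotype = SOD1] + ε,
    a_i ~ N(0, animal_sd_m²),  ε ~ N(0, noise_sd_m²),

with the programmed deficit piecewise linear:

    δ_m(w) = slope · s_m · max(0, w − w_onset),  w_onset = 12, slope = 0.5/week.

`s_m` is the SD unit of the decline (`deficit_sd`). By default it is the
session-level SD √(animal_sd² + noise_sd²): the SD of a single measurement
is the natural dispersion unit, and because weekly averaging over two
sessions shrinks the baseline pool's SD below it, the expected group z sits
at ≈ −0.58 to −0.61 at week 13 — strictly past the inclusive −0.5 threshold
one week after the deficit start, rather than exactly on it. That makes
"onset at week 13" a stable property of the design instead of a coin flip on
the noise, while week 12 stays at expected z = 0. The default healthy means
and dispersions (pulling 30 ± 4/3 s, hindlimbs 20 ± 3/2.5 s, length
80 ± 12/10 cm, written mean ± session/animal SD) are free parameters of the
generator — the study reports no variance components — chosen as plausible
magnitudes for 1-minute sessions; all conclusions the tests draw are about
recovery of the programmed structure, not about these particular values.

Times and lengths are truncated at zero, pulling time is capped at the 60 s
session, and hindlimb time is capped at pulling time (it is a subset of it).
At the default noise levels these clips move programmed means by < 0.2 s and
nearly equally across baseline and onset weeks, so they do not shift the
programmed crossing.

Weight follows `weight_start_g` = 20 g + 0.15 g/week WT growth with a 1.5 g
between-animal SD and 0.3 g weekly measurement SD; SOD1 animals additionally
lose `sod1_weight_deficit_slope` g/week relative to the WT trend from week
12. That slope is not stated anywhere as a generative quantity; it was fixed
at 0.22 g/week by simulation (analysis/00_calibrate_defaults.py) so the
expected deviation z at week 13 is ≈ −0.6 — the same safety margin past the
threshold that the behavioral metrics get from the session-SD convention —
and frozen.

Histology: expected MN count per field is healthy_count −
slope_count_per_unit × δ (the programmed deficit of the region's matched
metric at the matched behavioral week: M1 ↔ time pulling, L5 ventral horn ↔
time on hindlimbs; week 7 → 9, 19 → 18). Healthy counts (30 CTIP2⁺/field in
M1, 12 large NeuN⁺/field in L5VH) and slopes giving ~50 % loss by week 19
are plausible magnitudes for 40× confocal fields in this model. Per-slice
counts are Gaussian around the expectation, rounded, floored at 0. The noise
SDs (11.0 for M1, 6.4 for L5VH) were calibrated by brute-force sweep — 500
simulated cohorts per grid point, interpolating 1 − R̄² against noise², then
a 0.1-step local refinement — so the mean 4-point group-mean R² reproduces
the reported correlations (0.91 cortical–pulling, 0.83 spinal–hindlimbs),
and then frozen. Only one cortical noise parameter exists, so the
cortical–hindlimb pair is computed but not a calibration target.

## The analysis

* **Session scoring.** Time metrics are interval-union occupancy (merged
  overlaps); displacement sums. Events must satisfy 0 ≤ start < end ≤ 60 and
  displacement ≥ 0; violations raise an error naming the event.
* **Weekly aggregation.** Arithmetic mean of the sessions present that week;
  a week with a single session uses it alone; empty weeks are absent, not
  zero.
* **Baseline.** Pool of per-animal weekly values in weeks 9–11 (group scope)
  or one animal's three weekly values (animal scope); mean plus sample SD
  (ddof = 1). A single-value pool flags SD as undefined; z-scoring a
  zero-or-undefined-SD baseline raises a degenerate-baseline error rather
  than emitting infinities.
* **Onset rules.** Crossings are inclusive (z ≤ −0.5, deviation ≥ 20 %) and a
  single crossing suffices by default; a `sustain = k` option requires k
  consecutive crossing weeks. All four metrics are decline metrics. Only
  post-baseline weeks (> 11) are scanned.
* **Weight counterfactual.** OLS on WT weekly mean relative weights over
  weeks 9–18 (the full-range fit; fitting 9–11 only would estimate a slope
  from three points), re-anchored through (10, SOD1 baseline mean), 10 being
  the baseline-window midpoint. Per-animal weight onsets use absolute grams
  against the animal's own baseline — relative weight has a near-zero
  baseline mean, so a proportional rule is ill-posed there.
* **Weekly comparisons.** Welch t by default (weekly group sizes and
  variances need not match), Sidak family = number of weeks actually tested;
  weeks with < 2 animals per group are skipped and logged. This per-week
  structure approximates the mixed-effects multiple-comparisons analysis it
  stands in for; it is not an equivalence, and no REML model is fitted.
* **Histology statistics.** Pooled-variance unpaired t test by default
  (Welch behind a flag), densities averaged within animal first. The
  " > 250 µm" spinal gate is read as soma cross-sectional area in µm² with a
  strict inequality — 250 µm as a diameter would be anatomically implausible
  for murine MNs; the threshold and unit are configurable.
* **Correlation.** Pearson r/R² and OLS of behavior on density over the 4
  group-mean timepoints; per-animal correlation is available behind a flag.
  Constant series raise an undefined-correlation error.

## Numerical and degenerate-input choices

* Sidak p_adj is clamped to [p, 1]: mathematically 1 − (1 − p)^m ≥ p, but
  floating point can land a hair below at m = 1.
* Identical groups short-circuit to t = 0, p = 1 to avoid 0/0.
* Mode of detected onset weeks takes the earliest week on ties; undetected
  replicates are excluded from the mode.
* All randomness flows through `numpy.random.SeedSequence(seed)` spawned into
  behavior/weight/histology streams, so the standalone histology generator is
  bit-identical to the one embedded in the full cohort and every table is
  reproducible across runs and platforms at the level of recorded values.

## Problem sizes

The replication experiments use 100 cohorts for onset modes and 500 for mean
R² — enough that the mode is stable (≥ 64 % of replicates land on week 13
for every metric) and the R̄² standard error is ≈ 0.005 — and run in seconds
to a couple of minutes on one core.

## What passing tests do and do not show

The generator matches the analysis' distributional assumptions by
construction (Gaussian noise, equal variances, linear decline, no
missingness, no deaths or exclusions, no litter/cage structure, no sex
effect, no floor effects until late disease). Recovery of the programmed
onset week and calibrated R² therefore validates the statistical machinery
and its implementation — not the biological claim, and not robustness to
real-data pathologies such as censoring by death, refusal to perform, or
non-Gaussian session noise. Known limitations: the mixed-effects analysis is
approximated per week; histology noise is purely per-slice (no between-animal
component); truncation at zero mildly biases means when programmed values
approach zero.
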