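# Methods

## Problem and data model

The pipeline predicts a person's Neuropsychiatric Inventory (NPI) total — an
informant-scored measure of behavioral and psychological symptoms of
dementia, bounded by 144 (12 domains × frequency 4 × severity 3) — from the
stream of facial-expression labels a video-based recognition system emits
during day-care attendance.  The upstream recognition model is treated
purely as a data source: the pipeline's inputs are flat CSVs of
`(participant, day, within-day rank, label)` records with labels in
{anger, sadness, neutrality, happiness}, plus dated NPI totals and
participant covariates (sex, age).

Labels are encoded ordinally — anger 1, sadness 2, neutrality 3,
happiness 4 — so that larger codes are more positive and the absolute
difference of consecutive codes measures the size of a mood swing.

## Windowing and features

For each assessment on day `d`, the codes with `day ∈ [d − w, d)` (default
`w = 7`, half-open, assessment day excluded) form the series `E1..EN`,
ordered by `(day, rank)`.  An assessment whose window holds no data is
dropped from the sample and logged, not an error.  `Ei` indexes individual
records, not days, since the source system logs continuously; a
configuration switch (`aggregate_daily`) collapses each day to its modal
code (ties toward the more negative code) for data sources that should be
aggregated per day.  Neither convention is asserted as the original study's;
both are supported.

The ten summary statistics are the five mood-frequency counts (negative =
sadness + anger, plus each mood), the happiness−sadness count difference,
the mean amplitude `ΣEi/N`, the switch frequency `Σ_{i≥2}|Ei − Ei−1|`, the
switch range `max_i|Ei − Ei−1| − min_i|Ei − Ei−1|`, and the sample standard
deviation (denominator `N − 1`).  Conventions for degenerate windows:
at `N = 1` the switch frequency, switch range and SD are defined as 0
(avoiding NaN propagation into the model fits); at `N = 2` the switch range
is 0 because max and min coincide.  Frequencies are raw counts by default; a
`normalize_features` switch divides the count-type features by `N` for
unequally covered windows.  Note the sample SD of codes in {1..4} is bounded
by `1.5·√(N/(N−1))`, not 1.5 — the population bound inflated by the ddof
factor.

## Predictors

**Stepwise linear regression.**  Bidirectional selection on t-test p-values:
repeatedly add the most significant excluded candidate with `p <
alpha_enter` (default 0.05), then drop any included term with `p >
alpha_remove` (default 0.10), to a fixed point (iteration-capped as a cycle
guard).  A candidate whose entry would make the design matrix rank-deficient
— e.g. the exact sum `freq_negative = freq_sadness + freq_anger` once both
addends are included — is permanently barred from entry and reported, never
a crash; this mirrors the known collinearity among the mood counts.  When
the sample is smaller than the candidate pool needs (fewer than p + 2
rows), candidates are capped at `n − 2` by a univariate |correlation|
screen, and the cap is logged; with the study-scale stages (~5–7 training
samples) the cap is active in every stage fit.  A zero-variance target
returns the intercept-only model directly, since any nonzero fit would be
floating-point noise.  The conventional 0.05/0.10 thresholds control
per-test error only; exact-support recovery additionally needs multiplicity
control, so the recovery simulations run entry at the Bonferroni-adjusted
0.05/10 = 0.005.

**Random forest.**  A scikit-learn regression forest (default 500 trees,
fixed seed, otherwise library defaults).  Importance is impurity-based by
default (permutation importance behind a flag); the ranking (1 = most
important) breaks ties by the canonical feature order, so it is a
deterministic bijection even when all importances are 0 (constant target).

**Selection and ensemble.**  The final feature set is the intersection of
the two stages' RF top-k sets (default k = 6); an empty intersection raises
an error suggesting a larger k.  The ensemble is the equal-weight mean
`EM = (LR + RF)/2` of the two *clamped* predictions, always computed from
unrounded values (rounding only in formatted report tables).  All
predictions are clamped to [0, 144]; the ceiling is standard-instrument
knowledge, the floor is what produces the exact zeros seen for asymptomatic
cases.  By the triangle and Minkowski inequalities MAE(EM) and RMSE(EM)
never exceed the LR/RF averages, which the report checks as an internal
invariant.

## Splitting protocols

**Two-stage.**  Participants are split by recruitment order into Stage 1
(first `stage1_size = 7`) and Stage 2 (the rest); within each stage the
assessments are split 50/50 into train/test at random under the run seed
(sample-level, since 7 participants cannot be halved patientwise; train
keeps the odd extra).

**Patientwise k-fold.**  Participants are processed largest-first by sample
count; each joins a currently-smallest fold, preferring the fold where the
participant's NPI level is least represented (ties by seeded draw).  Fold
participant counts therefore differ by at most one, and no participant's
assessments ever straddle folds.  Metrics pool the out-of-fold predictions
rather than averaging per fold, giving a single number per protocol.

**Minimization.**  Sequential Pocock–Simon allocation at participant
granularity into train/test arms with targets `(1 − f, f)` (default
`f = 1/6`): participants are processed in seeded random order, and each
joins the arm minimising the summed marginal imbalance — per factor level,
the range of arm counts divided by the arm targets — over sex, age band
(<80 / ≥80, near the cohort median age) and NPI level, with equal factor
weights.  An always-on total-count pseudo-factor keeps the arm ratio on
target even when every real factor is constant (constant factors are dropped
with a warning).  The best arm is taken deterministically; a classical
biased coin is available via `biased_coin_p < 1`.  Exact ties fall to a
seeded fair coin.  "NPI level" is 0 → none, 1–12 → mild, >12 → marked
(configurable); the mild cut sits at the upper quartile of the cohort's
totals.

## Synthetic cohort generator

Each participant carries a latent severity `s ~ Beta(1.2, 2.2)`.  Moods
evolve as a first-order Markov chain: at each step the state is kept, or
with probability `0.2 + 0.5·s` (capped at 0.9) redrawn from a stationary
distribution whose negative-mood mass is `expit(−2.5 + 3.6·s)` and whose
happiness share of the remaining mass declines from 0.45 by 0.25·s (sadness
takes 0.65 of the negative mass).  Redrawing from the stationary
distribution itself keeps the marginal mood distribution exact while the
realised switching rate grows with severity — so the switch features carry
real signal, as the analysis requires.  The NPI total is generated from the
*realised* window features, `round(clip(−16 + 0.45·freq_negative +
0.15·switch_frequency + N(0, 3), 0, 144))`, which makes downstream parameter
recovery well-posed.  Defaults (23 participants × 30 days × 20 records/day =
13,800 records; 38 assessments, every window fully covered) reproduce the
documented cohort scale, an NPI span of roughly 0–50 with ~40 % exact zeros,
and the published sign pattern of the feature–NPI correlations.  These
scale defaults are targets of convenience — nothing is known about the real
stream's per-day record counts — and are flagged as such.

What the generator does **not** emulate: facial images or video, the
recognition model's error structure (labels are taken as given), the 12 NPI
domains' internal frequency×severity structure, within-day circadian
patterns, and any nonlinearity or participant-level confounding between
moods and symptoms beyond the linear generative link.  Passing tests
therefore demonstrate that the pipeline recovers structure *of this
generative form* at study scale — not that the clinical effect sizes would
replicate on real cohorts.

## Numerical and reporting conventions

Every run derives all randomness (splits, forests, allocation order) from a
single integer seed; reports are byte-identical across reruns.  Correlation
is Pearson with the two-sided t-approximation p-value (Spearman behind a
flag, the NPI being ordinal-like); it requires ≥3 pairs and nonzero variance
and reports NaN (logged) for degenerate evaluation sets rather than failing
a whole run.  Formatted prediction tables round to 3 significant figures
(stage-1 style) or integers (stage-2 style); JSON reports always keep raw
values, and the ensemble is always computed before any rounding.  Stage
coefficients are reported with "N.A." for terms the stepwise fit excluded.

Problem sizes in the shipped drivers and suites — the default cohort, 20
replicate cohorts for the recovery study, 200 simulated strata tables for
the allocation comparison, 100 seeds for the stepwise recovery simulation —
are the package's chosen desk-scale study conditions; they run in a few
minutes on one CPU.

## Known limitations

The stage fits operate on very small samples (≈5–7 training assessments),
so stage-level stepwise coefficient tables are unstable across seeds by
construction — as in any cohort of this size; the cross-stage RF-rank
intersection is the stabilising device.  The two-stage 50/50 split is
sample-level and thus not leakage-free within a stage (a participant can
appear in both halves); the patientwise and minimization protocols are the
leakage-controlled evaluations.  Whether the original analysis fitted its
published stage coefficients on the training halves only is not documented;
this pipeline fits on training halves.  MAE/RMSE/r values computed on
synthetic cohorts characterise the pipeline, not the published cohort, whose
raw data are unavailable.
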