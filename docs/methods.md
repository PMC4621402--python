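# Methods

This note documents the models, the default parameters and where they come
from, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Trajectory model

Each subject's SCCS series is summarized by an ordinary-least-squares fit of
`Y_i = a + b·ln(t_i)`.  The time variable is the 1-based occasion index, not
the calendar week: occasions are scheduled every two weeks (near-equal
spacing), and the 1-based index keeps `ln` defined at the first occasion.
Week-based fitting is available (`time_from="week"`) for irregular designs
with positive week values.

The fluctuation statistic divides the residual sum of squares by `k`, the
number of occasions — it is the population SD of the residuals, not the
`k−2`-denominator regression standard error.  It is therefore defined for
`k = 2` (where it is 0) and is location-invariant.

### Shape rules

Shapes are decided entirely by the signs of the lag-1 differences relative
to the reliable-change threshold (default 3.48 SCCS points), with strict
inequalities: a change of exactly the threshold is treated as noise.  Two
readings of the rules were open:

* *Lag.*  Differences are taken between consecutive observed occasions
  (lag-1).  A lag-2 window was considered and rejected: under lag-2 the
  plateau definition ("no reliable change between adjacent measurements")
  becomes incoherent with the other four rules.
* *"V" strictness.*  The V label requires exactly one reliable decrease and
  an immediately following reliable increase.  It does **not** require the
  rebound to recover the pre-dip level, and it permits additional reliable
  increases elsewhere in the series — the definition constrains the count of
  decreases and the immediacy of the rebound only.

The five rules form a total partition (checked exhaustively against an
independently coded oracle over all integer series with `k ≤ 5` in a
17-point window).  When occasions are missing, differences are taken between
successive *observed* occasions and a warning is logged.

## Thresholds and cutoffs

The reliable-change constants (SCCS 3.48, KS-II 56.6) are configured
constants, not derived quantities: the standard Jacobson–Truax closed form
`z·SD·√(2(1−r))` with plausible published reliabilities does not reproduce
them, so the package treats them as instrument metadata and exposes the
closed form as a separate utility (`reliable_change_threshold`, two-sided
z-convention: 0.95 → 1.959964).

The SCC integration cutoff is the simple midpoint of a clinical
(mean 23.76, SD 7.44) and a healthy (mean 44.88, SD 11.28) baseline
distribution, rounded to the nearest integer: 34.32 → 34.  The SD-weighted
"c" criterion would give ≈ 32.15; the simple midpoint is what reproduces the
applied cutoff.  "Integrated" is SCCS ≥ 34 (inclusive).

The KON-2006 functionality cutoff is the median baseline KON among the
*integrated* subjects, computed on that subgroup but applied to the whole
cohort — the only reading consistent with disposition sizes 22/21/10/32.
"Functional" is KON strictly below the cutoff; a subject exactly at the
cutoff is dysfunctional.  A fixed cutoff can be configured for exact
replication of a known split.

The KS-II score range is taken as 0–595 (85 items with the 0/a/b/c anchors
scored 0/1/4/7): observed sample means above 300 rule out a 0–255 range.

## Inferential battery

* **G-tests.**  `G = 2 Σ O·ln(O/E)` with expecteds from the independence
  margins and `0·ln 0 = 0`, referred to χ²(1); computed via scipy's
  log-likelihood-ratio mode and cross-checked in the tests against the
  algebraic `2n Σ p·ln(p/(row·col))` form.  Strata tests use the
  shape-vs-all-other-shapes column split; tables with a zero margin are
  skipped with a notice, not errored.  No multiple-testing correction is
  applied across the 25 tests by default.
* **Moderation model.**  `change ~ rmse + pd_fi + rmse:pd_fi` by OLS, with
  `pd_fi = 1` for integrated-functional.  The rmse coefficient is thus the
  pooled-other-three slope and the interaction is the IF-minus-others slope
  difference.  "Explained variance" per term is the sequential incremental
  R² with terms entering in the listed order (order-dependent by
  construction; the shares sum to the total R²).
* **ANOVA.**  Type-III sums of squares with sum-to-zero contrasts — the
  common factorial default for unbalanced designs — and partial
  η² = SS_effect/(SS_effect + SS_error).  Empty factor levels are dropped
  with a notice.
* **Variance components.**  The intercept-only three-level model
  `change = μ + u_unit + g_group + e` is fitted by direct maximisation of
  the Gaussian ML or REML criterion (default REML) over the non-negative
  variance components, with μ profiled out by GLS.  The general-purpose
  mixed-model optimisers are unreliable at this design's scale (three
  level-3 units), so the package uses its own L-BFGS-B routine with
  multiple starts on a variance-of-y scale; on balanced designs the REML
  estimates agree with the closed-form ANOVA estimators to 1e-6 (tested).
  Wald statistics are estimate/SE with SEs from a central-finite-difference
  observed information at the optimum, referred to a standard normal.
  *Limitation:* the normal reference is poor for variance components near
  the zero boundary; components estimated at 0 can carry undefined SEs,
  reported as NaN.

## Synthetic cohort generator

The generator emulates the study's structure: 85 subjects with *fixed*
disposition sizes 22/21/10/32 in 7 therapy groups nested in 3 units; six
SCCS occasions (configurable 3–9); baseline SCCS/KON/KS-II drawn per
disposition from truncated normals at the observed subgroup means/SDs,
truncated to the disposition-consistent side of the cutoffs (at
half-integer edges) and to the instrument ranges, then rounded to integer
questionnaire totals.

Trajectories are shape archetypes — step patterns with reliable moves of
±8 points (margin ≈ 2.3× the threshold) and flat moves of 0 — anchored at
the subject's drawn baseline, with the start level clamped so the
noise-free path stays inside 12–60 (the clamp preserves every step size
exactly), plus i.i.d. Gaussian occasion noise.  Shape frequencies per
disposition are the study's observed marginal frequencies.  The per-subject
noise SD is drawn from Gamma(shape 4, scale 0.5) (mean 2, SD 1 SCCS
points): subjects must differ in fluctuation for the RMSE regression to be
estimable; a fixed SD can be configured (recovery checks use SD ≤ 1, where
classification accuracy is ≥ 95%).

Outcomes come in two modes:

* `by_shape` (default): KS-II change ~ Normal per shape × disposition-contrast
  cell.  The four cells with published means/SDs are used verbatim (V/other
  103/87, V/IF 30/116, plateau/IF 129/58, plateau/other −15/68); the
  remaining cells were fixed once so that P(change > 56.6) matches the
  observed improvement proportion of that cell at a typical change SD:
  increase/IF 150/60, increase/other 75/90, discontinuous/IF 40/90,
  discontinuous/other 20/90, decrease −80/70 in both strata.  Improvement
  is *not* assigned; it emerges from the drawn change relative to 56.6.
* `linear`: change = 1.92 + 29.76·rmse + 61.25·pd_fi − 48.49·pd_fi·rmse + ε,
  ε ~ N(0, 85.26²), using the realized RMSE of the generated series — used
  for moderation-recovery checks.  Recovered interaction estimates average
  ≈ −42 rather than −48.5 because the analysis assigns dispositions from
  noisy observed baselines (misclassification attenuates the contrast);
  this is deliberate realism, not estimator bias.

What the generator does **not** emulate: dropout/missingness, within-subject
autocorrelation of occasion noise (an AR(1) extension would be natural but
is not validated), item-level responses, and any mechanistic
assimilation/accommodation dynamics.  Passing recovery tests therefore show
that the pipeline detects the constructed effects under independent
Gaussian noise at study scale — not that real SCC data satisfy those
assumptions.

## Problem sizes and determinism

All simulation-based checks run at the study scale (n = 85 per cohort):
shape recovery pools 5 cohorts, moderation-sign recovery uses 150–200
cohorts, and variance-component recovery uses 15 replications — sizes
chosen to make Monte-Carlo error small relative to the effects being
recovered.  Every stochastic routine takes an explicit seed; k-means uses
10 restarts with a seeded initializer, and the generator is byte-identical
per (config, seed).
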