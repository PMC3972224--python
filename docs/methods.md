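# Methods

## The problem

During eating, aroma compounds are released from the food bolus into
the breath, and the amount and timing of that release depends on how a
person chews, salivates, and forms the bolus. `oralblocks` implements
the statistical machinery to relate a block of aroma-release summaries
(the response, **Y**) to several blocks of oral-physiology measurements
(the predictors, **X1..X5**) within one latent-variable model, and to
quantify *which block matters most*. The reference layout is a cohort
of 48 subjects with six blocks: nine release parameters (Y), bolus
rheology (7 variables), mouth coating / oral volume / bolus moistening
(3), masticatory electromyography (4), and resting and stimulated
saliva composition (8 each).

## Release-curve parameterization

A nosespace recording is intensity versus time for one volatile ion
while a subject eats, annotated with the first-swallow time. The curve
is smoothed with a centered moving average (edge-truncated so constants
are preserved; the window is configurable and should span roughly one
breathing cycle for real breath-modulated data — smoothing is the
caller's choice and defaults to off), then split into a chewing phase
(up to and including the swallow sample) and a post-swallowing phase
(from the next sample to the return to baseline).

Baseline return is the first post-swallow time at which the signal
stays within `baseline ± epsilon` for `k` consecutive samples
(defaults: epsilon = 0.5% of the peak excursion, k = 3). The scan
starts only after the post-swallow signal has first *risen above*
`baseline + epsilon`; without this guard the shallow onset of the
second phase, which necessarily starts near baseline, would be mistaken
for an immediate return. If the signal never rises, the second phase is
the flat tail (zero area, zero maximum); if it never settles, the
recording end is used and a warning logged.

Per phase we report the trapezoid-rule area above baseline (a.u.·min),
the maximum intensity above baseline (a.u.), the time of that maximum
(minutes, measured from mouth entry for both phases — an
interpretation, since the convention for the second phase is genuinely
ambiguous), and the rate Imax/Tmax (a.u./min), plus the phase-area
ratio A1/A2. Ties in the maximum break to the earliest sample. A phase
maximum at baseline leaves Tmax and the rate undefined (NaN); A2 = 0
leaves the ratio undefined rather than infinite; a phase with fewer
than two samples has all its parameters flagged missing rather than
raising.

## Feature rules

* **Replicates**: triplicate measurements are collapsed to their
  median, ignoring missing replicates (even counts take the midpoint).
  The median was preferred over the mean for robustness to outliers.
* **Imputation**: a missing cell is replaced by the median of the
  observed values of the same variable within the same group (in a real
  analysis, the same cheese product; synthetic data use one group). A
  variable with no observation in some group is a hard error.
  Imputation is idempotent by construction.
* **Moistening**: the saliva fraction of bolus water is computed by a
  dry-matter mass balance,
  `Moist_% = 100 · (Bwc − Bdm · Cwc/Cdm) / Bwc`,
  where Bwc/Bdm are bolus water/dry-matter percentages and Cwc/Cdm the
  cheese's. The cheese contributes `Bdm · Cwc/Cdm` water per unit
  bolus (dry matter is conserved through chewing); the excess is
  saliva. This mass-balance form is an interpretation documented here
  because the source protocol states the formula only informally.
* **Alignment**: blocks are joined on the intersection of subject IDs,
  deterministically sorted; a subject missing from any block is dropped
  everywhere (the model needs complete rows).

## Multiblock PLS

Each variable is mean centered and autoscaled (SD, ddof = 1); every
variable of block *b* is then divided by `sqrt(p_b · (n − 1))` so each
block's total sum of squares is exactly 1. This block balancing stops
large blocks from dominating purely by variable count. Y is balanced
the same way.

Dimensions are extracted by a NIPALS-style iteration (block weights
from the Y score, block scores, super weights combining the block
scores, super score, Y weights, Y score) until the super score's
relative change falls below 1e-10. All X blocks *and* Y are deflated on
the super score. With super-score deflation the algorithm is exactly
equivalent to ordinary PLS2 on the column-concatenation of the scaled
blocks — the concatenated weight vector of dimension *h* is
`(a_1 w_1, …, a_B w_B)` and has unit norm — which gives an independent
oracle for the test suite and makes prediction a standard
weights/loadings recursion in the concatenated space.

Numerical choices:

* The Y score is initialized from the Y column of maximal variance
  (first column on the exact ties produced by balanced scaling);
  together with the sign convention (largest-magnitude entry of the
  concatenated weight vector positive) the fit is fully deterministic.
* The iteration cap is 10 000. NIPALS converges linearly at the ratio
  of the two leading eigenvalues, and dimensions beyond the true rank
  of a dataset have near-degenerate spectra: on leave-one-out folds of
  study-scale simulations we measured legitimate convergence after
  700–1500 iterations, so a few-hundred cap would spuriously error.
  Iterations are cheap at these matrix sizes; exhausting the cap raises
  an error carrying the dimension and last score change.

**Block importance** of block *b* on dimension *h* is `a_b(h)²`, the
squared share of that block in the unit-norm concatenated weight
vector; importances of a dimension sum to 1 and are reported as
percentages. (The literature contains several related indices, some
weighting dimensions by explained Y variance; the squared-super-weight
form is the documented choice here.)

**Explained inertia** of dimension *h* for a block is
`100 · ‖t(h) c(h)ᵀ‖² / ‖block₀‖²` with the loadings taken from the
deflation regression and the denominator the preprocessed, undeflated
block (= 1 by construction). Because super scores are mutually
orthogonal, per-dimension inertias are non-negative and cumulative sums
are bounded by 100; the cumulative Y inertia equals the least-squares
projection of Y onto the score space (asserted against a direct
projection oracle in the tests).

## Cross-validation and component choice

Leave-one-subject-out: every fold recomputes preprocessing *and* the
fit on the remaining n − 1 rows, predicts the held-out row, and
accumulates squared error on the fold's preprocessed Y scale (so the
nine response variables contribute comparably). Three selection rules
are provided: PRESS argmin; PRESS plateau (smallest count whose
relative PRESS improvement over its predecessor drops below a
threshold); and the explained-variance rule — the largest count whose
Y-variance increment in the full fit is at least a threshold percent,
6% by default, which is the package default.

A practical note on PRESS-argmin, measured on the synthetic generator:
when noise is much weaker than the signal, PRESS values beyond the true
rank collapse together and the argmin degenerates toward a coin flip
among the over-fitted counts; it discriminates reliably when the noise
standard deviation is comparable to the per-variable signal amplitude.
This is a property of the statistic, not of the implementation, and is
one reason the variance-increment rule is the default.

## Correlation loadings and display filtering

Interpretation plots place each variable at its Pearson correlation
with two retained super scores. Predictor variables are drawn only when
`max(|r|)` over the two plotted dimensions reaches a threshold (0.45 by
default); response variables are always drawn. The magnitude (not the
signed value) is thresholded, since anti-correlated variables are as
informative as correlated ones. Filtering is per plot: a variable can
appear in the (1,2) projection and not in (1,3). Constant variables get
an undefined (NaN) correlation and are never drawn. Plots are produced
for dimension pairs (1,2) and (1,3) when three components are retained.

## Synthetic-data generator

The generator emulates the study conditions: 48 subjects, blocks of
9/7/3/4/8/8 variables carrying the standard variable names, triplicate
replicates, and sporadic missing predictor cells (2% by default,
never exhausting a subject's replicate set for any variable;
placement is re-drawn if it would). Data follow a low-rank latent
model: subject scores i.i.d. standard normal; per-block loading columns
are unit-norm random vectors scaled by a configured magnitude, zero for
blocks without that component's signal; Gaussian noise (sd 0.5 by
default) is added independently per replicate.

The default structure has two latent components: the first loads on the
EMG-like block (magnitude 3) and on Y (magnitude 2); the second on the
rheology-like block (magnitude 2) and on Y (magnitude 1.5). These
magnitudes give per-variable signal-to-noise ratios between roughly 1.5
and 3 — strong enough that the latent structure, not noise, dominates
the fitted model, which is what the design of the emulated study
assumes — and they reproduce the qualitative headline the pipeline is
meant to surface: the masticatory block ranks first on dimension 1.

What the generator does *not* emulate: breathing oscillations on the
release curves (curves are analytic triangles with closed-form areas,
chosen so parameter extraction is testable exactly), inter-block
physiological covariance beyond the configured latent structure,
non-Gaussian measurement error, and structured missingness. Passing
tests therefore demonstrate correctness of the statistical machinery
under a known truth, not fidelity of any particular physiological
claim on real cohorts.

## Problem sizes used in validation

The test suite and the acceptance script run at the study scale
(48 subjects, six blocks, triplicates) for end-to-end checks; oracle
equivalence uses 20 random datasets of 10–30 subjects; block-importance
recovery uses 500-subject single-component datasets over 50 seeds;
component-count recovery runs 50 study-scale rank-2 simulations with
leave-one-out CV. All randomness is seeded; every reported number is
recomputed at run time.

## Known limitations

* No missing-data-aware fitting: imputation is a hard prerequisite of
  the model, as in the emulated protocol.
* No sparse or regularized multiblock variants, no k-fold or
  Monte-Carlo CV, no significance testing of loadings.
* The swallow time is an input annotation; the package does not detect
  swallows from the signal.
* PNG figures are rendered for convenience and are not byte-stable
  across matplotlib versions; the CSV/JSON outputs are the
  deterministic artifacts.
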