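# Methods

## Model and assumptions

The core analysis is symmetric PLS correlation (PLSC) between two blocks
measured on the same subjects: `X` (n x p), the vectorized Fisher-z FC
profiles, and `Y` (n x q), the ordinal mood items treated as continuous.
Both blocks are column z-scored with training statistics (sample SD,
`ddof=1`); `standardize="center"` switches to centering only. The
cross-covariance `R = Yᵀ X/(n−1)` — on the z-scored scale this is the matrix
of pairwise Pearson correlations — is decomposed by SVD, and
`k = min(p, q, n−1)` components are retained (the rank bound on a centered
cross-product). Explained covariance is `s_k²/Σs²`, the fraction of the
squared Frobenius norm of `R` carried by component k.

PLSC assumes linear, homogeneous coupling between blocks and is estimated
without regularization, so with p ≫ n the FC saliences are noisy and
in-sample score correlations are optimistic; the permutation test, the
bootstrap, and the external replication exist precisely to separate signal
from that optimism.

**Sign convention.** Each component's sign pair is arbitrary. The covariance
between paired scores equals the singular value and is therefore never
negative; the residual joint flip is resolved by making the
largest-magnitude mood-salience entry positive (both blocks flipped
together). Recovery analyses against a known planted pattern must still
sign-align, since the convention can mirror the planted direction.

**Confound control.** `residualize` replaces each column by its OLS residual
on covariates plus intercept (age, sex, education, BMI, head motion in the
intended use). It is off by default and exposed as an option, mirroring an
analysis in which confound adjustment is a robustness check rather than part
of the primary model.

## Connectivity

FC is `atanh(r)` of the pairwise Pearson correlation between region time
series, diagonal excluded, upper triangle (i < j, row-major) stored once;
1431 edges for 54 parcels. Zero-variance regions and perfect off-diagonal
correlations are errors, named. Motion scrubbing censors frames with
framewise displacement above a threshold (default 0.5 mm, the common
convention) with optional 1-back/2-forward widening; correlations are then
computed on surviving frames only, with no interpolation — the simplest
defensible contract. Fewer than 50% surviving frames triggers a flagged
warning; censoring everything is an error.

## Resampling inference

**Permutation test.** Rows of `Y` are permuted (X fixed), which breaks the
between-block coupling while preserving each block's internal covariance.
Null singular values are compared rank for rank with the observed ones and
`p = (1+m)/(1+B)`, which cannot be zero. The permuted-solution Procrustes
alignment used by some toolboxes is available (`align=True`) but off by
default: rotating an unrelated null solution onto the observed one spreads
singular-value energy evenly across components, so the aligned null
first-component value systematically undershoots the observed maximum and
the test rejects always. With raw comparison the measured LC1 rejection
rate under pure noise is within [0.03, 0.07] at the 0.05 level (500
replicates; n=200, p=100, q=37, B=200 — the simulation sizes used
throughout the calibration checks, scaled down from the B=5000 one would
use on real data).

**Bootstrap.** Subjects are resampled with replacement; resamples producing
a zero-variance column are redrawn (counted, warned, capped at 10·B
attempts). Each resampled solution is aligned to the observed one in the
singular-value-scaled convention: rotation fitted on the mood saliences by
orthogonal Procrustes, applied to `U_b S_b` and `V_b S_b`. The scaling is
not cosmetic: with as many components as mood items the mood-side rotation
alone is an exact basis change (bootstrap SD collapses to zero), whereas the
scaled aligned FC solution reduces to `R_bᵀ U₀`, a fixed-direction projection
of each resample's cross-covariance. BSR divides the observed scaled
salience by the bootstrap SD of its aligned counterparts; an SD of exactly
zero yields an infinite BSR, flagged rather than raised. Under the global
null the measured `|BSR| > 2` exceedance pooled over features and components
is ≈ 4.7% (n=200, p=200, B=500); the first component alone runs higher
(~10–14%) because its direction is estimated from the same data — the BSR is
z-*like*, not exactly z. Loading CIs are percentile (2.5/97.5) over the
per-resample loadings; "significant" means the 95% CI excludes zero.

**Edge selection.** Reliable: `|BSR| > 2` and significant loading. Robust:
`|BSR| > 3`, significant loading, and within the top `ceil(0.05·p)` edges by
absolute loading. Empty selections are results, not errors.

## Replication

External cohorts are standardized with their own column statistics before
projection onto the training saliences — the choice that removes
scanner/site scale differences and makes predicted scores comparable across
samples; projecting the training cohort itself therefore reproduces the
training scores exactly. Loading similarity correlates the two cohorts'
independently estimated loading vectors for the first component (others via
`component=`); all replication metrics are reported after sign alignment,
with the flip recorded.

## Prediction

Outcome records follow the standard clinical definitions: percentage
reduction `(baseline − post)/baseline × 100` with response requiring a
*strict* >50% reduction and remission a posttreatment total ≤ 7; flags are
decided in exact rational arithmetic so the 50.0% boundary is unambiguous.
Only completers (subjects with posttreatment scores) enter the models; the
exclusion count is warned, and no imputation is performed.

Stepwise fitting is classical forward entry (smallest Wald p < 0.05) with
backward pruning (drop if p > 0.10), capped against enter/remove cycling.
An empty selection is a legitimate reported outcome. Linear models are fit
on per-SD standardized predictors ("standardized B"); logistic models on raw
predictor units so odds ratios are per FC-score unit. Separation (detected
as a non-convergent logistic likelihood) is flagged and falls back to a
ridge-penalized fit for point estimates and probabilities, without
confidence intervals. ROC curves use a threshold sweep; AUC is the
trapezoidal area, identical to the concordant-pair (Mann-Whitney) fraction;
accuracy is evaluated at a fixed 0.5 probability threshold.

## Synthetic cohorts

`generate_cohort` plants one latent component: subject factor `t ~ N(0,1)`,
`X = γ_x t uᵀ + ε`, `Y* = γ_y t vᵀ + ε`, with noise SD 1. The FC salience
`u` places equal positive weight on a random 5% of edges — uniform
magnitudes because per-column z-scoring would otherwise distort unequal
planted weights and make the planted direction unrecoverable in principle.
The mood salience `v` loads negatively on the 10 positive-affect items and
positively elsewhere, echoing the clinical pattern in which higher
subcortical connectivity accompanies greater negative affect. Continuous
item values are mapped onto each instrument's ordinal range by monotone
quantile discretization (PANAS 1–5; HRSD-17 item-specific maxima, total
0–52), which preserves Pearson-based PLSC structure while honoring the
scales.

Defaults emulate the geometry of a naturalistic moderate-to-severe
depression cohort: n = 135 subjects, 1431 edges, 37 items, 84/135
completers, baseline HRSD-17 drawn in 14–33 (the severity inclusion range).
The coupling scales default to γ = 4.2, calibrated so the first component
explains roughly half of the cross-covariance at n = 135; posttreatment
totals follow `clip(round(8 + 3t + N(0,5)), 0, 52)`, which yields a
remission rate near 49% among completers. An optional binary outcome with a
planted log odds ratio per unit of the standardized FC projection (default
scale −0.05, i.e. OR ≈ 0.95, a realistically small clinical effect) supports
odds-ratio recovery studies. `structure_seed` lets independent cohorts share
one planted structure for replication experiments. Recovery tests use
γ = 6 ("strong coupling"), where salience cosines exceed 0.9 at n = 500 and
cross-cohort loading similarities exceed 0.6 at n = 150.

`generate_timeseries` emulates the upstream data instead: per subject,
multivariate-normal frames whose correlation matrix is a shared base plus
`t_i`-scaled shifts on the planted edges, projected to the nearest valid
correlation matrix (eigenvalue clipping with diagonal renormalization,
shrinking toward identity if needed); FD traces are attached so scrubbing is
exercised end to end. No hemodynamics or neural-mass dynamics are modelled.

**What passing tests do and do not show.** The generator matches the
analysis' own statistical assumptions (one linear latent component, Gaussian
noise, exchangeable subjects). Passing recovery and calibration tests
therefore validates the estimator and its inference under those assumptions;
it does not establish robustness to real-data violations — autocorrelated
BOLD noise, site effects, heavy-tailed motion artifacts, multiple overlapping
components, or item-level floor effects.

## Numerical choices

* Sample SDs use `ddof=1` everywhere a block is standardized; loadings use
  population-scale moments internally (ratio-invariant).
* Perfect correlation guard in FC at `|r| ≥ 1 − 1e−12`.
* SVD reconstruction and orthonormality hold to 1e−8/1e−10 on the sizes
  tested; the equivalence oracle (eigendecomposition of `RᵀR`) agrees to
  better than 1e−13.
* Constant columns: errors at fit time (named), NaN-with-warning in
  loadings, redraw in bootstrap resamples.
* Tie-break in robust-edge ranking is stable sort by descending |loading|.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs and results; identical seed + config reproduces outputs byte for
  byte.

## Known limitations

* No regularized/sparse PLS; with p ≫ n the FC-side saliences are noisy, as
  in any unpenalized PLSC analysis at this dimensionality.
* Only symmetric PLSC — no predictive PLS regression.
* The permutation test is calibrated for the first component; later
  components inherit the usual sequential-testing optimism.
* Separation fallback reports penalized point estimates without intervals.
* No multi-site harmonization beyond per-cohort standardization; no NIfTI or
  voxel-level processing (ROI tables are the entry point).
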