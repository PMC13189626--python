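# Methods

## Overview

`cogstack` studies how much of the relationship between general cognition
and mental health is captured by brain-derived measures.  The analysis has
four stages:

1. derive a per-subject general-cognition score (g) from a battery of 12
   cognitive tests via a hierarchical factor model;
2. predict that score from 133 mental-health indices and, separately, from
   each of several blocks of neuroimaging-derived phenotypes, using partial
   least squares regression (PLSR) under nested cross-validation;
3. combine the per-block predictions with stacked second-level models,
   within each imaging pseudo-modality and across all of them;
4. decompose the variance of the observed g score explained by the
   mental-health prediction and by each brain prediction into unique and
   common parts (commonality analysis), and report the common part as a
   percentage of the mental-health effect — "% of the cognition–mental-
   health relationship explained by the brain".

Because the cohort data this design targets are access-restricted, the
package ships a synthetic-cohort generator whose population-level variance
structure is known in closed form; every stage is validated against that
closed form rather than against irreproducible numbers.

## The g-factor model

The 12 test scores are first mapped to their analysis scales: log(x) for
the reaction-time mean and the two trail-making durations, log(x+1) for the
pairs-matching error count, a {0,1,2}→0, {3}→1 recode for the prospective-
memory first answer, negative values to missing everywhere, and zero to
missing only where zero marks an invalid trial (fluid intelligence, picture
vocabulary, trail durations).

Factorability is checked with the KMO sampling-adequacy statistic and
Bartlett's sphericity test.  The number of first-order factors is chosen by
Horn's parallel analysis; the default criterion compares common-factor
(reduced, SMC-on-diagonal) eigenvalues against the mean of eigenvalues
from random normal data of the same shape, with a 95th-percentile rule
available.  The reduced-matrix criterion is the conventional one for
factor counts; note that on pure-noise data the mean rule is a coin flip
at rank one by construction, so noise calibration is assessed with the
p95 rule.

The hierarchical model is
`Sigma = Lambda (gamma gamma' + diag(1 - gamma^2)) Lambda' + Theta`,
with first-order factors at unit variance.  Estimation minimizes the ML
discrepancy `ln|Sigma| + tr(S Sigma^-1) - ln|S| - p` with L-BFGS-B under
bounds (uniquenesses ≥ 1e-6; Heywood cases are bounded and flagged).
Rotational identification follows an exploratory-within-confirmatory
approximation: an oblique (quartimin) ML exploratory solution supplies one
anchor variable per factor (largest absolute loading, no reuse), and the
anchor rows of Lambda are fixed at their exploratory values while all
other loadings are free.  For 12 indicators and 4 factors this leaves
32 + 4 + 12 = 48 free parameters and 30 degrees of freedom.  With a single
factor the second-order structure is vacuous (the factor covariance is the
scalar 1 whatever gamma), so gamma is fixed to 1 by convention and dropped
from the parameter count.

Fit indices follow the standard definitions: chi2 = (n-1) F_ML; CFI and
TLI against the independence baseline (for a correlation matrix the
baseline discrepancy is -ln|S|); RMSEA = sqrt(max(chi2-df,0)/(df(n-1)));
SRMR as the root mean square residual correlation over the lower triangle
including the diagonal; BIC from the full Gaussian log-likelihood.

Subject scores use the Thurstone regression method,
`w = Sigma^-1 Lambda gamma`, applied to scores standardized with training
means and SDs; the factor determinacy `sqrt(gamma' Lambda' Sigma^-1 Lambda
gamma)` bounds the correlation between the score and the true factor.
Scoring method and rotation are the natural open choices here; regression
scores and quartimin are the defaults because they are the field's most
common pairing for this model class.

## Prediction

PLS1 (NIPALS) is implemented from the standard equations: per component
the weight vector is the covariance direction `X'y` normalized to unit
length, scores `t = Xw`, loadings `p = X't/t't`, y-weight `c = y't/t't`,
followed by deflation of X.  Coefficients are `B = W(P'W)^-1 c'`.  When
the deflated covariance vanishes before the requested component count the
Krylov space has saturated and the current solution already equals the
least-squares limit, so extraction stops there.  The only hyperparameter,
the number of components, is selected on ten inner folds by mean absolute
error with ties broken toward fewer components; the default grid is
1..min(20, p, n-1).

The nested design uses five outer folds (near-equal random partition,
sizes differing by at most one) and ten inner folds within each outer
training set.  Everything estimated from data — factor model, scaling,
confound regression, tangent reference, component counts, stacking
hyperparameters — is estimated on the outer-training set only.

Stacked models take base-model predictions as features.  Training-set
features are cross-fitted (inner-fold out-of-fold base predictions), so
the stack cannot learn base-model training optimism; test-set features
come from the base models refit on the full outer-training set.  Four
algorithms are evaluated — elastic net, random forest, RBF-kernel support
vector regression, and gradient-boosted trees — with inner-fold grid
search minimizing MSE, and the algorithm with the highest mean
out-of-sample R² wins (exact ties break in a fixed order).  The default
hyperparameter grids are deliberately small: a 3x3 elastic-net grid
exercises the search machinery, while the tree and kernel models run one
sensible configuration each; all grids are configurable.

Evaluation reports R² (coefficient of determination), Pearson r, MAE and
MSE per outer fold and averaged, with pooled out-of-sample predictions
(each subject predicted exactly once, as a member of its outer test set)
used for significance and commonality.  Significance uses a paired
percentile bootstrap of Pearson's r (5000 resamples by default, 95%
interval, significant if the interval excludes zero).

## Connectivity features

For cohorts with node time series, subject-level connectivity is
quantified by full Pearson correlation, ridge-regularized partial
correlation (`Omega = (S + rho * mean(diag S) * I)^-1`, partial
`r_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`, rho = 0.5; the penalty
multiplies the mean diagonal so shrinkage is scale-free), or tangent-space
parameterization: per-subject Ledoit-Wolf-shrunk covariances of z-scored
series, a reference covariance equal to the Euclidean mean of the training
subjects' covariances, and the matrix logarithm of the whitened subject
covariance, vectorized without the diagonal.  Correlations can be
variance-stabilized with arctanh.  The choice among the three metrics is
treated as a hyperparameter scored on inner folds, with ties resolved in
favour of the tangent parameterization.  Time series are z-scored per node
before covariance estimation in the tangent path only, matching the usual
placement of that step.

## Deconfounding

MRI-type features are standardized with training parameters, and scanner
confounds — site (reference-coded dummies) and acquisition date, plus any
extra numeric columns supplied — are regressed out per outer fold with
training-estimated coefficients applied to the test rows.  Age and sex are
deliberately **not** in the default confound battery: they are study
variables and enter the commonality analysis as their own predictor set
(age, sex, age², age×sex, age²×sex, with age standardized before powers).
Treating them as confounds instead would make the demographic overlap
questions unanswerable by construction.

## Commonality analysis

With pooled predictions aligned by subject (inner join; each analysis uses
the subjects available to its models), three regressions of the observed g
score — on the mental-health prediction, on the brain prediction, and on
both — give `Unique_mh = R2_joint - R2_brain`,
`Unique_brain = R2_joint - R2_mh`,
`Common = R2_mh + R2_brain - R2_joint`, and
`% explained = 100 * Common / R2_mh`.  Negative commonalities
(suppression) are reported as-is with a flag; truncation would break the
exact sum identity, which is asserted to 1e-12.  The three-set extension
over (mental health, brain, demographics) expands R² over the seven
nonempty predictor subsets by inclusion–exclusion.  The %-explained
statistic is reported as undefined whenever the mental-health model itself
is not significant (its bootstrap interval covers zero): a sample R² in
the denominator is never exactly zero, so the flag is tied to
significance rather than to an equality test.

Feature importance uses the Haufe activation-pattern view: the Pearson
correlation between each scaled, centred feature and the pooled predicted
g over outer-test rows, which depends only on features and predictions and
is therefore invariant to model re-parameterization.

## The synthetic cohort

Every observed variable is a linear combination of independent standard-
normal sources plus strictly idiosyncratic noise.  The sources are: a
component shared by g, the mental-health latent and (partially) the brain;
a g–mental-health-only component; one brain-specific component per feature
block; a cognition-only component; standardized age, sex, and a scalar
per-site effect; and residual components for each latent.  g is the
configured weighted sum of sources (weights' squares summing to 1), the
mental-health latent loads on the shared and specific components and on
age/sex, and the 133 items load on that latent with heterogeneous signs
(60% positive) at a common loading of 0.30.  Questionnaire refusal codes
(−818, −121, −3, −1) are injected completely at random at rate 0.02.

Brain blocks do not see the shared source directly: their overlap with
mental health and with demographics flows through two brain-wide
intermediate factors — a "brain view" of the shared source (alignment
0.50) and a brain-aging factor (alignment 0.85 with age).  This mirrors
the strong cross-correlation of real imaging phenotypes and has a
deliberate consequence: what a stack of many blocks can recover saturates
at the intermediate factors instead of growing without bound as blocks are
added, which is what keeps the gain from stacking all modalities in a
realistic range.  Each block's latent splits its signal between the shared
view (`overlap_share`) and its own component, carries a site shift, and
emits features with loadings drawn once per block (uniform 0.25–0.5, fixed
independent of the cohort seed) plus a small direct site leakage.

Raw cognitive scores are produced by inverting the analysis transforms so
the behavioral module is exercised end to end: durations are exponentiated
from the published log-scale means/SDs (e.g. reaction time
exp(6.4 + 0.2z)), counts are rounded and clipped to their published
ranges, the pairs-matching error count is expm1-rounded, and the
prospective-memory item is a Bernoulli draw (success probability rising in
its latent) coded on the raw 0–3 shape scale.  Rounding and
dichotomization attenuate correlations slightly; the Monte-Carlo check at
n=200,000 shows the closed form still matches the simulated pipeline
within ~0.5 percentage points on every %-explained value.

Default study conditions (n = 5000; six blocks of 55–120 features across
three pseudo-modalities) were calibrated once, by the closed-form algebra
alone, so that the population values equal the conditions the analysis is
designed around: mental-health→g correlation 0.31 (after item reliability
and score determinacy ≈ 0.83), per-modality stacked %-explained ≈
26/29/32, all-modality ≈ 48, demographic share of the mental-health
relationship ≈ 44%, and roughly two-thirds of that demographic overlap
visible to the brain.  The pipeline's estimates are then required to
recover these closed-form values within ±5 percentage points (±0.03 for
the correlation); they are never compared against numbers the package
cannot compute.

`theoretical_commonality` computes all population quantities exactly: the
observed-g direction is the population best linear predictor (BLP) of g
from the 12 analysis-scale scores (the Thurstone direction), the
mental-health and per-block predictors are population BLPs of that score
from their feature sets (block features population-residualized on the
site effect, matching the pipeline's deconfounding), stacked predictors
are BLPs from the member blocks' BLPs, and all R²s and commonality
components follow by covariance algebra.  Zero-signal predictors get unit
placeholder variance so stacked systems remain well-posed, and the
%-explained is flagged undefined when the mental-health R² is zero.

What the generator does **not** emulate: non-Gaussian marginals beyond the
discretized cognitive scales, missing-not-at-random refusal patterns,
per-modality subject attrition (supported via masks but off by default),
site-by-feature interactions, and any nonlinearity in the latent
structure.  Passing tests therefore demonstrate that the machinery is
correct and leakage-free under a faithful linear-Gaussian analogue of the
study design, not that the pipeline's numbers would reproduce on the
restricted cohort.

## Problem sizes and numerical choices

The reference checks run the full pipeline at n = 5000 with all four
stacking algorithms, parameter-recovery checks at n = 100,000, and the
Monte-Carlo validation of the closed form at n = 150,000–200,000; these
sizes make sampling error comfortably smaller than the stated tolerances
while keeping a complete run in minutes on a single core.  Optimizer
tolerances: L-BFGS-B with projected-gradient tolerance 1e-6 and loading
bounds ±1.5; NIPALS stops a component when the deflated covariance norm
falls below 1e-12 of its initial value; eigenvalue-based whitening asserts
positive definiteness rather than repairing it.  Exact ties in component
selection go to the smaller count, in metric selection to tangent, in
algorithm selection to a fixed order — all logged in results.

## Known limitations

* The exploratory-within-confirmatory identification fixes whole anchor
  rows at their exploratory values; standard errors of the remaining
  loadings do not account for that conditioning (no SEs are reported).
* The %-explained denominator makes the statistic asymmetric in its two
  predictors by design; it is a share of the mental-health effect, not a
  symmetric overlap measure.
* Percentile bootstrap intervals are first-order accurate only; a BCa
  option is not implemented.
* The weighted PLSR loading summary uses incremental training-R² weights
  by default; a standalone-R² weighting is provided because the summary's
  conventional definition is not unique.
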