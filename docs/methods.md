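# Methods

`cogslope` implements a complete synthetic re-analysis pipeline for
polygenic-score prediction of the *level* and *slope* of general cognitive
ability in a longitudinal ageing cohort: a generative model of the cohort,
polygenic scoring from GWAS summary statistics, a hierarchical
"factors of curves" growth SEM estimated by full-information maximum
likelihood (FIML), and the downstream association, mediation and
validation statistics.  This note records the models, the defaults and the
design decisions, and what the synthetic experiments do and do not show.

## The factors-of-curves model

For each of 13 cognitive tests \(t\) observed at waves \(w = 1..4\), a
linear latent growth curve is assumed:

\[ y_{itw} = I_{it} + \lambda_w S_{it} + \varepsilon_{itw}, \]

with intercept loadings fixed to 1 and slope loadings \(\lambda_w\) fixed
to the time basis \((0, 2.98, 6.71, 9.78)\) years — the mean spacing of the
cohort's four triennial waves (mean ages 69.5, 72.5, 76.3, 79.3).  The
per-test intercepts load on one of four domain *level* factors
(visuospatial, verbal memory, crystallized, processing speed) and the
slopes on four domain *slope* factors; the domain factors load on a
general level factor \(g_L\) and a general slope factor \(g_S\).

**Identification.** The general factors' (residual) variances are fixed to
1; every hierarchical loading is free; test-level intercept/slope factors
keep their natural scale through the fixed observation loadings; domain
factors have free loadings and free residual variances.  Allowed
covariances: \(g_L \leftrightarrow g_S\) and a per-test intercept–slope
residual covariance; no cross-domain residual covariances.  Occasion
residual variances are constant over waves within test (the data the model
emulates do not identify a preferred alternative; the flag
`FoCModelSpec.test_is_cov` / `level_slope_cov` expose the covariance
structure).  Free parameters for the baseline 13-test model: 121; with 52
observed variables the model df is \(52\cdot55/2 + 52 - 121 = 1361\).

**Exogenous predictors.** Genetic predictors and ancestry covariates enter
as exogenous regressors on the general factors, and the likelihood is the
*conditional* normal of the scores given the predictors (complete-case for
the predictors, FIML over the cognitive indicators).  This avoids a
normality assumption on the binary APOE indicator and adds no nuisance
parameters for the predictor block.  Reported effects are standardized
with respect to the outcome — \(\beta = \gamma\,\mathrm{sd}(x)/
\mathrm{sd}(g)\) with the factor SD taken from the model-implied total
variance (residual system plus the exogenous channel) — and with respect
to the predictor only when it is continuous; binary predictors stay 0/1.

## Estimation

Rows are grouped by missingness pattern; each pattern's contribution uses
pre-computed cross-moments of the observed block with the design
\((1, x)\), so one likelihood evaluation costs a Cholesky factorization
per pattern regardless of sample size.  The gradient is analytic:
derivatives with respect to the implied moments are backpropagated through
the RAM algebra \(\Sigma = F(I-A)^{-1}S(I-A)^{-\top}F^\top\) (verified
against central differences in the test suite).  Optimization runs
L-BFGS-B from a data-driven start (per-test growth moments split across
the hierarchy by a fixed prior ratio), then switches to Levenberg-damped
Newton steps using a finite-difference Jacobian of the analytic gradient,
reusing each Hessian while it still makes progress; the quasi-Newton tail
of this surface is ill-conditioned and the Newton polish is what reaches
gradient norms near machine precision in a few seconds.  Additional
jittered starts are attempted only when the first start fails the
convergence check; the reported flag is honest.  Convergence accepts a
solution when the per-observation gradient norm falls below `gtol`
(default 1e-4) *or* when the Newton decrement — the log-likelihood gain a
full regularized Newton step could still achieve — is below 1e-8 of the
absolute log-likelihood; the second, scale-invariant clause matters on
sharp ridges where one parameter's curvature is orders of magnitude above
the rest and a raw gradient norm never looks small.  Variance parameters are optimized on
the log scale; non-positive-definite proposals receive a large finite
penalty, never NaN.  Standard errors come from the inverse observed
information, with the delta method for transformed parameters and for
derived quantities (standardized betas, indirect effects).  Each test's
columns are divided by their wave-1 SD before fitting so all parameters
are O(1); standardized outputs are unaffected and raw-scale growth means
are obtained from the dedicated univariate models.

**Reference models for fit indices.**  The saturated FIML model is
estimated by multivariate-normal EM over the missingness patterns; the
independence baseline has the closed-form available-case solution.
\(\chi^2 = 2(\ell_{sat} - \ell_m)\);
RMSEA \(= \sqrt{\max(\chi^2 - df, 0)/(df\,N)}\) with \(N\) (not \(N-1\))
in the denominator, matching the software family the emulated analysis
used (a dialect flag switches this); CFI and TLI in their standard forms;
SRMR from covariance residuals between the EM-saturated and implied
covariances on the correlation scale.  RMSEA of a zero-df model with zero
chi-square is reported as 0.

**Factor scores** use the regression method per missingness pattern from
the joint latent–observed implied moments, conditioning on any exogenous
regressors; persons with no observed score get missing values.  When an
in-SEM predictor model does not converge, the association functions fall
back to OLS on these factor scores and record
`method = "factor_score_regression"` — mirroring the fallback the emulated
analysis itself needed for its APOE models.

## The synthetic cohort generator

Observed scores are an explicit linear map over independent base variables
(predictor scores, one residual per layer of the hierarchy, sex, baseline
age) plus independent occasion noise, so the population moments of
complete data are available exactly (`GenerativeSpec.implied_moments`) and
the simulator and the moments can never drift apart.  Defaults:

- **Battery.** 13 tests, 3/3/3/4 across the four domains, with baseline
  means/SDs and mean raw slopes per year set to the emulated study's
  descriptives (e.g. block design 33.79 (10.32), −0.423/year; choice
  reaction time is stored time-like and sign-corrected before analysis).
- **Hierarchy.** Standardized test-on-domain level loadings 0.76 and
  domain-on-general 0.8415, so the general level factor carries
  \((0.76\cdot0.8415)^2 \approx 40.9\%\) of each test's level variance;
  slope loadings 0.92 and 0.9075 give \(\approx 69.7\%\) at the general
  slope — the variance shares the emulated analysis reported.
- **Scales.** Latent intercept variance is 85% of baseline raw variance
  (`level_reliability`); latent slope SD is 4.5% of baseline SD per year
  (`slope_sd_ratio`) — about 0.45 baseline SD of fan-out over the 9.8-year
  window, a typical magnitude for cognitive ageing batteries; level–slope
  correlation 0.30 (higher level, shallower decline).
- **Predictors.** Fourteen trait PGSs plus a Bernoulli(0.30) APOE-like
  indicator.  Standardized effect sizes follow the emulated study's
  association tables: education 0.300 on level (realised through the
  mediation structure below), smoking −0.178, schizophrenia −0.148, BMI
  −0.135, …; only APOE carries a slope effect (−0.30, outcome-
  standardized).  True scores are drawn independently across traits; a
  correlated factor-structured battery is available separately
  (`simulate_pgs_battery`) for factor-retention experiments.
- **Childhood score.** The age-11 score is built so its standardized
  regression with the general level factor is 0.814, partly through shared
  genetic effects (`beta_age11`, e.g. education 0.32) and partly through a
  common stable component.
- **Education mediation.** Years of education is `a = 0.3` on the
  education PGS; its path into the level factor (`b`) and the direct path
  (`c'`) default to 0.064 and 0.2808, keeping the marginal education
  effect at 0.300 while making the structural mediated share
  \(ab/(ab+c') = 6.4\%\).  Note: with the default shared-genetics
  structure, the *age-11-adjusted conditional* paths differ from this
  structural triple (other predictors influence both the childhood score
  and later level), so the pipeline's conditional mediation estimate on
  the default cohort is attenuated and flagged unstable; the dedicated
  mediation experiment isolates the triple (a=0.3, b=0.2, c'=0.14,
  proportion 0.30) so the conditional model identifies it.
- **Dropout.** Monotone, with exact per-wave counts (1091/866/697/550 by
  default, scaled proportionally for other cohort sizes).  Retention at
  each wave is sampled without replacement with weights
  \(\exp(\text{mar\_strength}\cdot z)\), where \(z\) is the standardized
  previous-wave composite of *observed* scores (`mar_strength` default
  0.6, giving completers ≈0.7 SD higher baseline composites than
  dropouts).  Because selection depends only on observed data, FIML's
  missing-at-random assumption holds by construction; a univariate model
  of a single test is *not* MAR-complete under this mechanism (selection
  uses the other tests too), which is why single-test growth estimates
  under dropout show the small, realistic missing-data sensitivity that
  FIML over the full battery avoids.
- **Nuisance structure.** Small sex effects on a few tests, a
  cross-sectional entry-age effect equal to each test's longitudinal
  slope, ancestry components as pure noise covariates, and validation
  phenotypes (continuous, binary, ordinal smoking) generated from their
  own PGS with coefficients matching the emulated study's own-phenotype
  table (heights of R² from 0.001% to 13%).

**What the generator does not emulate:** practice/retest effects,
nonlinear trajectories, residual autocorrelation across occasions,
measurement non-invariance, population stratification (the ancestry
components are noise), X-chromosome and imputation artefacts, and
mortality as a distinct process from dropout.  Passing recovery tests on
these data shows the estimation machinery is correct under the stated
model, not that the model is adequate for any particular real cohort.

## Genotypes and polygenic scores

Dosages are Hardy–Weinberg binomials over two haplotype copies whose
latent Gaussian liabilities share an exchangeable correlation within
blocks of 20 adjacent SNPs (default latent r 0.35; blocks span well under
250 kb, separated by 400 kb gaps).  This is the simplest LD structure that
makes clumping non-trivial.  GWAS summary statistics add normal noise with
SE \(=1/\sqrt{N\,2p(1-p)}\) to per-allele true effects drawn for a random
causal subset explaining a set heritability (default 0.25 over 20% of
SNPs, discovery N = 300,000).

Scoring follows clumping + thresholding: harmonization to the target
coding (sign flips for swapped alleles, complement matching for strand
flips, strand-ambiguous A/T–C/G SNPs dropped, irreconcilable pairs dropped
with a logged reason); greedy clumping in ascending p with ties broken by
chromosome, position, id (making the result order-invariant), removing
SNPs with squared dosage correlation > 0.25 within ±250 kb of the index;
then \(score_i = \sum_j d_{ij}\hat\beta_j\) over retained SNPs with
\(p \le\) the threshold (default 1.0; a stricter 0.01 score is built for
the Alzheimer's stats).  Missing dosages are mean-imputed per SNP and
logged.  Scores are standardized before association analyses.

## Downstream statistics

- **FDR.** Benjamini–Hochberg step-up (via statsmodels), applied per
  outcome column across the 15 genetic predictors.
- **Williams's test** for two dependent correlations sharing one variable
  uses the Steiger-modified form with
  \(|R| = 1 - r_{12}^2 - r_{13}^2 - r_{23}^2 + 2r_{12}r_{13}r_{23}\) and
  \(\bar r = (r_{12}+r_{13})/2\), df \(= n-3\); non-positive-definite
  triples are rejected.
- **Own-phenotype validation.** Continuous outcomes: OLS with score and
  outcome standardized; variance explained is the full-model \(R^2\) minus
  the covariate-only \(R^2\).  Binary outcomes: logistic regression;
  variance explained is the difference of Nagelkerke \(R^2\)
  (\((1-e^{2(\ell_0-\ell_1)/n})/(1-e^{2\ell_0/n})\)) between full and
  covariate-only models.  Ordinal smoking status is coded 0/1/2 in a
  linear model (the emulated analysis reports a standardized beta for it,
  implying a continuous-style model).
- **Parallel analysis.** Correlation-matrix (principal-component)
  eigenvalues against the mean (or a quantile) of eigenvalues from
  simulated uncorrelated normal data of the same shape; the retained count
  is the number of *leading* ranks above the reference.  The leading-rank
  (Horn) rule is used rather than a total count because chance crossings
  at deep ranks otherwise inflate retention on weakly correlated
  batteries.
- **Mediation.** Estimated jointly in the SEM with the mediator as an
  observed endogenous variable; indirect = \(a\cdot b\), proportion
  mediated = \(ab/(ab+c')\), delta-method SEs (a bootstrap is not
  provided); the proportion is flagged unstable when the total effect is
  within 10 SEs of zero.

## Pipeline and reproducibility

`run-all` executes: preliminary own-phenotype validation → PGS correlation
matrix and parallel analysis → per-test raw growth curves → baseline
factors-of-curves fit with indices and variance decomposition →
single-predictor level/slope models (15 predictors, FDR per column) →
APOE-adjusted models for FDR-significant level predictors → the
simultaneous 14-PGS model → lifetime-change (age-11-adjusted) models →
education mediation → phenotype-vs-PGS Williams comparisons.  A single
root seed is fanned out deterministically per stage; outputs carry a
provenance header (config SHA-256, seed) and contain no timestamps, so a
given config + seed is byte-reproducible.

## Validation experiments and problem sizes

The acceptance experiments (also run by `scripts/acceptance.py`) use these
sizes, chosen to finish on one CPU in a few minutes: FIML-vs-closed-form
checks at n = 500 over the full 52-variable battery; clumping against a
brute-force oracle on 100 random 50-SNP panels; BH-FDR against the direct
step-up definition on 1000 random vectors; parameter recovery over 20
cohorts at the study scale (n = 1091, retention 1091/866/697/550); type-I
error from 400 null predictors (40 reduced-battery cohorts × 10 predictors
each, factor-score path); MAR robustness over 20 study-scale replicates;
mediation recovery at n = 5000; parallel-analysis structure recovery over
20 replicate 4-factor batteries; and a byte-reproducibility run of the
full pipeline at n = 300 with 2000 SNPs.

## Known limitations

- Linear growth only; no latent-class or nonlinear trajectories, no
  measurement-invariance testing, no mortality/competing-risk models.
- Clumping computes r² in the target sample (no external reference
  panel); no shrinkage or Bayesian PGS weighting; no permutation-based
  empirical thresholds.
- The conditional mediation decomposition is only as interpretable as the
  covariate structure allows (see the note on shared genetic effects
  above).
- Exogenous-variable missingness is handled complete-case, not by FIML.
- Standard errors assume a correctly specified likelihood (observed
  information); no robust/sandwich option.
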