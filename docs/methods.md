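# Methods

## Setting and estimand

One-sample Mendelian randomization with a single continuous instrument G
(a standardized genetic risk score), exposure X, outcome Y, unmeasured
confounder U, and a candidate stratifying variable C.  The causal effect
of X on Y is estimated by the ratio method, theta_hat = beta_YG / beta_XG,
where beta_YG and beta_XG are the coefficients of Y-on-G and X-on-G
regressions (OLS for continuous responses, maximum-likelihood logistic for
binary ones, in which case theta_hat is a log odds ratio per exposure
unit).  With a single instrument the ratio estimate is numerically
identical to two-stage least squares; the test suite verifies this against
statsmodels' IV2SLS to 1e-10.

## Residual-collider stratification

If C is influenced by X (and possibly by Y), conditioning on C opens the
path G → X ← U → Y: within C-strata the instrument is correlated with the
confounder and every stratum estimate is biased.  The package stratifies
instead on the residual collider C0, the OLS residual (with intercept) of
C on G.  C0 has exactly zero sample covariance with G, so strata defined
by its quantiles cannot induce an instrument–confounder association,
while C0 remains highly correlated with C when the instrument explains
little exposure variance.

Strata are the k sample-quantile groups of the chosen stratification
variable (k = 4 by default; cut points at the j/k quantiles with linear
interpolation, intervals right-closed, ties assigned to the lower
stratum).  Per stratum, the instrument–outcome association is estimated
within the stratum and divided by the instrument–exposure association
from the full sample; a per-stratum denominator is available
(`exposure_assoc_scope="per_stratum"`) for settings where the
instrument–exposure association is believed to differ across strata.

Two summary tests are computed over the stratum estimates theta_k with
standard errors se_k:

* **Cochran's Q**: weights w_k = 1/se_k², pooled mean
  theta_bar = Σ w_k theta_k / Σ w_k, Q = Σ w_k (theta_k − theta_bar)²,
  compared with chi-square on K−1 degrees of freedom (upper tail).
* **Trend meta-regression**: fixed-effect weighted least squares of
  theta_k on the stratum centers with weights 1/se_k² and *known*
  variances (the covariance is (XᵀWX)⁻¹, not rescaled by a residual
  variance); two-sided p-value from the normal approximation.  Stratum
  centers are medians (means optional) of the stratifier on its original
  scale — interpretable units such as kg of bodyweight — even when strata
  were formed on the residual scale; residual-scale centers are available
  behind a flag.

The ratio standard error is the first-order delta approximation with the
denominator treated as fixed, se = se_num / |beta_XG|, the usual
convention when the denominator is estimated once in the full sample; a
second-order version adding the denominator-variance term is available.
Confidence intervals are estimate ± 1.96·se.  A denominator below 1e-8 in
absolute value raises an error rather than returning an unstable ratio.

## Data-generating models

All simulated variables derive from G, U, eps_X, eps_Y, eps_C i.i.d.
standard normal:

    X = alpha0 + alpha1 G + alpha2 U + eps_X
    Y = beta0 + beta1 X + beta2 U + eps_Y          (continuous outcomes)
    logit P(Y=1) = beta0 + beta1 X + beta2 U       (binary outcomes)
    C = mu0 + mu1 X + mu2 U [+ mu3 Y] + eps_C

beta1 may be constant or vary per individual with the collider
(beta1 = 0.5 + 0.2 C) or the confounder (0.5 + 0.2 U).  Generation order
is X → C → Y when the collider depends only on the exposure (so a
collider-modified effect is evaluated per individual before Y is drawn)
and X → Y → C when C is a child of the outcome; in the latter case beta1
cannot depend on C.  The nine canonical scenarios:

| family | collider parents | outcome | beta1 in scenarios 1/2/3 |
|---|---|---|---|
| A | X (mu-grid) | continuous | 0 / 0.5 / 0.5 + 0.2 C |
| B | X and Y (mu2 = 0.3, mu3-grid) | continuous | 0 / 0.5 / 0.5 + 0.2 U |
| C | X (mu-grid) | binary, beta0 = 0.5 | 0 / 0.5 / 0.5 + 0.2 C |

Defaults: n = 10,000 individuals, alpha1 = 0.1 (instrument R² ≈ 0.006,
first-stage F ≈ 61), confounding positive (alpha2 = beta2 = 0.8; negative
and mixed settings flip the signs), all intercepts 0 except the binary
beta0 = 0.5.  Parameters stated only as grid ranges need a single default
for one-off simulation: mu1 = mu2 = 1.0 and (B family) mu3 = 1.0, the
strongest tabulated collider effects; the B family's mu1, nowhere fixed
by the study design, defaults to 0.3 to mirror its mu2 and is exposed as
a grid axis.  These choices only matter for direct calls to
`build_scenario` without overrides; every reported quantity sets them
explicitly.

### What the generator does and does not emulate

The generator reproduces the linear-Gaussian world in which the
residual-collider method's properties were derived: a single continuous
instrument, one scalar confounder, homoscedastic noise, and (for binary
outcomes) a correctly specified logit link.  Real applications involve
many weak variants aggregated into a score, non-normal exposures,
selection effects, and measurement error — none of which are simulated.
Passing tests therefore certify the estimators and their calibration
under the stated models, not robustness to those real-data features.
The applied-style fixture (`make_applied_fixture`) is purely synthetic:
it mimics the *shape* of a biobank smoking/bladder-cancer analysis
(binary exposure from a logit model on the score, bodyweight-like
collider lowered by the exposure, rare outcome with an exactly calibrated
baseline prevalence, age/sex covariates) and writes its generating
parameters to a sidecar file so downstream analyses can be checked
against known truth.

## Monte-Carlo engine

`run_replications` simulates m cohorts (m = 500 by default) and applies
one or more analysis plans to the *same* cohorts, mirroring tables that
report several analyses of identical simulated datasets:

* `unadjusted` — the plain ratio estimate;
* `collider_adjusted` — the Y-on-G regression adjusts for C (the biased
  analysis being demonstrated; optionally X-on-G adjusts too);
* `stratify_collider` / `stratify_residual` — quantile strata of C or C0.

Aggregates are the per-stratum (or overall) medians across replicates,
the proportion of replicates whose 95% CI excludes zero (the empirical
type-I error under a null effect), and the proportion with Q-test
p < 0.05.  Replicate r of cell c draws from the seed stream
(base_seed, cell_key, r), where cell_key is a CRC-32 of the cell's own
parameter values: results are bitwise reproducible, independent of worker
count (joblib parallelism optional), and any sub-grid reproduces the
matching cells of a larger run.  Replicates that fail (e.g. logistic
separation in a sparse stratum) are dropped and counted; more than 1%
failures aborts the cell.

Rejection is operationalized as two-sided p < 0.05 (equivalently, the
95% CI excluding zero) throughout; no multiplicity correction is applied.

## Numerical conventions and edge cases

* Complete-case analysis: rows with any missing value among mapped
  variables are dropped at fit time and counted; quantile boundaries are
  computed on the analysis sample.
* `assign_strata` requires at least k distinct values and rejects
  configurations that leave a stratum empty after tie handling.
* Logistic fits require both outcome classes; non-convergence or perfect
  separation raises with a diagnostic rather than returning garbage.
* Genetic risk scores are plain weighted dosage sums; weights are assumed
  pre-harmonized to the dosage effect allele — **no strand or allele
  flipping is attempted**.  Dosages outside [0, 2] are rejected.
* The trend meta-regression needs at least 3 strata and strictly monotone
  centers; with k = 2 only the Q test is reported.

## Known limitations

* Single-instrument, one-sample design: no multi-variant IVW/Egger/median
  estimators, no two-sample summary-statistic mode.
* Fixed-effect meta-regression only; random-effects variants are out of
  scope.
* The first-order ratio SE ignores denominator uncertainty; with weak
  instruments (F ≲ 10) stratum CIs will be anti-conservative — the
  second-order option mitigates but weak-instrument corrections proper
  are not implemented.
* No selection/survival-bias mechanisms and no inverse-probability
  weighting.
* Under *direct* collider stratification the stratum biases do not depend
  on instrument strength, but their estimation precision does, so the
  homogeneity test's empirical rejection rate rises steeply with
  instrument strength and sample size.  The delta-method stratum SEs used
  by the Q test are calibrated (they match the empirical sampling spread
  of the stratum estimates to within a few percent in the unit tests), so
  these rejection rates are properties of the data-generating process,
  not artifacts of understated uncertainty.
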