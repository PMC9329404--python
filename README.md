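# stratamr — collider-safe stratified Mendelian randomization

Mendelian randomization (MR) uses a genetic instrument G (a variant or a
weighted genetic risk score) to estimate the causal effect of an exposure X
on an outcome Y from observational data via the ratio estimator

    theta_hat = beta_YG / beta_XG,

the instrument–outcome association divided by the instrument–exposure
association.  Researchers often want such estimates *within strata* of a
third variable C (does the effect of smoking on bladder cancer vary with
bodyweight?).  But if C is itself influenced by the exposure, C is a
**collider**: conditioning or stratifying on it opens the path
G → X ← U → Y through unmeasured confounders U and biases every stratum
estimate — even under a null causal effect.

`stratamr` implements the remedy of stratifying on the **residual
collider**

    C0 = C − Ĉ,   Ĉ = fitted values of the regression of C on G,

which is independent of the instrument by construction and therefore safe
to stratify on, while remaining highly correlated with C whenever the
instrument explains little of the exposure (the typical MR setting).  The
package provides:

* quantile-stratum MR estimates (stratum-specific beta_YG over the
  full-sample beta_XG), with Cochran's Q homogeneity test and a
  fixed-effect meta-regression trend test over stratum centers;
* the complete simulation framework used to study the problem —
  scenarios with an exposure-only collider (A1–A3), a collider that is a
  child of both exposure and outcome (B1–B3), and binary outcomes through
  a logit model (C1–C3) — plus a Monte-Carlo grid engine that regenerates the full
  simulation-study tables;
* applied-analysis plumbing: CSV/TSV cohort ingestion, weighted genetic
  risk scores from dosages, odds-ratio-scale reporting, and a fully
  synthetic biobank-shaped fixture generator (binary exposure, rare binary
  outcome, bodyweight-like collider).

## Worked example

Simulate a cohort with a true effect of 0.5 and a strong collider, then
compare direct and residual-collider stratification:

```python
import stratamr as smr

params = smr.build_scenario("A2", {"mu1": -1.0, "mu2": -1.0})  # beta1 = 0.5
cohort = smr.simulate_cohort(params, seed=1)

direct = smr.stratified_mr(cohort.g, cohort.x, cohort.y, cohort.c,
                           stratify_on="collider")
safe = smr.stratified_mr(cohort.g, cohort.x, cohort.y, cohort.c,
                         stratify_on="residual_collider")
print("direct  :", direct.estimates.round(2))
print("residual:", safe.estimates.round(2), " Q p =", round(safe.q_pvalue, 3))
```

Output from this exact run:

```
direct  : [0.21 0.04 0.38 0.12]
residual: [0.67 0.61 0.95 0.61]  Q p = 0.469
```

Stratifying directly on the collider drags the stratum estimates far below
the true 0.5 (first quartile 0.21); residual-collider strata scatter
around 0.5 with no evidence of heterogeneity (single-cohort estimates have
standard errors of roughly 0.3 at this instrument strength, so the spread
is sampling noise — Monte-Carlo medians over 500 such cohorts are
0.50–0.51 in every stratum).

The same analysis runs from the shell on any cohort file:

```bash
strata-mr simulate --scenario A2 --seed 1 --set mu1=-1.0 --set mu2=-1.0 --out cohort.csv
strata-mr analyze --data cohort.csv --instrument g --exposure x --outcome y \
    --stratifier c --method residual --out strata.csv
strata-mr grid --scenario A2 --alpha1 0.1 --confounding positive \
    --plans stratify_collider,stratify_residual --m 500 --seed 11 \
    --mu1 -1 --mu2 -1 --out table.csv --layout table2_3
```

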