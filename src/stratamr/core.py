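"""Collider-safe stratified Mendelian randomization.

Stratifying a Mendelian randomization (MR) analysis on a variable that is
downstream of the exposure (a collider) opens a backdoor path between the
genetic instrument and the confounders, biasing stratum-specific causal
estimates.  The remedy implemented here is the *residual collider*: the
residual from regressing the candidate stratifying variable on the
instrument.  By construction it is independent of the instrument, so
quantile strata defined on it leave the instrumental-variable assumptions
intact while still splitting the population by (essentially) the same
variable.

The module is laid out in the order an analysis runs:

1.  configuration — scenario catalogue, confounding settings, seeds;
2.  simulation — the data-generating models (Scenarios A, B, C);
3.  estimation — regressions, the ratio IV estimator, residual-collider
    construction, quantile strata, Cochran's Q and the trend
    meta-regression;
4.  Monte-Carlo study engine — replications, parameter grids, table
    rendering;
5.  data interchange — cohort files, genetic risk scores, an applied-style
    synthetic fixture.

Notation follows the standard one-sample MR setting: G is the instrument
(a genetic score), X the exposure/risk factor, Y the outcome, U an
unmeasured confounder, C the candidate stratifying variable and
C0 = C - fitted(C ~ G) its residual.  The causal estimate is the ratio
theta_hat = beta_YG / beta_XG.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger("stratamr")

__all__ = [
    "EffectSpec",
    "SimulationParams",
    "SimulatedCohort",
    "SCENARIOS",
    "CONFOUNDING_SETTINGS",
    "build_scenario",
    "simulate_cohort",
    "AssocResult",
    "RatioEstimate",
    "StratumEstimate",
    "StratifiedMRResult",
    "FirstStageDiagnostics",
    "linear_assoc",
    "logistic_assoc",
    "ratio_estimate",
    "residualize",
    "assign_strata",
    "stratified_mr",
    "cochran_q",
    "trend_meta_regression",
    "first_stage_diagnostics",
    "AnalysisPlan",
    "ReplicationSummary",
    "run_replications",
    "run_grid",
    "summarize_to_table",
    "CohortTable",
    "read_cohort_table",
    "compute_grs",
    "make_applied_fixture",
    "analyze_cohort",
]

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: (alpha2, beta2) pairs: effect of the confounder U on X and on Y.
CONFOUNDING_SETTINGS: dict[str, tuple[float, float]] = {
    "positive": (0.8, 0.8),
    "negative": (-0.8, -0.8),
    "mixed": (0.8, -0.8),
}

#: Default number of individuals per simulated cohort.
DEFAULT_N = 10_000

#: Default number of Monte-Carlo replicates per parameter setting.
DEFAULT_M = 500

#: |beta_XG| below this is treated as a failed (weak) denominator.
WEAK_DENOMINATOR_TOL = 1e-8

_MODIFIERS = ("none", "collider", "confounder")
_COLLIDER_PARENTS = ("exposure_only", "exposure_and_outcome")
_OUTCOME_TYPES = ("continuous", "binary")


def _seed_sequence(seed) -> np.random.SeedSequence:
    """Normalise ints / int-sequences / SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (int, np.integer)):
        if seed < 0:
            raise ValueError("seed must be a non-negative integer")
        return np.random.SeedSequence(int(seed))
    return np.random.SeedSequence([int(s) for s in seed])


def _stable_key(*parts) -> int:
    """Deterministic 32-bit key for a cell of a parameter grid.

    Keys depend only on the cell's own parameter values, so running a
    sub-grid reproduces exactly the values of the corresponding cells of a
    larger run.
    """
    text = "|".join(f"{p:g}" if isinstance(p, float) else str(p) for p in parts)
    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# simulation: data-generating models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """Causal effect of the exposure on the outcome, possibly varying.

    The per-individual effect is ``intercept + slope * modifier_i`` where
    the modifier is the collider C, the confounder U, or nothing (constant
    effect).  A collider modifier is only meaningful when C is generated
    before Y, i.e. when the collider is a child of the exposure only.
    """

    intercept: float
    modifier: str = "none"
    slope: float = 0.0

    def __post_init__(self):
        if self.modifier not in _MODIFIERS:
            raise ValueError(f"modifier must be one of {_MODIFIERS}, got {self.modifier!r}")
        if not np.isfinite(self.intercept) or not np.isfinite(self.slope):
            raise ValueError("EffectSpec coefficients must be finite")

    def evaluate(self, collider=None, confounder=None) -> np.ndarray | float:
        """Per-individual effect values given the modifier arrays."""
        if self.modifier == "none":
            return self.intercept
        source = collider if self.modifier == "collider" else confounder
        if source is None:
            raise ValueError(f"modifier {self.modifier!r} requires its array")
        return self.intercept + self.slope * np.asarray(source, dtype=float)


@dataclass
class SimulationParams:
    """All coefficients of the data-generating model for one cohort.

    The model (all noise terms standard normal, independent)::

        X = alpha0 + alpha1*G + alpha2*U + eps_X
        Y = beta0  + beta1*X  + beta2*U  + eps_Y      (continuous)
        logit P(Y=1) = beta0 + beta1*X + beta2*U      (binary)
        C = mu0 + mu1*X + mu2*U [+ mu3*Y] + eps_C

    ``mu3`` is only active when ``collider_parent == "exposure_and_outcome"``
    (the B family), in which case Y is generated before C and ``beta1``
    cannot depend on C.
    """

    n: int = DEFAULT_N
    alpha0: float = 0.0
    alpha1: float = 0.1
    alpha2: float = 0.8
    beta0: float = 0.0
    beta1: EffectSpec = field(default_factory=lambda: EffectSpec(0.0))
    beta2: float = 0.8
    mu0: float = 0.0
    mu1: float = 1.0
    mu2: float = 1.0
    mu3: float = 0.0
    outcome_type: str = "continuous"
    collider_parent: str = "exposure_only"

    def __post_init__(self):
        if isinstance(self.beta1, (int, float)):
            self.beta1 = EffectSpec(float(self.beta1))
        self.validate()

    def validate(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError("n must be an integer >= 2")
        for name in ("alpha0", "alpha1", "alpha2", "beta0", "beta2", "mu0", "mu1", "mu2", "mu3"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")
        if self.outcome_type not in _OUTCOME_TYPES:
            raise ValueError(f"outcome_type must be one of {_OUTCOME_TYPES}")
        if self.collider_parent not in _COLLIDER_PARENTS:
            raise ValueError(f"collider_parent must be one of {_COLLIDER_PARENTS}")
        if self.collider_parent == "exposure_and_outcome" and self.beta1.modifier == "collider":
            raise ValueError(
                "beta1 cannot depend on the collider when the collider is a "
                "child of the outcome (C is generated after Y)"
            )
        if self.outcome_type == "binary" and self.collider_parent != "exposure_only":
            raise ValueError("binary outcomes require collider_parent='exposure_only'")

    def replace(self, **overrides) -> "SimulationParams":
        return dataclasses.replace(self, **overrides)


@dataclass
class SimulatedCohort:
    """Per-individual arrays of one simulated cohort.

    ``x0`` is the residual exposure (exposure minus its fitted value on the
    instrument) and ``c0`` the residual collider; ``c0`` is ``None`` until
    computed via :meth:`add_residual_collider` or inside
    :func:`stratified_mr`.
    """

    g: np.ndarray
    u: np.ndarray
    x: np.ndarray
    x0: np.ndarray
    y: np.ndarray
    c: np.ndarray
    c0: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.g.shape[0]

    def add_residual_collider(self) -> "SimulatedCohort":
        if self.c0 is None:
            self.c0 = residualize(self.c, self.g)
        return self

    def to_frame(self) -> pd.DataFrame:
        cols = {"g": self.g, "u": self.u, "x": self.x, "x0": self.x0, "y": self.y, "c": self.c}
        if self.c0 is not None:
            cols["c0"] = self.c0
        return pd.DataFrame(cols)


def _scenario_table() -> dict[str, SimulationParams]:
    a_kw = dict(mu1=1.0, mu2=1.0)
    b_kw = dict(mu1=0.3, mu2=0.3, mu3=1.0, collider_parent="exposure_and_outcome")
    c_kw = dict(mu1=1.0, mu2=1.0, beta0=0.5, outcome_type="binary")
    return {
        "A1": SimulationParams(beta1=EffectSpec(0.0), **a_kw),
        "A2": SimulationParams(beta1=EffectSpec(0.5), **a_kw),
        "A3": SimulationParams(beta1=EffectSpec(0.5, "collider", 0.2), **a_kw),
        "B1": SimulationParams(beta1=EffectSpec(0.0), **b_kw),
        "B2": SimulationParams(beta1=EffectSpec(0.5), **b_kw),
        "B3": SimulationParams(beta1=EffectSpec(0.5, "confounder", 0.2), **b_kw),
        "C1": SimulationParams(beta1=EffectSpec(0.0), **c_kw),
        "C2": SimulationParams(beta1=EffectSpec(0.5), **c_kw),
        "C3": SimulationParams(beta1=EffectSpec(0.5, "collider", 0.2), **c_kw),
    }


SCENARIOS: dict[str, SimulationParams] = _scenario_table()

# Fields that define the scenario family and may not be overridden.
_SCENARIO_FIXED = ("outcome_type", "collider_parent")


def build_scenario(scenario_id: str, overrides: Mapping | None = None) -> SimulationParams:
    """Canonical parameters for one of the nine simulation scenarios.

    A1/B1/C1: null effect (beta1 = 0); A2/B2/C2: constant beta1 = 0.5;
    A3/C3: beta1 = 0.5 + 0.2*C; B3: beta1 = 0.5 + 0.2*U.  The B family has
    the collider downstream of the outcome (mu2 = 0.3, mu3 on its own
    grid); the C family has a binary outcome generated through a logit
    model with beta0 = 0.5.  ``overrides`` may replace any non-defining
    field (e.g. ``{"alpha1": 0.3}`` or ``{"confounding": "mixed"}``).
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; choose from {sorted(SCENARIOS)}")
    params = SCENARIOS[scenario_id]
    overrides = dict(overrides or {})
    if "confounding" in overrides:
        setting = overrides.pop("confounding")
        if setting not in CONFOUNDING_SETTINGS:
            raise ValueError(f"unknown confounding setting {setting!r}")
        overrides.setdefault("alpha2", CONFOUNDING_SETTINGS[setting][0])
        overrides.setdefault("beta2", CONFOUNDING_SETTINGS[setting][1])
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown override field(s): {sorted(unknown)}")
    fixed = set(overrides) & set(_SCENARIO_FIXED)
    if fixed:
        raise ValueError(
            f"field(s) {sorted(fixed)} are fixed by scenario {scenario_id} and cannot be overridden"
        )
    return params.replace(**overrides)


def simulate_cohort(params: SimulationParams, seed) -> SimulatedCohort:
    """Draw one cohort from the data-generating model.

    G, U and the three noise terms are i.i.d. standard normal.  Generation
    order is X -> C -> Y for exposure-only colliders (so a collider-modified
    effect can be evaluated per individual) and X -> Y -> C when the
    collider is also a child of the outcome.  The same seed gives a
    bitwise-identical cohort.
    """
    params.validate()
    rng = np.random.default_rng(_seed_sequence(seed))
    n = int(params.n)
    g, u, eps_x, eps_y, eps_c = rng.standard_normal((5, n))
    x = params.alpha0 + params.alpha1 * g + params.alpha2 * u + eps_x

    if params.collider_parent == "exposure_only":
        c = params.mu0 + params.mu1 * x + params.mu2 * u + eps_c
        beta1 = params.beta1.evaluate(collider=c, confounder=u)
        lin = params.beta0 + beta1 * x + params.beta2 * u
        if params.outcome_type == "binary":
            y = (rng.random(n) < expit(lin)).astype(float)
        else:
            y = lin + eps_y
    else:
        beta1 = params.beta1.evaluate(confounder=u)
        y = params.beta0 + beta1 * x + params.beta2 * u + eps_y
        c = params.mu0 + params.mu1 * x + params.mu2 * u + params.mu3 * y + eps_c

    x0 = residualize(x, g)
    return SimulatedCohort(g=g, u=u, x=x, x0=x0, y=y, c=c)


# ---------------------------------------------------------------------------
# estimation: associations, ratio IV, residual collider, strata, tests
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    """One instrument-association coefficient with its standard error."""

    beta: float
    se: float
    n_used: int
    model: str
    adjusted_for: tuple[str, ...] = ()


@dataclass
class RatioEstimate:
    """The ratio IV estimate theta_hat = beta_YG / beta_XG with a 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    numerator: AssocResult
    denominator: AssocResult

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class StratumEstimate:
    index: int
    lower: float
    upper: float
    n: int
    center: float
    ratio: RatioEstimate


@dataclass
class StratifiedMRResult:
    strata: list[StratumEstimate]
    stratify_on: str
    q_stat: float
    q_df: int
    q_pvalue: float
    trend_slope: float | None = None
    trend_se: float | None = None
    trend_pvalue: float | None = None

    @property
    def estimates(self) -> np.ndarray:
        return np.array([s.ratio.estimate for s in self.strata])

    @property
    def ses(self) -> np.ndarray:
        return np.array([s.ratio.se for s in self.strata])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": s.index,
                "lower": s.lower,
                "upper": s.upper,
                "n": s.n,
                "center": s.center,
                "estimate": s.ratio.estimate,
                "se": s.ratio.se,
                "ci_low": s.ratio.ci_low,
                "ci_high": s.ratio.ci_high,
            }
            for s in self.strata
        ]
        return pd.DataFrame(rows)


@dataclass
class FirstStageDiagnostics:
    r2: float
    f_stat: float


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(np.asarray(a, dtype=float))
    return mask


def _as_covariate_items(covariates) -> list[tuple[str, np.ndarray]]:
    if covariates is None:
        return []
    if isinstance(covariates, Mapping):
        return [(str(k), np.asarray(v, dtype=float)) for k, v in covariates.items()]
    raise TypeError("covariates must be a mapping of name -> numeric vector")


def linear_assoc(response, instrument, covariates=None) -> AssocResult:
    """OLS coefficient of the response on the instrument (with intercept).

    Rows with any missing value among response, instrument or covariates
    are dropped.  Without covariates this is a plain simple regression;
    with covariates an OLS fit adjusting for them, the reported beta being
    the instrument coefficient.
    """
    response = np.asarray(response, dtype=float)
    instrument = np.asarray(instrument, dtype=float)
    if response.shape != instrument.shape:
        raise ValueError("response and instrument must have equal length")
    cov_items = _as_covariate_items(covariates)
    mask = _complete_cases(response, instrument, *(v for _, v in cov_items))
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("linear_assoc: dropped %d incomplete rows", n_dropped)
    y, g = response[mask], instrument[mask]
    p = 2 + len(cov_items)
    if y.size < p + 1:
        raise ValueError(f"need at least {p + 1} complete cases, got {y.size}")
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant (zero variance)")

    if not cov_items:
        fit = stats.linregress(g, y)
        return AssocResult(beta=float(fit.slope), se=float(fit.stderr), n_used=y.size, model="linear")

    design = np.column_stack([np.ones(y.size), g] + [v[mask] for _, v in cov_items])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("perfect collinearity among predictors")
    res = sm.OLS(y, design).fit()
    return AssocResult(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        n_used=y.size,
        model="linear",
        adjusted_for=tuple(k for k, _ in cov_items),
    )


def logistic_assoc(response, instrument, covariates=None) -> AssocResult:
    """Maximum-likelihood logistic regression coefficient (log-odds per unit
    of the instrument), with intercept and optional covariate adjustment."""
    response = np.asarray(response, dtype=float)
    instrument = np.asarray(instrument, dtype=float)
    if response.shape != instrument.shape:
        raise ValueError("response and instrument must have equal length")
    cov_items = _as_covariate_items(covariates)
    mask = _complete_cases(response, instrument, *(v for _, v in cov_items))
    y, g = response[mask], instrument[mask]
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("binary response must be coded 0/1")
    if classes.size < 2:
        raise ValueError("response contains a single class; logistic fit is undefined")
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant (zero variance)")
    design = np.column_stack([np.ones(y.size), g] + [v[mask] for _, v in cov_items])
    try:
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic regression failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic regression did not converge (possible separation)")
    return AssocResult(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        n_used=y.size,
        model="logistic",
        adjusted_for=tuple(k for k, _ in cov_items),
    )


def ratio_estimate(
    numerator: AssocResult,
    denominator: AssocResult,
    weak_denominator_tol: float = WEAK_DENOMINATOR_TOL,
    second_order: bool = False,
) -> RatioEstimate:
    """Ratio IV estimate: instrument-outcome over instrument-exposure.

    The standard error is the first-order delta approximation treating the
    denominator as fixed, se_num / |beta_XG| — the usual one-sample MR
    convention when the denominator is estimated once in the full sample.
    ``second_order=True`` adds the denominator-variance term.
    """
    b_den = denominator.beta
    if abs(b_den) < weak_denominator_tol:
        raise ValueError(
            f"instrument-exposure association too weak (|beta|={abs(b_den):.3g} "
            f"< {weak_denominator_tol:g}); ratio estimate unstable"
        )
    estimate = numerator.beta / b_den
    if second_order:
        se = np.sqrt(
            numerator.se**2 / b_den**2 + numerator.beta**2 * denominator.se**2 / b_den**4
        )
    else:
        se = numerator.se / abs(b_den)
    half = 1.96 * se
    return RatioEstimate(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - half),
        ci_high=float(estimate + half),
        numerator=numerator,
        denominator=denominator,
    )


def residualize(collider, instrument) -> np.ndarray:
    """Residual collider: OLS residuals (with intercept) of C on G.

    The output has exactly zero sample covariance with the instrument and
    zero mean, so quantile strata defined on it cannot re-open the
    instrument-confounder path.
    """
    c = np.asarray(collider, dtype=float)
    g = np.asarray(instrument, dtype=float)
    if c.shape != g.shape:
        raise ValueError("collider and instrument must have equal length")
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant (zero variance)")
    gc = g - g.mean()
    slope = gc.dot(c) / gc.dot(gc)
    return c - c.mean() - slope * gc


def _stratum_cuts(values: np.ndarray, k: int) -> np.ndarray:
    return np.quantile(values, np.arange(1, k) / k)


def assign_strata(values, k: int) -> np.ndarray:
    """Quantile-stratum labels 1..k, ascending with value.

    Cut points are the j/k sample quantiles (linear interpolation).
    Intervals are right-closed (a value equal to a cut point goes to the
    lower stratum); the first interval is closed on both ends.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(values).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} strata")
    cuts = _stratum_cuts(values, k)
    labels = np.searchsorted(cuts, values, side="left") + 1
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if (counts == 0).any():
        empty = [i + 1 for i in range(k) if counts[i] == 0]
        raise ValueError(f"stratum/strata {empty} empty after tie handling; use fewer strata")
    return labels


def cochran_q(estimates, ses) -> tuple[float, int, float]:
    """Cochran's Q homogeneity test over stratum estimates.

    Inverse-variance weights w = 1/se^2; Q = sum w*(theta - theta_bar)^2
    around the fixed-effect pooled mean; upper-tail chi-square p-value on
    K-1 degrees of freedom.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape or theta.size < 2:
        raise ValueError("need >= 2 estimates with matching standard errors")
    if not (np.isfinite(theta).all() and np.isfinite(se).all()):
        raise ValueError("non-finite estimate or standard error")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = w.dot(theta) / w.sum()
    q = float(w.dot((theta - pooled) ** 2))
    df = theta.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def trend_meta_regression(estimates, ses, centers) -> tuple[float, float, float]:
    """Fixed-effect meta-regression of stratum estimates on stratum centers.

    Weighted least squares with weights 1/se^2 and known (not re-estimated)
    variances; the slope's two-sided p-value comes from the normal
    approximation.  Detects a dose-like gradient of the causal effect
    across the stratifier distribution.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    cen = np.asarray(centers, dtype=float)
    if not (theta.shape == se.shape == cen.shape):
        raise ValueError("estimates, ses and centers must have equal length")
    if theta.size < 3:
        raise ValueError("meta-regression needs >= 3 strata")
    if (se <= 0).any() or not np.isfinite(np.concatenate([theta, se, cen])).all():
        raise ValueError("inputs must be finite with positive standard errors")
    d = np.diff(cen)
    if not ((d > 0).all() or (d < 0).all()):
        raise ValueError("stratum centers must be strictly monotone")
    design = np.column_stack([np.ones(theta.size), cen])
    w = 1.0 / se**2
    xtwx = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("collinear or constant stratum centers") from exc
    coef = cov @ design.T @ (w * theta)
    slope = float(coef[1])
    slope_se = float(np.sqrt(cov[1, 1]))
    z = slope / slope_se
    return slope, slope_se, float(2 * stats.norm.sf(abs(z)))


def first_stage_diagnostics(exposure, instrument) -> FirstStageDiagnostics:
    """Instrument-strength diagnostics of the exposure-on-instrument OLS:
    R-squared and the first-stage F statistic (n-2)*R2/(1-R2)."""
    x = np.asarray(exposure, dtype=float)
    g = np.asarray(instrument, dtype=float)
    mask = _complete_cases(x, g)
    x, g = x[mask], g[mask]
    if np.ptp(g) == 0:
        raise ValueError("instrument is constant (zero variance)")
    fit = stats.linregress(g, x)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        raise ValueError("R^2 = 1: F statistic is infinite")
    f = (x.size - 2) * r2 / (1 - r2)
    return FirstStageDiagnostics(r2=r2, f_stat=float(f))


def stratified_mr(
    instrument,
    exposure,
    outcome,
    stratifier,
    k: int = 4,
    stratify_on: str = "residual_collider",
    outcome_type: str = "continuous",
    exposure_type: str = "continuous",
    exposure_assoc_scope: str = "full_sample",
    covariates=None,
    center_summary: str = "median",
    residual_scale_centers: bool = False,
) -> StratifiedMRResult:
    """Stratum-specific MR estimates with homogeneity and trend tests.

    The stratifier is optionally replaced by its residual on the instrument
    (``stratify_on="residual_collider"``), individuals are split into k
    quantile strata, the instrument-outcome association is estimated within
    each stratum and divided by the instrument-exposure association from
    the full sample (per-stratum denominators optional).  Stratum centers
    are summaries (median by default) of the stratifier on its ORIGINAL
    scale, so they stay interpretable (e.g. kg of bodyweight) even under
    residual stratification; ``residual_scale_centers=True`` switches to
    the stratification scale.
    """
    if stratify_on not in ("collider", "residual_collider"):
        raise ValueError("stratify_on must be 'collider' or 'residual_collider'")
    if exposure_assoc_scope not in ("full_sample", "per_stratum"):
        raise ValueError("exposure_assoc_scope must be 'full_sample' or 'per_stratum'")
    if center_summary not in ("median", "mean"):
        raise ValueError("center_summary must be 'median' or 'mean'")

    g = np.asarray(instrument, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    c = np.asarray(stratifier, dtype=float)
    cov_items = _as_covariate_items(covariates)
    mask = _complete_cases(g, x, y, c, *(v for _, v in cov_items))
    g, x, y, c = g[mask], x[mask], y[mask], c[mask]
    cov_items = [(name, v[mask]) for name, v in cov_items]

    strat_values = residualize(c, g) if stratify_on == "residual_collider" else c
    labels = assign_strata(strat_values, k)
    cuts = _stratum_cuts(strat_values, k)
    bounds = np.concatenate([[-np.inf], cuts, [np.inf]])

    outcome_fit = logistic_assoc if outcome_type == "binary" else linear_assoc
    exposure_fit = logistic_assoc if exposure_type == "binary" else linear_assoc
    denominator = None
    if exposure_assoc_scope == "full_sample":
        denominator = exposure_fit(x, g, dict(cov_items) or None)

    center_fn = np.median if center_summary == "median" else np.mean
    center_source = strat_values if residual_scale_centers else c

    strata: list[StratumEstimate] = []
    for j in range(1, k + 1):
        sel = labels == j
        try:
            num = outcome_fit(y[sel], g[sel], {n_: v[sel] for n_, v in cov_items} or None)
            den = denominator if denominator is not None else exposure_fit(
                x[sel], g[sel], {n_: v[sel] for n_, v in cov_items} or None
            )
            ratio = ratio_estimate(num, den)
        except ValueError as exc:
            raise ValueError(f"stratum {j}: {exc}") from exc
        strata.append(
            StratumEstimate(
                index=j,
                lower=float(bounds[j - 1]),
                upper=float(bounds[j]),
                n=int(sel.sum()),
                center=float(center_fn(center_source[sel])),
                ratio=ratio,
            )
        )

    est = np.array([s.ratio.estimate for s in strata])
    ses = np.array([s.ratio.se for s in strata])
    q, df, q_p = cochran_q(est, ses)
    trend_slope = trend_se = trend_p = None
    if k >= 3:
        centers = np.array([s.center for s in strata])
        try:
            trend_slope, trend_se, trend_p = trend_meta_regression(est, ses, centers)
        except ValueError as exc:
            logger.warning("trend meta-regression unavailable: %s", exc)
    return StratifiedMRResult(
        strata=strata,
        stratify_on=stratify_on,
        q_stat=q,
        q_df=df,
        q_pvalue=q_p,
        trend_slope=trend_slope,
        trend_se=trend_se,
        trend_pvalue=trend_p,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo study engine
# ---------------------------------------------------------------------------

_MODES = ("unadjusted", "collider_adjusted", "stratify_collider", "stratify_residual")


@dataclass
class AnalysisPlan:
    """How each simulated cohort is analysed.

    unadjusted          ratio estimate, no collider in sight (the valid analysis);
    collider_adjusted   the Y-on-G regression adjusts for C (the biased analysis);
    stratify_collider   quantile strata of C itself;
    stratify_residual   quantile strata of the residual collider C0.
    """

    mode: str
    k: int = 4
    alpha: float = 0.05
    exposure_assoc_scope: str = "full_sample"
    center_summary: str = "median"
    adjust_exposure_assoc: bool = False  # also adjust X-on-G for C (collider_adjusted only)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.stratified and self.k < 2:
            raise ValueError("stratified modes need k >= 2")

    @property
    def stratified(self) -> bool:
        return self.mode in ("stratify_collider", "stratify_residual")


@dataclass
class ReplicationSummary:
    """Monte-Carlo aggregates over m replicates of one parameter setting."""

    mode: str
    m: int
    m_used: int
    median_estimate: float | np.ndarray | None
    rejection_rate: float | None
    het_rejection_rate: float | None
    trend_rejection_rate: float | None
    mean_r2: float
    mean_f: float
    k: int | None = None
    n_failed: int = 0


def _apply_plan(cohort: SimulatedCohort, plan: AnalysisPlan, outcome_type: str) -> dict:
    outcome_fit = logistic_assoc if outcome_type == "binary" else linear_assoc
    if plan.mode in ("unadjusted", "collider_adjusted"):
        covs = {"c": cohort.c} if plan.mode == "collider_adjusted" else None
        num = outcome_fit(cohort.y, cohort.g, covs)
        den_covs = covs if (plan.mode == "collider_adjusted" and plan.adjust_exposure_assoc) else None
        den = linear_assoc(cohort.x, cohort.g, den_covs)
        ratio = ratio_estimate(num, den)
        return {"estimate": ratio.estimate, "reject": ratio.excludes_zero}
    res = stratified_mr(
        cohort.g,
        cohort.x,
        cohort.y,
        cohort.c,
        k=plan.k,
        stratify_on="collider" if plan.mode == "stratify_collider" else "residual_collider",
        outcome_type=outcome_type,
        exposure_assoc_scope=plan.exposure_assoc_scope,
        center_summary=plan.center_summary,
    )
    return {
        "stratum_estimates": res.estimates,
        "het_reject": res.q_pvalue < plan.alpha,
        "trend_reject": (res.trend_pvalue is not None and res.trend_pvalue < plan.alpha),
    }


def _one_replicate(params: SimulationParams, plans: Sequence[AnalysisPlan], entropy) -> dict:
    cohort = simulate_cohort(params, entropy)
    diag = first_stage_diagnostics(cohort.x, cohort.g)
    out = {"r2": diag.r2, "f": diag.f_stat, "plans": []}
    for plan in plans:
        try:
            out["plans"].append(_apply_plan(cohort, plan, params.outcome_type))
        except ValueError as exc:
            out["plans"].append({"error": str(exc)})
    return out


def _summarize_records(plan: AnalysisPlan, records: list[dict], m: int, mean_r2, mean_f) -> ReplicationSummary:
    failures = [r for r in records if "error" in r]
    ok = [r for r in records if "error" not in r]
    if len(failures) > 0.01 * m:
        raise RuntimeError(
            f"{len(failures)}/{m} replicates failed for mode {plan.mode!r}; "
            f"first error: {failures[0]['error']}"
        )
    for r in failures:
        logger.warning("replicate failed (%s): %s", plan.mode, r["error"])
    if plan.stratified:
        est = np.array([r["stratum_estimates"] for r in ok])
        return ReplicationSummary(
            mode=plan.mode,
            m=m,
            m_used=len(ok),
            median_estimate=np.median(est, axis=0),
            rejection_rate=None,
            het_rejection_rate=float(np.mean([r["het_reject"] for r in ok])),
            trend_rejection_rate=float(np.mean([r["trend_reject"] for r in ok])),
            mean_r2=mean_r2,
            mean_f=mean_f,
            k=plan.k,
            n_failed=len(failures),
        )
    return ReplicationSummary(
        mode=plan.mode,
        m=m,
        m_used=len(ok),
        median_estimate=float(np.median([r["estimate"] for r in ok])),
        rejection_rate=float(np.mean([r["reject"] for r in ok])),
        het_rejection_rate=None,
        trend_rejection_rate=None,
        mean_r2=mean_r2,
        mean_f=mean_f,
        n_failed=len(failures),
    )


def run_replications_multi(
    params: SimulationParams,
    plans: Sequence[AnalysisPlan],
    m: int = DEFAULT_M,
    base_seed: int = 0,
    cell_key: int | None = None,
    n_jobs: int = 1,
) -> list[ReplicationSummary]:
    """Run m replicates once and apply every plan to the same cohorts.

    Replicate r draws from the seed stream (base_seed[, cell_key], r), so
    results are deterministic, independent of worker count, and matched
    across plans (every plan sees identical cohorts, as when a table
    reports several analyses of the same simulated datasets).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    entropy_head = [int(base_seed)] if cell_key is None else [int(base_seed), int(cell_key)]
    entropies = [tuple(entropy_head + [r]) for r in range(m)]
    if n_jobs == 1:
        results = [_one_replicate(params, plans, e) for e in entropies]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(params, plans, e) for e in entropies
        )
    mean_r2 = float(np.mean([r["r2"] for r in results]))
    mean_f = float(np.mean([r["f"] for r in results]))
    return [
        _summarize_records(plan, [r["plans"][i] for r in results], m, mean_r2, mean_f)
        for i, plan in enumerate(plans)
    ]


def run_replications(
    params: SimulationParams,
    plan: AnalysisPlan,
    m: int = DEFAULT_M,
    base_seed: int = 0,
    cell_key: int | None = None,
    n_jobs: int = 1,
) -> ReplicationSummary:
    """Monte-Carlo summary of one analysis plan over m simulated cohorts."""
    return run_replications_multi(
        params, [plan], m=m, base_seed=base_seed, cell_key=cell_key, n_jobs=n_jobs
    )[0]


_GRID_AXES = ("alpha1", "confounding", "mu1", "mu2", "mu3", "n")


def run_grid(
    scenario_id: str,
    grid: Mapping[str, Sequence] | None = None,
    plans: Sequence[AnalysisPlan] | Sequence[str] | None = None,
    m: int = DEFAULT_M,
    base_seed: int = 0,
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Cartesian parameter grid of Monte-Carlo summaries, tidy long format.

    Axes: alpha1, confounding (positive/negative/mixed), mu1, mu2, mu3
    (B family only) and n.  Each cell's seed stream is a deterministic
    function of the base seed and the cell's own parameter values, so any
    sub-grid reproduces the matching cells of a larger run exactly.
    """
    grid = dict(grid or {})
    unknown = set(grid) - set(_GRID_AXES)
    if unknown:
        raise ValueError(f"unknown grid axes: {sorted(unknown)}")
    if "mu3" in grid and not scenario_id.startswith("B"):
        raise ValueError("mu3 axis is only valid for the B scenario family")
    if plans is None:
        plans = [AnalysisPlan("unadjusted")]
    plans = [AnalysisPlan(p) if isinstance(p, str) else p for p in plans]

    axes = {name: list(grid.get(name, [None])) for name in _GRID_AXES}
    rows = []
    cells = list(itertools.product(*(axes[a] for a in _GRID_AXES)))
    for idx, combo in enumerate(cells):
        cell = dict(zip(_GRID_AXES, combo))
        overrides = {k: v for k, v in cell.items() if v is not None}
        params = build_scenario(scenario_id, overrides)
        key = _stable_key(
            scenario_id,
            *(cell[a] if cell[a] is not None else "-" for a in _GRID_AXES),
        )
        if progress:
            logger.info("grid cell %d/%d: %s", idx + 1, len(cells), overrides)
        summaries = run_replications_multi(
            params, plans, m=m, base_seed=base_seed, cell_key=key, n_jobs=n_jobs
        )
        for plan, summary in zip(plans, summaries):
            row = {"scenario": scenario_id}
            for a in _GRID_AXES:
                row[a] = cell[a] if cell[a] is not None else getattr(params, a, None)
            row.update(
                mode=plan.mode,
                m=summary.m,
                m_used=summary.m_used,
                mean_r2=summary.mean_r2,
                mean_f=summary.mean_f,
                rejection_rate=summary.rejection_rate,
                het_rejection_rate=summary.het_rejection_rate,
                trend_rejection_rate=summary.trend_rejection_rate,
            )
            if summary.rejection_rate is not None:
                row["median_estimate"] = summary.median_estimate
            if plan.stratified:
                for j, v in enumerate(np.atleast_1d(summary.median_estimate), start=1):
                    row[f"median_q{j}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_to_table(rows: pd.DataFrame, layout: str = "tidy") -> pd.DataFrame:
    """Render grid rows in one of three layouts.

    ``tidy`` is the identity (full precision, round-trippable).  ``table1``
    arranges, per (mu1, mu2), the median estimate and rejection percentage
    of the unadjusted vs collider-adjusted analyses under each confounding
    setting.  ``table2_3`` arranges per-(mu1, mu2) heterogeneity-rejection
    percentages and the four stratum medians for direct-collider vs
    residual-collider stratification.  Display rounding: estimates to 2
    decimals, rates to whole percents; missing cells appear as "NA".
    """
    if layout == "tidy":
        return rows.copy()
    if layout not in ("table1", "table2_3"):
        raise ValueError("layout must be one of 'tidy', 'table1', 'table2_3'")
    index_cols = ["mu1", "mu2"]
    if rows.empty:
        return pd.DataFrame(columns=index_cols)

    out = {}
    if layout == "table1":
        for (conf, mode), grp in rows.groupby(["confounding", "mode"], sort=True):
            grp = grp.set_index(index_cols)
            out[f"{conf}/{mode}/median"] = grp["median_estimate"].round(2)
            out[f"{conf}/{mode}/reject_pct"] = (100 * grp["rejection_rate"]).round(0)
    else:
        k_cols = sorted(c for c in rows.columns if c.startswith("median_q"))
        for mode, grp in rows.groupby("mode", sort=True):
            grp = grp.set_index(index_cols)
            out[f"{mode}/het_pct"] = (100 * grp["het_rejection_rate"]).round(0)
            for c in k_cols:
                out[f"{mode}/{c}"] = grp[c].round(2)
    table = pd.DataFrame(out).sort_index()
    return table.fillna("NA").reset_index()


# ---------------------------------------------------------------------------
# data interchange, risk scores, applied-style fixtures
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Validated per-individual analysis table with a role -> column map."""

    frame: pd.DataFrame
    column_map: dict
    outcome_type: str
    source: str
    n_total: int
    n_complete: int

    def column(self, role: str) -> np.ndarray:
        return self.frame[self.column_map[role]].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.column_map.get("covariates", []))

    def covariates(self) -> dict[str, np.ndarray] | None:
        names = self.covariate_names
        if not names:
            return None
        return {n: self.frame[n].to_numpy(dtype=float) for n in names}


_TRUTHY = {"yes": 1.0, "y": 1.0, "true": 1.0, "1": 1.0}
_FALSY = {"no": 0.0, "n": 0.0, "false": 0.0, "0": 0.0}


def read_cohort_table(
    path,
    column_map: Mapping,
    outcome_type: str = "continuous",
    delimiter: str | None = None,
    na_values: Iterable[str] | None = None,
) -> CohortTable:
    """Read a CSV/TSV cohort file and validate the mapped columns.

    ``column_map`` maps roles (instrument, exposure, outcome, stratifier,
    covariates) to column names.  The delimiter is sniffed unless given.
    Non-numeric cells become missing values and are counted; complete-case
    filtering itself is deferred to the analysis step.
    """
    if outcome_type not in _OUTCOME_TYPES:
        raise ValueError(f"outcome_type must be one of {_OUTCOME_TYPES}")
    read_kw = dict(na_values=list(na_values) if na_values else None)
    if delimiter is None:
        frame = pd.read_csv(path, sep=None, engine="python", **read_kw)
    else:
        frame = pd.read_csv(path, sep=delimiter, **read_kw)

    column_map = dict(column_map)
    needed = [column_map[r] for r in ("instrument", "exposure", "outcome", "stratifier") if r in column_map]
    needed += list(column_map.get("covariates", []))
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"mapped column(s) not found in {path}: {missing}")

    out_col = column_map.get("outcome")
    if outcome_type == "binary" and out_col is not None:
        raw = frame[out_col]
        if raw.dtype == object:
            frame[out_col] = raw.astype(str).str.strip().str.lower().map({**_TRUTHY, **_FALSY})
        vals = pd.to_numeric(frame[out_col], errors="coerce").dropna().unique()
        bad = sorted(v for v in vals if v not in (0.0, 1.0))
        if bad:
            raise ValueError(f"binary outcome column {out_col!r} has values outside {{0,1}}: {bad}")

    for col in needed:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        n_bad = int(coerced.isna().sum() - frame[col].isna().sum())
        if n_bad:
            logger.warning("column %r: %d non-numeric cell(s) treated as missing", col, n_bad)
        frame[col] = coerced

    n_total = len(frame)
    n_complete = int(frame[needed].notna().all(axis=1).sum())
    if n_complete < n_total:
        logger.warning("%d of %d rows have missing mapped values", n_total - n_complete, n_total)
    return CohortTable(
        frame=frame,
        column_map=column_map,
        outcome_type=outcome_type,
        source=str(path),
        n_total=n_total,
        n_complete=n_complete,
    )


def compute_grs(dosages: pd.DataFrame, weights, strict: bool = True) -> pd.Series:
    """Weighted genetic risk score: per-individual sum of weight * dosage.

    ``dosages`` is individuals x variants (variant IDs as columns, values in
    [0, 2] allele counts); ``weights`` maps variant ID to per-allele weight
    (a Series, or a two-column DataFrame).  Weights are assumed to be
    pre-harmonized to the dosage effect allele — no strand or allele
    flipping is attempted here.  In strict mode every weighted variant must
    be present; in lenient mode the intersection is used and mismatches
    logged.
    """
    if isinstance(weights, pd.DataFrame):
        if weights.shape[1] != 2:
            raise ValueError("weights DataFrame must have exactly two columns (variant, weight)")
        weights = weights.set_index(weights.columns[0])[weights.columns[1]]
    weights = pd.Series(weights).astype(float)

    present = weights.index.intersection(dosages.columns)
    absent = weights.index.difference(dosages.columns)
    if len(present) == 0:
        raise ValueError("no weighted variant is present in the dosage table")
    if len(absent) and strict:
        raise ValueError(f"{len(absent)} weighted variant(s) missing from dosages: {list(absent[:5])}")
    if len(absent):
        logger.warning("lenient GRS: %d weighted variant(s) missing, %d matched", len(absent), len(present))

    mat = dosages[present].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    if np.nanmin(mat) < 0 or np.nanmax(mat) > 2:
        raise ValueError("dosages outside the valid [0, 2] range")
    score = mat @ weights.loc[present].to_numpy()
    logger.info("GRS built from %d variant(s); %d unmatched", len(present), len(absent))
    return pd.Series(score, index=dosages.index, name="grs")


def _calibrate_intercept(linear_predictor: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean(expit(b0 + lp)) equals the target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expit(mid + linear_predictor).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_applied_fixture(
    path,
    n: int = 50_000,
    seed: int = 0,
    outcome_prevalence: float = 0.002,
    exposure_prevalence: float = 0.10,
    outcome_log_or: float = 0.5,
    trend_per_unit: float = 0.0,
    instrument_effect: float = 0.3,
    confounding_strength: float = 0.4,
) -> CohortTable:
    """Write a synthetic cohort shaped like a biobank smoking/cancer analysis.

    Purely synthetic stand-in data: a continuous genetic score instrument, a
    binary exposure (smoker yes/no) driven by the score and a latent
    confounder, a continuous stratifier (bodyweight, kg) lowered by the
    exposure — hence a collider — and a rare binary outcome whose baseline
    prevalence is calibrated exactly.  ``trend_per_unit`` adds effect
    modification of the exposure log-odds by the stratifier (per kg around
    its mean), so trend-detection properties can be tested against known
    truth.  Generating parameters are documented in a ``<path>.meta.json``
    sidecar.
    """
    if not 0 < outcome_prevalence < 1 or not 0 < exposure_prevalence < 1:
        raise ValueError("prevalences must lie strictly between 0 and 1")
    rng = np.random.default_rng(_seed_sequence(seed))
    g = rng.standard_normal(n)
    u = rng.standard_normal(n)
    age = rng.normal(57.0, 8.0, n)
    sex = (rng.random(n) < 0.46).astype(float)

    lp_x = instrument_effect * g + confounding_strength * u
    b0_x = _calibrate_intercept(lp_x, exposure_prevalence)
    x = (rng.random(n) < expit(b0_x + lp_x)).astype(float)

    weight = 78.0 - 2.5 * x + 3.0 * u - 0.05 * (age - 57.0) - 5.0 * sex + rng.normal(0, 12.0, n)

    log_or_i = outcome_log_or + trend_per_unit * (weight - weight.mean())
    lp_y = log_or_i * x + 0.5 * u + 0.02 * (age - 57.0)
    b0_y = _calibrate_intercept(lp_y, outcome_prevalence)
    y = (rng.random(n) < expit(b0_y + lp_y)).astype(float)

    frame = pd.DataFrame({"grs": g, "smoker": x, "cancer": y, "weight_kg": weight, "age": age, "sex": sex})
    frame.to_csv(path, index=False)
    meta = {
        "synthetic": True,
        "n": int(n),
        "seed": int(seed),
        "outcome_prevalence_target": outcome_prevalence,
        "outcome_prevalence_realized": float(y.mean()),
        "exposure_prevalence_target": exposure_prevalence,
        "exposure_prevalence_realized": float(x.mean()),
        "outcome_log_or": outcome_log_or,
        "trend_per_unit": trend_per_unit,
        "instrument_effect": instrument_effect,
        "confounding_strength": confounding_strength,
        "exposure_intercept": float(b0_x),
        "outcome_intercept": float(b0_y),
    }
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return read_cohort_table(
        path,
        column_map={
            "instrument": "grs",
            "exposure": "smoker",
            "outcome": "cancer",
            "stratifier": "weight_kg",
            "covariates": ["age", "sex"],
        },
        outcome_type="binary",
    )


def analyze_cohort(
    table: CohortTable,
    k: int = 4,
    stratify_on: str = "residual_collider",
    exposure_type: str | None = None,
    exposure_assoc_scope: str = "full_sample",
    center_summary: str = "median",
    adjust_covariates: bool = True,
    or_scale: bool = False,
) -> tuple[pd.DataFrame, StratifiedMRResult]:
    """Stratified MR analysis of a cohort table.

    Returns a tidy per-stratum DataFrame (bounds, n, center, estimate, se,
    CI, plus the homogeneity and trend test results repeated on every row)
    and the underlying :class:`StratifiedMRResult`.  With ``or_scale`` the
    estimate and CI columns are exponentiated (odds-ratio scale) for binary
    outcomes; log-scale columns are kept alongside.
    """
    if exposure_type is None:
        vals = pd.unique(table.column("exposure"))
        vals = vals[np.isfinite(vals)]
        exposure_type = "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"
    covs = table.covariates() if adjust_covariates else None
    res = stratified_mr(
        table.column("instrument"),
        table.column("exposure"),
        table.column("outcome"),
        table.column("stratifier"),
        k=k,
        stratify_on=stratify_on,
        outcome_type=table.outcome_type,
        exposure_type=exposure_type,
        exposure_assoc_scope=exposure_assoc_scope,
        covariates=covs,
        center_summary=center_summary,
    )
    frame = res.to_frame()
    if or_scale:
        if table.outcome_type != "binary":
            raise ValueError("--or-scale requires a binary outcome")
        frame = frame.rename(
            columns={"estimate": "log_or", "ci_low": "log_ci_low", "ci_high": "log_ci_high"}
        )
        frame["or"] = np.exp(frame["log_or"])
        frame["or_ci_low"] = np.exp(frame["log_ci_low"])
        frame["or_ci_high"] = np.exp(frame["log_ci_high"])
    frame["q_stat"] = res.q_stat
    frame["q_df"] = res.q_df
    frame["p_het"] = res.q_pvalue
    frame["trend_slope"] = res.trend_slope
    frame["trend_se"] = res.trend_se
    frame["p_trend"] = res.trend_pvalue
    return frame, res
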