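"""Estimators and tests: regressions, ratio IV, residual collider, strata,
Cochran's Q, trend meta-regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.sandbox.regression.gmm import IV2SLS

import stratamr as smr

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestLinearAssoc:
    def test_matches_closed_form_normal_equations(self):
        g = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        oracle = ((g - g.mean()) * (y - y.mean())).sum() / ((g - g.mean()) ** 2).sum()
        res = smr.linear_assoc(y, g)
        assert res.beta == pytest.approx(oracle, rel=1e-12)
        assert res.n_used == 5 and res.model == "linear"

    def test_exact_linear_relation_has_zero_se(self):
        g = np.linspace(0, 1, 20)
        res = smr.linear_assoc(2 * g, g)
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-10)

    def test_null_slope_for_independent_data(self, rng):
        res = smr.linear_assoc(rng.standard_normal(100_000), rng.standard_normal(100_000))
        assert abs(res.beta) < 0.02

    def test_covariate_adjustment_changes_coefficient(self, a2_cohort):
        plain = smr.linear_assoc(a2_cohort.y, a2_cohort.g)
        adj = smr.linear_assoc(a2_cohort.y, a2_cohort.g, {"c": a2_cohort.c})
        assert adj.adjusted_for == ("c",)
        assert adj.beta != plain.beta

    def test_missing_rows_dropped(self):
        g = np.arange(10.0)
        y = 2 * g
        y[3] = np.nan
        assert smr.linear_assoc(y, g).n_used == 9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            smr.linear_assoc(np.arange(5.0), np.ones(5))
        g = np.arange(10.0)
        with pytest.raises(ValueError, match="collinearity"):
            smr.linear_assoc(2 * g, g, {"dup": g})


class TestLogisticAssoc:
    def test_recovers_generating_log_odds(self, rng):
        g = rng.standard_normal(100_000)
        y = (rng.random(100_000) < stats.logistic.cdf(0.5 + 0.3 * g)).astype(float)
        res = smr.logistic_assoc(y, g)
        assert res.beta == pytest.approx(0.3, abs=0.03)
        assert res.model == "logistic"

    def test_null_when_instrument_permuted(self, rng):
        g = rng.standard_normal(100_000)
        y = (rng.random(100_000) < 0.3).astype(float)
        assert abs(smr.logistic_assoc(y, rng.permutation(g)).beta) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            smr.logistic_assoc(np.ones(50), np.arange(50.0))

    def test_noninteger_coding_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            smr.logistic_assoc(np.array([0.0, 1, 2] * 10), np.arange(30.0))


class TestRatioEstimate:
    def test_arithmetic_and_ci(self):
        num = smr.AssocResult(beta=0.05, se=0.01, n_used=100, model="linear")
        den = smr.AssocResult(beta=0.1, se=0.005, n_used=100, model="linear")
        r = smr.ratio_estimate(num, den)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        assert (r.ci_low, r.ci_high) == (pytest.approx(0.304), pytest.approx(0.696))

    def test_zero_numerator_gives_zero_estimate(self):
        num = smr.AssocResult(beta=0.0, se=0.01, n_used=100, model="linear")
        den = smr.AssocResult(beta=0.1, se=0.005, n_used=100, model="linear")
        assert smr.ratio_estimate(num, den).estimate == 0.0

    def test_weak_denominator_fails_instead_of_diverging(self):
        num = smr.AssocResult(beta=0.05, se=0.01, n_used=100, model="linear")
        den = smr.AssocResult(beta=1e-12, se=0.005, n_used=100, model="linear")
        with pytest.raises(ValueError, match="weak"):
            smr.ratio_estimate(num, den)

    def test_equals_two_stage_least_squares(self, a2_cohort):
        """The single-IV ratio estimate coincides with 2SLS; the oracle is
        statsmodels' IV2SLS, an entirely independent code path."""
        coh = a2_cohort
        r = smr.ratio_estimate(smr.linear_assoc(coh.y, coh.g), smr.linear_assoc(coh.x, coh.g))
        z = np.column_stack([np.ones(coh.n), coh.g])
        xmat = np.column_stack([np.ones(coh.n), coh.x])
        oracle = IV2SLS(coh.y, xmat, instrument=z).fit().params[1]
        assert r.estimate == pytest.approx(oracle, rel=1e-10)

    def test_second_order_se_exceeds_first_order(self):
        num = smr.AssocResult(beta=0.05, se=0.01, n_used=100, model="linear")
        den = smr.AssocResult(beta=0.1, se=0.02, n_used=100, model="linear")
        assert smr.ratio_estimate(num, den, second_order=True).se > smr.ratio_estimate(num, den).se


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        v = np.array([1.0, 2, 3, 4])
        np.testing.assert_allclose(smr.residualize(v, v), 0.0, atol=1e-12)

    def test_uncorrelated_input_is_just_centered(self, rng):
        g = np.array([-1.0, 1, -1, 1])
        c = np.array([2.0, 2, 4, 4])
        np.testing.assert_allclose(smr.residualize(c, g), c - 3.0, atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_residuals_orthogonal_to_instrument_and_centered(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(200)
        c = 0.7 * g + rng.standard_normal(200)
        c0 = smr.residualize(c, g)
        assert abs(np.corrcoef(c0, g)[0, 1]) < 1e-10
        assert abs(c0.mean()) < 1e-12

    def test_constant_instrument_rejected(self):
        with pytest.raises(ValueError):
            smr.residualize(np.arange(5.0), np.zeros(5))


class TestAssignStrata:
    def test_exact_quartiles_of_eight_points(self):
        labels = smr.assign_strata(np.arange(1.0, 9.0), 4)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_ties_go_to_lower_stratum(self):
        labels = smr.assign_strata(np.array([1.0, 2, 2, 3]), 2)
        np.testing.assert_array_equal(labels, [1, 1, 1, 2])

    def test_normal_cut_points_match_quantile_oracle(self, rng):
        values = rng.standard_normal(10_000)
        labels = smr.assign_strata(values, 4)
        for j, q in enumerate(stats.norm.ppf([0.25, 0.5, 0.75]), start=1):
            boundary = values[labels == j].max()
            assert boundary == pytest.approx(q, abs=0.05)

    def test_labels_ascend_with_value(self, rng):
        values = rng.standard_normal(500)
        labels = smr.assign_strata(values, 5)
        order = np.argsort(values)
        assert (np.diff(labels[order]) >= 0).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            smr.assign_strata(np.ones(100), 4)
        with pytest.raises(ValueError, match="empty"):
            smr.assign_strata(np.array([1.0] * 97 + [2, 3, 4]), 4)
        with pytest.raises(ValueError):
            smr.assign_strata(np.arange(10.0), 1)


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        q, df, p = smr.cochran_q([0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.1, 0.3])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 3 and p == pytest.approx(1.0)

    def test_two_estimate_arithmetic(self):
        q, df, p = smr.cochran_q([0.0, 1.0], [1.0, 1.0])
        assert q == pytest.approx(0.5)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.5, 1), rel=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_direct_formula_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=4)
        se = rng.uniform(0.1, 2.0, size=4)
        w = 1 / se**2
        pooled = (w * theta).sum() / w.sum()
        oracle = (w * (theta - pooled) ** 2).sum()
        q, _, _ = smr.cochran_q(theta, se)
        assert q == pytest.approx(oracle, rel=1e-12)
        perm = rng.permutation(4)
        assert smr.cochran_q(theta[perm], se[perm])[0] == pytest.approx(q, rel=1e-10)
        assert smr.cochran_q(theta + 3.7, se)[0] == pytest.approx(q, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            smr.cochran_q([0.5], [0.1])
        with pytest.raises(ValueError):
            smr.cochran_q([0.5, np.inf], [0.1, 0.1])
        with pytest.raises(ValueError):
            smr.cochran_q([0.5, 0.6], [0.1, 0.0])


class TestTrendMetaRegression:
    def test_flat_estimates_give_zero_slope(self):
        slope, _, p = smr.trend_meta_regression([0.4, 0.4, 0.4], [0.1, 0.1, 0.1], [1.0, 2, 3])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_exact_linear_trend_recovered(self):
        centers = np.array([10.0, 20, 30, 40])
        slope, _, _ = smr.trend_meta_regression(0.1 + 0.03 * centers, [0.2] * 4, centers)
        assert slope == pytest.approx(0.03, rel=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_weighted_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.uniform(-2, 2, 4))
        if np.diff(centers).min() < 1e-3:
            centers = np.arange(4.0)
        theta = rng.normal(size=4)
        se = rng.uniform(0.2, 1.5, size=4)
        design = np.column_stack([np.ones(4), centers])
        w = np.diag(1 / se**2)
        coef = np.linalg.solve(design.T @ w @ design, design.T @ w @ theta)
        cov = np.linalg.inv(design.T @ w @ design)
        slope, slope_se, _ = smr.trend_meta_regression(theta, se, centers)
        assert slope == pytest.approx(coef[1], rel=1e-10)
        assert slope_se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            smr.trend_meta_regression([0.1, 0.2], [0.1, 0.1], [1.0, 2.0])
        with pytest.raises(ValueError, match="monotone"):
            smr.trend_meta_regression([0.1, 0.2, 0.3], [0.1] * 3, [1.0, 1.0, 2.0])


class TestFirstStageDiagnostics:
    def test_null_f_statistic_near_one(self):
        fs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fs.append(smr.first_stage_diagnostics(rng.standard_normal(2000), rng.standard_normal(2000)).f_stat)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.3)

    def test_perfect_fit_rejected(self):
        g = np.arange(10.0)
        with pytest.raises(ValueError):
            smr.first_stage_diagnostics(2 * g, g)


class TestStratifiedMR:
    def test_outcome_equal_exposure_gives_unit_estimates(self, a2_cohort):
        """When Y is X itself, numerator and denominator regressions coincide
        within each stratum, so every per-stratum-denominator estimate is 1."""
        coh = a2_cohort
        for method in ("collider", "residual_collider"):
            res = smr.stratified_mr(
                coh.g, coh.x, coh.x, coh.c, stratify_on=method,
                exposure_assoc_scope="per_stratum",
            )
            np.testing.assert_allclose(res.estimates, 1.0, atol=1e-10)

    def test_partition_and_center_invariants(self, a2_cohort):
        coh = a2_cohort
        res = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c, k=4)
        assert sum(s.n for s in res.strata) == coh.n
        centers = [s.center for s in res.strata]
        assert centers == sorted(centers)
        assert res.q_df == 3
        assert 0 <= res.q_pvalue <= 1 and 0 <= res.trend_pvalue <= 1

    def test_location_shift_of_stratifier_preserves_memberships(self, a2_cohort):
        coh = a2_cohort
        a = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c, stratify_on="collider")
        b = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c + 100.0, stratify_on="collider")
        assert [s.n for s in a.strata] == [s.n for s in b.strata]
        np.testing.assert_allclose(a.estimates, b.estimates, rtol=1e-10)

    def test_outcome_scaling_scales_estimates(self, a2_cohort):
        coh = a2_cohort
        a = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c)
        b = smr.stratified_mr(coh.g, coh.x, 3.0 * coh.y, coh.c)
        np.testing.assert_allclose(b.estimates, 3.0 * a.estimates, rtol=1e-10)

    def test_residual_stratification_differs_from_direct(self, a2_cohort):
        coh = a2_cohort
        direct = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c, stratify_on="collider")
        resid = smr.stratified_mr(coh.g, coh.x, coh.y, coh.c, stratify_on="residual_collider")
        assert not np.allclose(direct.estimates, resid.estimates)

    def test_stratum_errors_annotated_with_index(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(400)
        x = 0.5 * g + rng.standard_normal(400)
        y = np.zeros(400)  # single-class binary outcome in every stratum
        c = rng.standard_normal(400)
        with pytest.raises(ValueError, match="stratum 1"):
            smr.stratified_mr(g, x, y, c, outcome_type="binary")
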