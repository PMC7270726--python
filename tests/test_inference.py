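"""Tests of Wald / score contrast tests, restricted fits, and intervals."""

import numpy as np
import pytest
from scipy import stats

import mmgee as mg


class TestDefaultDf:
    def test_all_models_three_params(self):
        assert mg.default_df(18, [3, 3, 3]) == 15

    def test_two_param_models_only(self):
        assert mg.default_df(18, [2]) == 16

    def test_forty_subjects(self):
        assert mg.default_df(40, [3, 3, 3]) == 37

    def test_insufficient_subjects(self):
        with pytest.raises(ValueError):
            mg.default_df(3, [5])


class TestContrastHypothesis:
    def test_inconsistent_rhs_rejected(self):
        L = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="inconsistent"):
            mg.ContrastHypothesis(L=L, r=[0.0, 1.0])

    def test_row_blocks(self, fixture_mmm, group_hyp):
        blocks = group_hyp.row_blocks(fixture_mmm.model_slices)
        assert blocks == [{0}, {1}, {2}]
        assert group_hyp.is_block_diagonal(fixture_mmm.model_slices)


class TestMaxWald:
    def test_single_row_equals_z_test(self, fixture_mmm, group_hyp):
        hyp1 = group_hyp.subset([0])
        res = mg.max_wald_test(fixture_mmm, hyp1, reference="mvn", bias_adjust=False)
        se = np.sqrt(fixture_mmm.sigma[1, 1])
        z = fixture_mmm.beta_stacked[1] / se
        assert res.statistic == pytest.approx(abs(z), rel=1e-10)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=2e-4)

    def test_duplicated_row_changes_nothing(self, fixture_mmm, group_hyp):
        L_dup = np.vstack([group_hyp.L, group_hyp.L[0]])
        hyp_dup = mg.ContrastHypothesis(L=L_dup)
        a = mg.max_wald_test(fixture_mmm, group_hyp, reference="mvn")
        b = mg.max_wald_test(fixture_mmm, hyp_dup, reference="mvn")
        assert b.statistic == pytest.approx(a.statistic, rel=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-6)

    def test_p_monotone_in_effect(self, fixture_mmm, group_hyp):
        shifted = mg.ContrastHypothesis(L=group_hyp.L, r=group_hyp.r + 0.5)
        a = mg.max_wald_test(fixture_mmm, group_hyp, reference="mvn")
        base_t = np.abs(a.per_row["statistic"]).max()
        b = mg.max_wald_test(fixture_mmm, shifted, reference="mvn")
        if np.abs(b.per_row["statistic"]).max() > base_t:
            assert b.p_value < a.p_value

    def test_one_sided_less_than_two_sided(self, fixture_mmm, group_hyp):
        two = mg.max_wald_test(fixture_mmm, group_hyp, reference="mvn")
        # the largest |t| here is positive, so 'greater' halves the p-value
        one = mg.max_wald_test(
            fixture_mmm, group_hyp, reference="mvn", alternative="greater"
        )
        assert one.p_value < two.p_value

    def test_null_calibration_normal_reference(self):
        """Monte-Carlo calibration: at K=400 the asymptotic test holds
        its level (99% binomial envelope around 0.05 at 500 reps)."""
        cfg = mg.ScenarioConfig(M=3, K=400, effects="null", seed=17)
        tab = mg.run_scenario(
            cfg,
            reps=500,
            procedures=[{"kind": "max-wald", "reference": "mvn", "bias_adjust": False}],
        )
        rate = tab["rate"].iloc[0]
        envelope = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) < envelope


class TestSimultaneousCI:
    def test_single_row_is_classical_interval(self, fixture_mmm, group_hyp):
        hyp1 = group_hyp.subset([1])
        ci = mg.simultaneous_ci(
            fixture_mmm, hyp1, reference="mvt", bias_adjust=False
        )
        sl = fixture_mmm.model_slices[1]
        est = fixture_mmm.beta_stacked[sl][1]
        se = np.sqrt(np.diag(fixture_mmm.sigma)[sl][1])
        tq = stats.t.ppf(0.975, 37)
        assert ci.table["lower"].iloc[0] == pytest.approx(est - tq * se, abs=1e-3)
        assert ci.table["upper"].iloc[0] == pytest.approx(est + tq * se, abs=1e-3)

    @pytest.mark.parametrize("bias_adjust", [False, True])
    def test_duality_with_single_step_test(self, fixture_mmm, group_hyp, bias_adjust):
        alpha = 0.2  # a level where some rows reject on this fixture
        res = mg.max_wald_test(
            fixture_mmm, group_hyp, alpha=alpha, reference="mvt", bias_adjust=bias_adjust
        )
        ci = mg.simultaneous_ci(
            fixture_mmm, group_hyp, level=1 - alpha, reference="mvt",
            bias_adjust=bias_adjust,
        )
        reject_rows = np.abs(res.per_row["statistic"].to_numpy()) > res.critical_value
        outside = ~ci.contains(group_hyp.r)
        assert np.array_equal(reject_rows, outside)


class TestQuadraticWald:
    def test_single_row_is_squared_z(self, fixture_mmm, group_hyp):
        hyp1 = group_hyp.subset([2])
        w = mg.quadratic_wald_test(fixture_mmm, hyp1, reference="chisq")
        z = mg.max_wald_test(fixture_mmm, hyp1, reference="mvn")
        assert w.statistic == pytest.approx(z.statistic**2, rel=1e-10)

    def test_rank_deficient_equals_full_rank_version(self, fixture_mmm, group_hyp):
        # third row = difference of the first two: same statistic, c = 2
        L2 = group_hyp.L[:2]
        L3 = np.vstack([L2, L2[0] - L2[1]])
        full = mg.quadratic_wald_test(
            fixture_mmm, mg.ContrastHypothesis(L=L2), reference="chisq"
        )
        degen = mg.quadratic_wald_test(
            fixture_mmm, mg.ContrastHypothesis(L=L3), reference="chisq"
        )
        assert degen.df == 2
        assert degen.statistic == pytest.approx(full.statistic, rel=1e-8)
        assert degen.p_value == pytest.approx(full.p_value, rel=1e-8)

    def test_row_scaling_invariance(self, fixture_mmm, group_hyp):
        D = np.diag([2.0, -0.5, 7.0])
        scaled = mg.ContrastHypothesis(L=D @ group_hyp.L, r=D @ group_hyp.r)
        a = mg.quadratic_wald_test(fixture_mmm, group_hyp, reference="chisq")
        b = mg.quadratic_wald_test(fixture_mmm, scaled, reference="chisq")
        assert b.statistic == pytest.approx(a.statistic, rel=1e-10)

    def test_references_order_p_values(self, fixture_mmm, group_hyp):
        # finite-df references are more conservative than chi-squared
        chi = mg.quadratic_wald_test(fixture_mmm, group_hyp, reference="chisq")
        f = mg.quadratic_wald_test(fixture_mmm, group_hyp, reference="f")
        sf = mg.quadratic_wald_test(fixture_mmm, group_hyp, reference="scaledf")
        assert chi.p_value < f.p_value < sf.p_value

    def test_scaledf_needs_enough_df(self, fixture_mmm, group_hyp):
        with pytest.raises(ValueError, match="df - c \\+ 1"):
            mg.quadratic_wald_test(
                fixture_mmm, group_hyp, reference="scaledf", df=2
            )


class TestRestrictedFit:
    def test_linear_case_matches_closed_form(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.6, -0.3]) + rng.normal(size=n)
        spec = mg.GEEModelSpec(
            response=y,
            design=X,
            cluster_id=np.arange(n),
            family="gaussian",
            working_correlation="independence",
        )
        Lm = np.array([[0.0, 1.0, -1.0]])
        rm = np.array([0.2])
        rf = mg.restricted_fit(spec, Lm, rm)
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        XtX_inv = np.linalg.inv(X.T @ X)
        correction = (
            XtX_inv @ Lm.T
            @ np.linalg.solve(Lm @ XtX_inv @ Lm.T, Lm @ bhat - rm)
        )
        assert np.allclose(rf.beta_tilde, bhat - correction.ravel(), atol=1e-8)
        assert np.abs(Lm @ rf.beta_tilde - rm).max() < 1e-8

    def test_already_satisfied_constraint_keeps_betahat(self, fixture_fits):
        fit = fixture_fits[0]
        Lm = np.array([[0.0, 1.0, 0.0]])
        rm = Lm @ fit.beta_hat
        rf = mg.restricted_fit(fit.spec, Lm, rm, init=fit.beta_hat)
        assert np.allclose(rf.beta_tilde, fit.beta_hat, atol=1e-6)
        assert np.abs(rf.lagrange).max() < 1e-4

    def test_constraint_satisfied_on_fixture(self, fixture_fits):
        for fit in fixture_fits:
            Lm = np.array([[0.0, 1.0, 0.0]])
            rf = mg.restricted_fit(fit.spec, Lm, np.zeros(1))
            assert abs(rf.beta_tilde[1]) < 1e-8

    def test_infeasible_restriction_signals(self, fixture_fits):
        Lm = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="infeasible"):
            mg.restricted_fit(fixture_fits[0].spec, Lm, np.array([0.0, 1.0]))


class TestScoreTests:
    def test_null_satisfied_exactly_gives_zero_statistic(self, fixture_mmm):
        hyp = mg.ContrastHypothesis(
            L=mg.group_contrast(3).L, r=mg.group_contrast(3).L @ fixture_mmm.beta_stacked
        )
        res = mg.max_score_test(fixture_mmm, hyp)
        assert res.statistic < 1e-4
        assert res.p_value > 0.999

    def test_quadratic_single_row_is_squared_max(self, fixture_mmm, group_hyp):
        hyp1 = group_hyp.subset([0])
        rs = mg.restricted_stack(fixture_mmm, hyp1)
        mx = mg.max_score_test(rs)
        qd = mg.quadratic_score_test(rs)
        assert qd.statistic == pytest.approx(mx.statistic**2, rel=1e-8)

    def test_cross_model_contrast_rejected(self, fixture_mmm):
        L = np.zeros((1, fixture_mmm.n_params_total))
        L[0, 1] = 1.0
        L[0, 4] = -1.0  # group coefficients of two different models
        with pytest.raises(ValueError, match="block-diagonal"):
            mg.restricted_stack(fixture_mmm, mg.ContrastHypothesis(L=L))

    def test_large_sample_agreement_with_wald(self):
        """First-order equivalence: score and Wald maximum statistics
        agree within 5% relative at K=5000."""
        cfg = mg.ScenarioConfig(M=3, K=5000, effects="all", seed=23)
        data = mg.generate_dataset(cfg)
        fits = [mg.fit_gee(s) for s in mg.analysis_specs(data, 3)]
        mmm = mg.stack_models(fits)
        hyp = mg.group_contrast(3)
        wald = mg.max_wald_test(mmm, hyp, reference="mvn", bias_adjust=False)
        score = mg.max_score_test(mmm, hyp)
        assert score.statistic == pytest.approx(wald.statistic, rel=0.05)

    def test_bias_adjusted_score_inflates_se(self, fixture_mmm, group_hyp):
        plain = mg.max_score_test(fixture_mmm, group_hyp, bias_adjust=False)
        adj = mg.max_score_test(fixture_mmm, group_hyp, bias_adjust=True)
        assert adj.statistic <= plain.statistic + 1e-9
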