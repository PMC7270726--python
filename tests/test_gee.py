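"""Unit tests for single-model GEE fitting and nuisance moment estimators."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mmgee as mg
from mmgee.gee import DegenerateDataError


class TestWorkingCorrelation:
    def test_exchangeable_zero_alpha_is_identity(self):
        R = mg.build_working_correlation("exchangeable", 0.0, 3)
        assert np.array_equal(R, np.eye(3))

    def test_ar1_matches_definition(self):
        R = mg.build_working_correlation("ar1", 0.5, 3)
        expected = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        assert np.allclose(R, expected)

    def test_exchangeable_eigenvalues(self):
        # compound symmetry eigenvalues are 1 - a (x3) and 1 + 3a
        R = mg.build_working_correlation("exchangeable", 0.75, 4)
        eig = np.sort(np.linalg.eigvalsh(R))
        assert np.allclose(eig, [0.25, 0.25, 0.25, 3.25])

    def test_fixed_takes_leading_submatrix(self):
        R_full = mg.build_working_correlation("ar1", 0.3, 5)
        R = mg.build_working_correlation("fixed", None, 3, fixed_R=R_full)
        assert np.allclose(R, R_full[:3, :3])

    @pytest.mark.parametrize(
        "kind,alpha,n", [("exchangeable", -0.6, 3), ("ar1", 1.2, 4)]
    )
    def test_invalid_alpha_signals(self, kind, alpha, n):
        with pytest.raises(mg.FitError):
            mg.build_working_correlation(kind, alpha, n)


class TestNuisanceEstimators:
    def test_independence_singletons(self):
        resid = [np.array([v]) for v in (1.0, -1.0, 1.0, -1.0)]
        alpha, phi = mg.estimate_nuisance(resid, p=0, kind="independence")
        assert alpha is None
        assert phi == pytest.approx(1.0)

    def test_exchangeable_identical_residuals_gives_unit_alpha(self):
        resid = [np.array([c, c]) for c in (0.5, -1.0, 2.0, 1.5, -0.3)]
        alpha, phi = mg.estimate_nuisance(resid, p=0, kind="exchangeable")
        assert alpha == pytest.approx(1.0)

    def test_ar1_uses_lag_one_products(self):
        # residuals (1, 1, -1): lag-1 products 1 and -1 sum to 0
        resid = [np.array([1.0, 1.0, -1.0])] * 4
        alpha, phi = mg.estimate_nuisance(resid, p=0, kind="ar1")
        assert alpha == pytest.approx(0.0)
        assert phi == pytest.approx(1.0)

    def test_zero_residuals_degenerate(self):
        resid = [np.zeros(3)] * 4
        with pytest.raises(DegenerateDataError):
            mg.estimate_nuisance(resid, p=0, kind="exchangeable")

    def test_scale_divisor_variants(self):
        resid = [np.array([2.0]), np.array([0.0]), np.array([2.0]), np.array([0.0])]
        _, phi_np = mg.estimate_nuisance(resid, p=2, kind="independence")
        _, phi_n = mg.estimate_nuisance(
            resid, p=2, kind="independence", scale_divisor="n"
        )
        assert phi_np == pytest.approx(8.0 / 2.0)
        assert phi_n == pytest.approx(8.0 / 4.0)


class TestFitGee:
    def test_singleton_gaussian_equals_ols(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(size=n)
        spec = mg.GEEModelSpec(
            response=y,
            design=X,
            cluster_id=np.arange(n),
            family="gaussian",
            working_correlation="independence",
        )
        fit = mg.fit_gee(spec)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta_hat, ols, atol=1e-10)
        assert fit.converged

    @pytest.mark.parametrize("corstr", ["independence", "exchangeable", "ar1"])
    def test_binomial_intercept_only_is_logit_of_weighted_mean(self, rng, corstr):
        """With equal cluster sizes the intercept-only estimating equation
        is solved by the R^-1-weighted mean response (the plain mean for
        independence and exchangeable, position-weighted for ar1)."""
        K, n = 30, 3
        y = rng.binomial(1, 0.3, size=K * n).astype(float)
        spec = mg.GEEModelSpec(
            response=y,
            design=np.ones((K * n, 1)),
            cluster_id=np.repeat(np.arange(K), n),
            family="binomial",
            working_correlation=corstr,
        )
        fit = mg.fit_gee(spec, tol=1e-10)
        if corstr == "ar1":
            R = mg.build_working_correlation("ar1", fit.alpha_hat, n)
            w = np.linalg.solve(R, np.ones(n))
        else:
            w = np.ones(n)
        ybar = (y.reshape(K, n) @ w).sum() / (K * w.sum())
        assert fit.beta_hat[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-7)

    def test_estimating_equation_solved_at_betahat(self, fixture_fits):
        for fit in fixture_fits:
            assert np.abs(fit.score_sum()).max() < 1e-4

    def test_fixture_matches_statsmodels(self, fixture_data, fixture_fits):
        """Cross-implementation oracle: coefficients, exchangeable alpha
        and robust covariance agree with statsmodels GEE to 1e-6."""
        families = [
            sm.families.Gaussian(),
            sm.families.Poisson(),
            sm.families.Binomial(),
        ]
        for m, fam in enumerate(families):
            fit = mg.fit_gee(fixture_fits[m].spec, tol=1e-10, max_iter=60)
            X = np.column_stack(
                [
                    np.ones(len(fixture_data)),
                    fixture_data["group"],
                    fixture_data[f"x{m + 1}"],
                ]
            )
            res = sm.GEE(
                fixture_data[f"y{m + 1}"],
                X,
                groups=fixture_data["id"],
                family=fam,
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit(maxiter=200, ctol=1e-11)
            assert np.allclose(fit.beta_hat, res.params.values, rtol=1e-6)
            assert fit.alpha_hat == pytest.approx(
                res.model.cov_struct.dep_params, rel=1e-6
            )
            sandwich = mg.stack_models([fit]).sigma
            assert np.allclose(sandwich, res.cov_params().values, rtol=1e-5)
        # gaussian scale follows the N - p convention
        gauss = mg.fit_gee(fixture_fits[0].spec, tol=1e-10, max_iter=60)
        res0 = sm.GEE(
            fixture_data["y1"],
            np.column_stack(
                [np.ones(len(fixture_data)), fixture_data["group"], fixture_data["x1"]]
            ),
            groups=fixture_data["id"],
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit(maxiter=200, ctol=1e-11)
        assert gauss.phi_hat == pytest.approx(res0.scale, rel=1e-6)

    def test_constant_weights_leave_beta_invariant(self, fixture_data):
        spec1 = mg.analysis_specs(fixture_data, 3)[0]
        weighted = mg.GEEModelSpec(
            response=spec1.response,
            design=spec1.design,
            cluster_id=spec1.cluster_id,
            family=spec1.family,
            working_correlation="exchangeable",
            weights=np.full(spec1.n_obs, 2.0),
        )
        f1 = mg.fit_gee(spec1)
        f2 = mg.fit_gee(weighted)
        assert np.allclose(f1.beta_hat, f2.beta_hat, atol=1e-8)
        # the constant weight is absorbed by the re-estimated scale, so
        # the score contributions (and the sandwich) are unchanged too
        assert f2.phi_hat == pytest.approx(2.0 * f1.phi_hat, rel=1e-8)
        assert np.allclose(
            np.asarray(f1.cluster_scores), np.asarray(f2.cluster_scores), rtol=1e-6
        )

    def test_misspecified_correlation_still_consistent(self):
        """Exchangeable data fitted with independence and exchangeable
        working correlations both recover the generating coefficients."""
        cfg = mg.ScenarioConfig(M=3, K=2000, effects="all", seed=11)
        data = mg.generate_dataset(cfg)
        for corstr in ("independence", "exchangeable"):
            spec = mg.analysis_specs(data, 3, working_correlation=corstr)[0]
            fit = mg.fit_gee(spec)
            se = np.sqrt(np.diag(mg.stack_models([fit]).sigma))
            assert np.all(
                np.abs(fit.beta_hat - cfg.coefficients[0]) < 4.0 * se
            )

    def test_nonconvergence_warns(self, fixture_data):
        spec = mg.analysis_specs(fixture_data, 3)[1]
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = mg.fit_gee(spec, max_iter=1)
        assert not fit.converged

    def test_missing_rows_dropped_per_model(self, fixture_data):
        data = fixture_data.copy()
        # knock out one subject's responses for endpoint 1 only
        data.loc[data["id"] == 5, "y1"] = np.nan
        spec = mg.GEEModelSpec.from_dataframe(
            data,
            response="y1",
            covariates=["group", "x1"],
            family="gaussian",
            working_correlation="exchangeable",
        )
        assert 5 not in spec.cluster_labels
        fit = mg.fit_gee(spec)
        assert fit.converged

    def test_rank_deficient_design_rejected(self, rng):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank deficient"):
            mg.GEEModelSpec(
                response=rng.normal(size=20),
                design=X,
                cluster_id=np.arange(20),
                family="gaussian",
            )
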