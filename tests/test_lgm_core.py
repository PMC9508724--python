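import math

import numpy as np
import pytest
from scipy import stats

from lgmsens import (GrowthSpec, LGMParams, fiml_loglik, fit_indices, fit_mar,
                     group_contrasts, implied_moments, independence_fit,
                     trial_emulation_defaults, saturated_fit, simulate_trial)
from lgmsens.lgm_core import FitIndices, FitResult, GrowthLayout, Convergence
from .conftest import make_dataset

SPEC = GrowthSpec.standard()
LAM = SPEC.loadings


def params(alpha=(3.5, 0.0, 0.0), beta=(0.0, 0.0, 0.0), psi=None, eps=1.0):
    psi = np.zeros((3, 3)) if psi is None else np.asarray(psi)
    return LGMParams(alpha=np.asarray(alpha, dtype=float),
                     B=np.asarray(beta, dtype=float)[:, None],
                     Psi=psi, eps=np.full(5, eps, dtype=float))


class TestImpliedMoments:
    def test_zero_psi_gives_identity_covariance(self):
        mu, sigma = implied_moments(params(), SPEC, x=[0.0])
        np.testing.assert_allclose(mu, 3.5)
        np.testing.assert_allclose(sigma, np.eye(5))

    def test_arm_slope_effect_shows_at_loadings(self):
        mu0, _ = implied_moments(params(beta=(0, -0.2, 0)), SPEC, x=[0.0])
        mu1, _ = implied_moments(params(beta=(0, -0.2, 0)), SPEC, x=[1.0])
        np.testing.assert_allclose(mu1 - mu0, LAM[:, 1] * -0.2)
        assert (mu1 - mu0)[3] == pytest.approx(-0.08)

    def test_matches_explicit_triple_product(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        psi = A @ A.T
        eps = rng.random(5) + 0.1
        p = LGMParams(alpha=rng.standard_normal(3),
                      B=rng.standard_normal((3, 1)), Psi=psi, eps=eps)
        x = rng.standard_normal(1)
        mu, sigma = implied_moments(p, SPEC, x)
        np.testing.assert_allclose(sigma, LAM @ psi @ LAM.T + np.diag(eps),
                                   atol=1e-12)
        np.testing.assert_allclose(mu, LAM @ (p.alpha + p.B @ x), atol=1e-12)

    def test_non_psd_psi_rejected(self):
        with pytest.raises(ValueError):
            implied_moments(params(psi=[[1, 0, 0], [0, -1, 0], [0, 0, 1]]),
                            SPEC, x=[0.0])


class TestFimlLoglik:
    def test_complete_case_equals_joint_density(self):
        p = params(psi=np.diag([2.0, 0.3, 0.05]))
        ds = make_dataset([[3.1, 3.0, 2.8, 2.5, 2.0]], arm=[1])
        mu, sigma = implied_moments(p, SPEC, x=[1.0])
        expected = stats.multivariate_normal(mu, sigma).logpdf(ds.outcome[0])
        assert fiml_loglik(p, SPEC, ds) == pytest.approx(expected, abs=1e-10)

    def test_baseline_only_case_is_univariate(self):
        p = params(psi=np.diag([2.0, 0.3, 0.05]))
        y = np.array([[3.1, np.nan, np.nan, np.nan, np.nan]])
        ds = make_dataset(y, arm=[0])
        expected = stats.norm(3.5, math.sqrt(2.0 + 1.0)).logpdf(3.1)
        assert fiml_loglik(p, SPEC, ds) == pytest.approx(expected, abs=1e-10)

    def test_duplicated_case_doubles_contribution(self):
        p = params(psi=np.diag([2.0, 0.3, 0.05]))
        y = np.array([[3.1, 2.9, np.nan, 2.5, np.nan]])
        single = fiml_loglik(p, SPEC, make_dataset(y, arm=[0]))
        double = fiml_loglik(p, SPEC, make_dataset(np.vstack([y, y]),
                                                   arm=[0, 0]))
        assert double == pytest.approx(2 * single, abs=1e-10)


class TestFitMar:
    def test_recovers_generating_parameters(self, emulated_trial):
        fit = fit_mar(emulated_trial, compute_se=True)
        cfg = trial_emulation_defaults()
        assert fit.convergence.converged
        np.testing.assert_allclose(fit.params.alpha[0], 3.5, atol=0.25)
        np.testing.assert_allclose(fit.params.eps, 1.0, atol=0.4)
        se = fit.estimates["se_sandwich"]
        assert (se.loc[[f"alpha[{f}]" for f in SPEC.factors]] > 0).all()

    def test_arm_recode_flips_coefficients(self, emulated_trial):
        fit = fit_mar(emulated_trial, compute_se=False)
        swapped = make_dataset(emulated_trial.outcome,
                               arm=1 - emulated_trial.arm,
                               covariates=emulated_trial.covariates)
        fit2 = fit_mar(swapped, compute_se=False)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-4)
        np.testing.assert_allclose(fit2.params.B[:, 0], -fit.params.B[:, 0],
                                   atol=2e-3)

    def test_row_order_invariance(self, emulated_trial):
        fit = fit_mar(emulated_trial, compute_se=False)
        rng = np.random.default_rng(0)
        perm = rng.permutation(emulated_trial.n)
        shuffled = emulated_trial.subset(perm)
        fit2 = fit_mar(shuffled, compute_se=False)
        np.testing.assert_allclose(fit2.theta, fit.theta, atol=1e-6)

    def test_start_value_jitter_invariance(self, emulated_trial):
        fit = fit_mar(emulated_trial, compute_se=False, polish=True)
        rng = np.random.default_rng(1)
        theta0 = fit.theta * (1 + 0.2 * rng.uniform(-1, 1, len(fit.theta)))
        fit2 = fit_mar(emulated_trial, compute_se=False, polish=True,
                       theta0=theta0)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        np.testing.assert_allclose(
            fit2.layout.natural_values(fit2.theta)[:6],
            fit.layout.natural_values(fit.theta)[:6], atol=1e-5)

    def test_complete_data_loglik_equals_joint_normal(self, complete_trial):
        fit = fit_mar(complete_trial, compute_se=False)
        mu0, sigma = implied_moments(fit.params, SPEC, x=[0.0])
        mu1, _ = implied_moments(fit.params, SPEC, x=[1.0])
        ll = 0.0
        for i in range(complete_trial.n):
            mu = mu1 if complete_trial.arm[i] else mu0
            ll += stats.multivariate_normal(mu, sigma).logpdf(
                complete_trial.outcome[i])
        assert fit.loglik == pytest.approx(ll, rel=1e-10)

    def test_sandwich_and_first_order_agree_when_correctly_specified(self):
        # large-N check; both estimators are consistent for the same limit
        ratios = []
        for seed in range(4):
            cfg = trial_emulation_defaults(n=4000, seed=100 + seed,
                                           mechanism="MAR")
            fit = fit_mar(simulate_trial(cfg), compute_se=True)
            sw = fit.estimates["se_sandwich"].to_numpy()
            fo = fit.estimates["se_first_order"].to_numpy()
            keep = fo > 1e-4
            ratios.append(np.median(np.abs(sw[keep] / fo[keep] - 1.0)))
        assert np.mean(ratios) < 0.10


class TestSaturatedAndIndices:
    def test_no_missing_em_fixed_point_is_sample_moments(self, complete_trial):
        sat = saturated_fit(complete_trial)
        np.testing.assert_allclose(sat.mean_coef[:, 0],
                                   complete_trial.outcome.mean(axis=0),
                                   atol=1e-8)
        np.testing.assert_allclose(
            sat.sigma, np.cov(complete_trial.outcome.T, ddof=0), atol=1e-8)

    def test_em_loglik_monotone(self, emulated_trial):
        sat = saturated_fit(emulated_trial)
        diffs = np.diff(sat.loglik_path)
        assert (diffs > -1e-8).all()

    def test_mcar_saturated_estimates_approach_truth(self):
        cfg = trial_emulation_defaults(n=8000, seed=21, mechanism="MCAR")
        ds = simulate_trial(cfg)
        sat = saturated_fit(ds)
        mu_true = ds.complete_outcome.mean(axis=0)
        np.testing.assert_allclose(sat.mean_coef[:, 0], mu_true, atol=0.08)

    def test_saturated_dominates_structured(self, emulated_trial):
        sat = saturated_fit(emulated_trial)
        fit = fit_mar(emulated_trial, compute_se=False)
        assert sat.loglik >= fit.loglik - 1e-6

    def test_bic_formula(self):
        conv = Convergence(True, 1, 0.0, "")
        fit = FitResult(model="m", spec=SPEC, layout=GrowthLayout(SPEC),
                        theta=np.zeros(17), params=params(), loglik=-100.0,
                        n=100, n_params=10, convergence=conv)
        assert fit.bic == pytest.approx(200 + 10 * math.log(100))

    def test_saturated_model_has_perfect_fit_indices(self, emulated_trial):
        sat = saturated_fit(emulated_trial)
        base = independence_fit(emulated_trial)
        conv = Convergence(True, 1, 0.0, "")
        pseudo = FitResult(model="sat", spec=SPEC, layout=GrowthLayout(SPEC),
                           theta=np.zeros(17), params=params(),
                           loglik=sat.loglik, n=emulated_trial.n,
                           n_params=sat.n_params, convergence=conv)
        fx = fit_indices(pseudo, sat, base)
        assert fx.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fx.cfi == 1.0
        assert fx.rmsea is None  # df = 0: undefined, not zero


class TestGroupContrasts:
    def make_fit(self, beta, cov_scale=0.01):
        layout = GrowthLayout(SPEC)
        p = params(beta=beta, psi=np.diag([1.0, 0.1, 0.01]))
        theta = layout.pack(p)
        conv = Convergence(True, 1, 0.0, "")
        cov = cov_scale * np.eye(layout.n_params)
        return FitResult(model="m", spec=SPEC, layout=layout, theta=theta,
                         params=p, loglik=0.0, n=100, n_params=17,
                         convergence=conv, cov_sandwich=cov,
                         cov_first_order=cov)

    def test_loading_algebra(self):
        tab = group_contrasts(self.make_fit((0.0, 0.1, 0.0)))
        assert tab.loc["diff_t4", "estimate"] == pytest.approx(0.12)
        assert tab.loc["change_diff_t4", "estimate"] == pytest.approx(-0.12)

    def test_identity_diff_minus_change_is_intercept_effect(self):
        tab = group_contrasts(self.make_fit((0.3, -0.2, 0.05)))
        for t in (3, 4):
            lhs = tab.loc[f"diff_t{t}", "estimate"] + \
                tab.loc[f"change_diff_t{t}", "estimate"]
            assert lhs == pytest.approx(0.3, abs=1e-12)

    def test_delta_ci_matches_parametric_bootstrap(self):
        fit = self.make_fit((0.2, -0.1, 0.03), cov_scale=0.04)
        tab = group_contrasts(fit)
        rng = np.random.default_rng(8)
        draws = fit.theta[None, :] + rng.standard_normal(
            (20000, len(fit.theta))) * 0.2
        layout = fit.layout
        q = len(SPEC.regressors)
        for t in (3, 4):
            lam_row = SPEC.loadings[t]
            c = np.zeros(layout.n_params)
            for i in range(3):
                c[layout.n_alpha + i * q] = lam_row[i]
            boot_sd = (draws @ c).std(ddof=1)
            assert tab.loc[f"diff_t{t}", "se"] == pytest.approx(boot_sd,
                                                                rel=0.02)
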