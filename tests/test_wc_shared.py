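import math

import numpy as np
import pytest
from scipy.stats import norm

from lgmsens import (GrowthSpec, LGMParams, code_missing_indicators, fit_mar,
                     fit_wc, trial_emulation_defaults, simulate_trial,
                     wc_loglik)
from lgmsens.dk_selection import _sel_start
from lgmsens.wc_shared import SharedParams, WCModel
from .conftest import make_dataset

SPEC = GrowthSpec.standard()


@pytest.fixture(scope="module")
def wc_trial():
    cfg = trial_emulation_defaults(n=500, seed=23, mechanism="MNAR_WC")
    return simulate_trial(cfg)


class TestWcLoglik:
    def test_zero_gamma_separates_into_fiml_plus_indicator_logistic(self,
                                                                    wc_trial):
        mar = fit_mar(wc_trial, compute_se=False, polish=False)
        tau = np.array([-1.5, -2.0, -3.0, -1.0])
        model = WCModel(wc_trial, SPEC, "survival", nodes=15)
        theta = np.concatenate([mar.theta, tau, [0.0, 0.0]])
        joint = model.casewise(theta).sum()
        ind = code_missing_indicators(wc_trial, "survival").values
        sel_ll = 0.0
        for t in range(4):
            at_risk = ind[:, t] >= 0
            events = (ind[:, t] == 1).sum()
            p = 1 / (1 + math.exp(-tau[t]))
            sel_ll += events * math.log(p) + \
                (at_risk.sum() - events) * math.log(1 - p)
        assert joint == pytest.approx(mar.loglik + sel_ll, abs=1e-6)

    def test_degenerate_factor_variances_collapse_the_integral(self):
        # with Psi = 0 the factors are deterministic at alpha + Bx, so the
        # marginal likelihood is the plain product of densities and logistics
        spec = GrowthSpec(factors=SPEC.factors, regressors=("arm",),
                          fixed_zero_variance=SPEC.factors)
        y = np.array([[3.0, 3.1, np.nan, np.nan, np.nan]])
        ds = make_dataset(y, arm=[0])
        alpha = np.array([3.2, -0.8, 0.3])
        p = LGMParams(alpha=alpha, B=np.zeros((3, 1)), Psi=np.zeros((3, 3)),
                      eps=np.ones(5))
        tau = np.array([-1.0, -0.5, -1.5, -2.0])
        gamma = np.array([0.25, -0.4])
        sel = SharedParams(coding="survival", tau=tau, gamma=gamma[:, None],
                           factor_names=("intercept", "linear"))
        got = wc_loglik(p, sel, spec, ds)
        lam = spec.loadings
        mu = lam @ alpha
        expect = norm(mu[0], 1.0).logpdf(3.0) + norm(mu[1], 1.0).logpdf(3.1)
        u = gamma[0] * alpha[0] + gamma[1] * alpha[1]
        # observed t1 (no event), dropout at t2, not at risk afterwards
        expect += math.log(1 - 1 / (1 + math.exp(-(tau[0] + u))))
        expect += math.log(1 / (1 + math.exp(-(tau[1] + u))))
        assert got == pytest.approx(expect, abs=1e-6)

    def test_node_doubling_stability(self, wc_trial):
        mar = fit_mar(wc_trial, compute_se=False, polish=False)
        k = 1
        tau = _sel_start(wc_trial, "survival",
                         code_missing_indicators(wc_trial, "survival"))[:4]
        theta = np.concatenate([mar.theta, tau, [0.15, -0.1]])
        ll15 = WCModel(wc_trial, SPEC, "survival", nodes=15).casewise(theta)
        ll31 = WCModel(wc_trial, SPEC, "survival", nodes=31).casewise(theta)
        assert np.max(np.abs(ll15 - ll31)) < 1e-4

    def test_quadrature_consistent_with_monte_carlo_bound(self, wc_trial):
        # quadrature value should not fall below the MC estimate by more than
        # 3 MC standard errors on any fixture case
        mar = fit_mar(wc_trial, compute_se=False, polish=False)
        tau = np.array([-1.8, -2.8, -4.0, -1.5])
        gamma = np.array([0.2, 0.1])
        theta = np.concatenate([mar.theta, tau, gamma])
        model = WCModel(wc_trial, SPEC, "survival", nodes=15)
        quad = model.casewise(theta)
        params = mar.params
        rng = np.random.default_rng(0)
        keys = wc_trial.pattern_keys()
        lam = SPEC.loadings
        chol = np.linalg.cholesky(params.Psi + 1e-10 * np.eye(3))
        for key in list(dict.fromkeys(keys))[:5]:
            i = int(np.flatnonzero(keys == key)[0])
            obs = np.flatnonzero(wc_trial.mask[i])
            x = float(wc_trial.arm[i])
            a = params.alpha + params.B[:, 0] * x
            n_mc = 200_000
            eta = a + rng.standard_normal((n_mc, 3)) @ chol.T
            logp = norm.logpdf(wc_trial.outcome[i, obs][None, :],
                               eta @ lam[obs].T,
                               np.sqrt(params.eps[obs])[None, :]).sum(axis=1)
            u = eta[:, 0] * gamma[0] + eta[:, 1] * gamma[1]
            from lgmsens.dk_selection import build_sel_structure
            struct = build_sel_structure(wc_trial.mask[i], "survival")
            for t, cat in zip(struct.at_risk, struct.category):
                e = tau[t - 1] + u
                logp += -np.log1p(np.exp(-e)) if cat == 1 \
                    else -np.log1p(np.exp(e))
            w = np.exp(logp - logp.max())
            mc = logp.max() + math.log(w.mean())
            mc_se = w.std() / (w.mean() * math.sqrt(n_mc))
            assert quad[i] >= mc - 3 * mc_se


class TestFitWc:
    def test_gamma_fixed_at_zero_reproduces_mar_growth(self, wc_trial):
        mar = fit_mar(wc_trial, compute_se=False)
        wc = fit_wc(wc_trial, coding="survival", compute_se=False,
                    fix_gamma=True, polish=True)
        np.testing.assert_allclose(wc.theta[:mar.layout.n_params], mar.theta,
                                   atol=1e-5)

    @pytest.mark.parametrize("coding", ["survival", "multinomial"])
    def test_joint_fit_reports_factor_odds(self, wc_trial, coding):
        fit = fit_wc(wc_trial, coding=coding, compute_se=True, nodes=9)
        assert fit.convergence.converged
        odds = fit.extra["selection_odds"]
        assert all("gamma" in name for name in odds.index)
        assert (odds["or"] > 0).all()

    def test_unknown_information_type_rejected(self, wc_trial):
        with pytest.raises(ValueError):
            fit_wc(wc_trial, information="expected")
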