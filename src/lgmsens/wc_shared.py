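"""Wu-Carroll shared-parameter model: the wave-wise missing-data indicators
are regressed on the latent growth factors, so missingness depends on each
participant's whole trajectory (observed and unobserved alike).

The marginal likelihood integrates the indicator probabilities over the latent
intercept and slope. Because the indicators depend on the factors only, the
joint density factorises exactly as

    p(y_obs, m) = p(y_obs) * E_{(I,S) | y_obs}[ prod_t P(m_t | I, S) ],

with p(y_obs) the FIML Gaussian factor and the conditional law of (I, S) given
the observed outcomes bivariate normal in closed form. The expectation is
evaluated by Gauss-Hermite quadrature centred at the conditional mean and
scaled by the conditional Cholesky factor — the adaptive (empirical-Bayes)
scheme. The quadratic growth factor, when present, is deliberately excluded
from the selection regression but stays in the growth model: it is absorbed
analytically by the Gaussian factor and the conditional moments, matching the
convention of omitting it to achieve convergence.

Shared-parameter models are prone to an observed-vs-expected information
mismatch; both sandwich and first-order (inverse outer-product-of-scores,
"MLF"-style) standard errors are computed, and a large relative disagreement
triggers a warning recommending the first-order flavour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data_model import LongitudinalDataset, N_WAVES, code_missing_indicators
from .dk_selection import (SelStructure, _logistic_logprob,
                           _multinomial_logprob, build_sel_structure,
                           gauss_hermite_grid, selection_odds_table, _sel_start,
                           _LOGIT_CLIP)
from .lgm_core import (FitResult, GrowthLayout, GrowthSpec,
                       NonConvergenceError, PatternData, _gaussian_scores,
                       _information_covariances, _maximise, _natural_table,
                       fit_mar, group_contrasts)

SHARED_FACTORS = ("intercept", "linear")   # factors entering the regression


@dataclass
class SharedParams:
    """Wave-specific intercepts plus coefficients on the latent factors.

    Survival coding: ``tau`` is (4,), ``gamma`` is (n_shared,). Multinomial
    coding: ``tau`` is (4, 2), ``gamma`` is (n_shared, 2) with one column per
    non-reference category (intermittent, dropout); per-category coefficients
    are unconstrained. The quadratic factor never enters the regression.
    """

    coding: str
    tau: np.ndarray
    gamma: np.ndarray
    factor_names: tuple[str, ...]


class WCLayout:
    """Growth-layout prefix plus shared-parameter coefficients."""

    def __init__(self, spec: GrowthSpec, coding: str):
        if coding not in ("survival", "multinomial"):
            raise ValueError(f"unknown indicator coding scheme: {coding!r}")
        self.coding = coding
        self.growth = GrowthLayout(spec)
        self.spec = spec
        self.n_alpha = self.growth.n_alpha
        self.n_b = self.growth.n_b
        self.shared = tuple(f for f in SHARED_FACTORS if f in spec.factors)
        ncat = 1 if coding == "survival" else 2
        self.ncat = ncat
        cats = [""] if ncat == 1 else [",intermittent", ",dropout"]
        sel_names = [f"sel_tau[t{t}{c}]" for t in range(1, N_WAVES) for c in cats]
        sel_names += [f"sel_gamma[{f}{c}]" for f in self.shared for c in cats]
        self.names = self.growth.names + sel_names
        self.n_growth = self.growth.n_params

    @property
    def n_params(self) -> int:
        return len(self.names)

    def unpack_sel(self, theta: np.ndarray) -> SharedParams:
        s = theta[self.n_growth:]
        k = self.ncat
        tau = s[:4 * k].reshape(4, k)
        gamma = s[4 * k:].reshape(len(self.shared), k)
        if k == 1:
            tau = tau[:, 0]
        return SharedParams(coding=self.coding, tau=tau, gamma=gamma,
                            factor_names=self.shared)

    def natural_names(self):
        return self.names

    def natural_values(self, theta):
        return np.concatenate([self.growth.natural_values(theta[:self.n_growth]),
                               theta[self.n_growth:]])

    def natural_names_full(self):
        return self.growth.natural_names() + self.names[self.n_growth:]


class WCModel:
    """Precomputed pattern structure + likelihood/score evaluator.

    Every selection term depends on the factors only through the linear
    predictors u = Gamma' (I, S), so the marginal integral is evaluated on the
    exact low-dimensional law of u given y_obs (1-D under survival coding, 2-D
    under multinomial coding). Node placement thereby scales with the spread
    of the linear predictor itself, keeping the quadrature accurate for
    arbitrarily steep coefficients.
    """

    def __init__(self, dataset: LongitudinalDataset, spec: GrowthSpec,
                 coding: str, nodes: int = 15):
        self.layout = WCLayout(spec, coding)
        self.pdata = PatternData(dataset, spec)
        self.coding = coding
        self.nodes = nodes
        self.n = dataset.n
        self.lam = spec.loadings
        self.J = [spec.factors.index(f) for f in self.layout.shared]
        self.grid = gauss_hermite_grid(self.layout.ncat, nodes)
        self.blocks = []
        for blk in self.pdata.blocks:
            st = build_sel_structure(dataset.mask[blk.rows[0]], coding)
            o = blk.obs
            self.blocks.append((blk, st, np.ix_(o, o)))

    def _cond_factor_law(self, psi, cf, lam_o, eta_f, resid_o):
        """Conditional mean (n, j) and covariance (j, j) of the shared factors
        given the observed outcomes of one pattern."""
        J = self.J
        cross = psi[J, :] @ lam_o.T
        Kmat = linalg.cho_solve(cf, cross.T).T
        V = psi[np.ix_(J, J)] - Kmat @ cross.T
        fmean = eta_f[:, J] + resid_o @ Kmat.T
        return fmean, 0.5 * (V + V.T), Kmat, cross

    # -- likelihood --------------------------------------------------------
    def casewise(self, theta: np.ndarray) -> np.ndarray:
        layout = self.layout
        params = layout.growth.unpack(theta[:layout.n_growth])
        sel = layout.unpack_sel(theta)
        lam = self.lam
        psi = params.Psi
        sigma = lam @ psi @ lam.T + np.diag(params.eps)
        k = layout.ncat
        gamma = sel.gamma                                   # (nj, k)
        Z, Wq = self.grid                                   # (K, k), (K,)
        out = np.empty(self.n)

        for blk, st, ix_oo in self.blocks:
            o = blk.obs
            ko = len(o)
            try:
                cf = linalg.cho_factor(sigma[ix_oo], lower=True)
            except linalg.LinAlgError:
                out[:] = -1e10
                return out
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            eta_f = params.alpha[None, :] + blk.X @ params.B.T
            mu = eta_f @ lam.T
            resid_o = blk.Y - mu[:, o]
            zsolve = linalg.cho_solve(cf, resid_o.T)
            quad = np.einsum("ij,ji->i", resid_o, zsolve)
            ll = -0.5 * (ko * math.log(2 * math.pi) + logdet + quad)

            fmean, V, _, _ = self._cond_factor_law(psi, cf, lam[o], eta_f,
                                                   resid_o)
            M = fmean @ gamma                               # (n, k)
            U = gamma.T @ V @ gamma                         # (k, k)
            Lu = np.linalg.cholesky(U + 1e-10 * np.eye(k))
            unodes = M[:, None, :] + (Z @ Lu.T)[None, :, :]  # (n, K, k)

            logg = np.zeros((len(blk.rows), Z.shape[0]))
            for t, cat in zip(st.at_risk, st.category):
                if k == 1:
                    eta = sel.tau[t - 1] + unodes[:, :, 0]
                    logg += _logistic_logprob(eta, event=cat == 1)
                else:
                    eta0 = sel.tau[t - 1, 0] + unodes[:, :, 0]
                    eta1 = sel.tau[t - 1, 1] + unodes[:, :, 1]
                    logg += _multinomial_logprob(eta0, eta1, cat)
            E = np.exp(logg) @ Wq
            out[blk.rows] = ll + np.log(np.maximum(E, 1e-300))
        return out

    # -- analytic scores ---------------------------------------------------
    def scores(self, theta: np.ndarray) -> np.ndarray:
        layout = self.layout
        gl = layout.growth
        ng = layout.n_growth
        S = np.zeros((self.n, layout.n_params))
        S[:, :ng] = _gaussian_scores(theta[:ng], gl, self.pdata)
        params = gl.unpack(theta[:ng])
        sel = layout.unpack_sel(theta)
        lam = self.lam
        J = self.J
        nj = len(J)
        psi = params.Psi
        sigma = lam @ psi @ lam.T + np.diag(params.eps)
        k = layout.ncat
        gamma = sel.gamma
        nf, q = gl.spec.n_factors, len(gl.spec.regressors)
        a0 = gl.n_alpha
        Z, Wq = self.grid

        # dPsi / dSigma for covariance-side thetas
        r = len(gl.free_factors)
        L = np.zeros((r, r))
        c0 = gl.n_chol
        L[gl._tri] = theta[a0 + gl.n_b:a0 + gl.n_b + c0]
        fi = gl.free_idx
        cov_derivs = []
        for e, (ia, ib) in enumerate(zip(*gl._tri)):
            dpsi_free = np.zeros((r, r))
            dpsi_free[ia, :] += L[:, ib]
            dpsi_free[:, ia] += L[:, ib]
            dpsi = np.zeros((nf, nf))
            dpsi[np.ix_(fi, fi)] = dpsi_free
            cov_derivs.append((a0 + gl.n_b + e, dpsi, lam @ dpsi @ lam.T))
        for t in range(N_WAVES):
            dS = np.zeros((N_WAVES, N_WAVES))
            dS[t, t] = params.eps[t]
            cov_derivs.append((a0 + gl.n_b + c0 + t, np.zeros((nf, nf)), dS))

        def tau_idx(t, c=0):
            return ng + (t - 1) * k + c

        def gamma_idx(j, c=0):
            return ng + 4 * k + j * k + c

        def dchol(Lu, dU):
            A = linalg.solve_triangular(Lu, dU, lower=True)
            A = linalg.solve_triangular(Lu, A.T, lower=True).T
            phi = np.tril(A)
            np.fill_diagonal(phi, 0.5 * np.diag(A))
            return Lu @ phi

        for blk, st, ix_oo in self.blocks:
            rows = blk.rows
            n_p = len(rows)
            o = blk.obs
            cf = linalg.cho_factor(sigma[ix_oo], lower=True)
            eta_f = params.alpha[None, :] + blk.X @ params.B.T
            mu = eta_f @ lam.T
            resid_o = blk.Y - mu[:, o]
            lam_o = lam[o]
            fmean, V, Kmat, cross = self._cond_factor_law(
                psi, cf, lam_o, eta_f, resid_o)
            M = fmean @ gamma
            U = gamma.T @ V @ gamma
            Lu = np.linalg.cholesky(U + 1e-10 * np.eye(k))
            unodes = M[:, None, :] + (Z @ Lu.T)[None, :, :]
            K = Z.shape[0]

            logg = np.zeros((n_p, K))
            D = np.zeros((n_p, K, k))       # d s / d u_c at each node
            terms = []
            for t, cat in zip(st.at_risk, st.category):
                if k == 1:
                    eta = sel.tau[t - 1] + unodes[:, :, 0]
                    logg += _logistic_logprob(eta, event=cat == 1)
                    sig = 1.0 / (1.0 + np.exp(-np.clip(eta, -_LOGIT_CLIP,
                                                       _LOGIT_CLIP)))
                    dlp = ((1.0 - sig) if cat == 1 else -sig,)
                else:
                    eta0 = sel.tau[t - 1, 0] + unodes[:, :, 0]
                    eta1 = sel.tau[t - 1, 1] + unodes[:, :, 1]
                    logg += _multinomial_logprob(eta0, eta1, cat)
                    lse = np.logaddexp(0.0, np.logaddexp(
                        np.clip(eta0, -_LOGIT_CLIP, _LOGIT_CLIP),
                        np.clip(eta1, -_LOGIT_CLIP, _LOGIT_CLIP)))
                    P0 = np.exp(np.clip(eta0, -_LOGIT_CLIP, _LOGIT_CLIP) - lse)
                    P1 = np.exp(np.clip(eta1, -_LOGIT_CLIP, _LOGIT_CLIP) - lse)
                    dlp = ((1.0 if cat == 0 else 0.0) - P0,
                           (1.0 if cat == 1 else 0.0) - P1)
                terms.append((t, dlp))
                for c, d in enumerate(dlp):
                    D[:, :, c] += d

            g = np.exp(logg) * Wq[None, :]
            E = g.sum(axis=1)
            pnode = g / np.maximum(E, 1e-300)[:, None]

            # selection intercepts
            for t, dlp in terms:
                for c, d in enumerate(dlp):
                    S[rows, tau_idx(t, c)] += (pnode * d).sum(axis=1)
            Dbar = np.einsum("nk,nkc->nc", pnode, D)          # (n, k)
            Nmat = np.einsum("nk,nkc,kb->ncb", pnode, D, Z)   # (n, k, k)
            # gamma coefficients: dM_c = fmean_j, dU = E'VG + G'VE
            VG = V @ gamma                                    # (nj, k)
            for j in range(nj):
                for c in range(k):
                    dU = np.zeros((k, k))
                    dU[c, :] += VG[j, :]
                    dU[:, c] += VG[j, :]
                    dLu = dchol(Lu, dU)
                    contrib = Dbar[:, c] * fmean[:, j] \
                        + np.einsum("ncb,cb->n", Nmat, dLu)
                    S[rows, gamma_idx(j, c)] += contrib
            # mean-side growth parameters: dfmean constant per factor
            for f in range(nf):
                const = np.array([1.0 if J[j] == f else 0.0 for j in range(nj)])
                const = const - Kmat @ lam_o[:, f]            # (nj,)
                dM = gamma.T @ const                          # (k,)
                base = Dbar @ dM
                S[rows, f] += base
                for qq in range(q):
                    S[rows, a0 + f * q + qq] += base * blk.X[:, qq]
            # covariance-side growth parameters
            Soo_inv = linalg.cho_solve(cf, np.eye(len(o)))
            for jidx, dpsi, dSig in cov_derivs:
                dcross = dpsi[J, :] @ lam_o.T
                dK = (dcross - Kmat @ dSig[ix_oo]) @ Soo_inv
                dV = dpsi[np.ix_(J, J)] - dK @ cross.T - Kmat @ dcross.T
                dV = 0.5 * (dV + dV.T)
                dU = gamma.T @ dV @ gamma
                dLu = dchol(Lu, dU)
                dM_i = (resid_o @ dK.T) @ gamma               # (n, k)
                S[rows, jidx] += (np.einsum("nc,nc->n", Dbar, dM_i)
                                  + np.einsum("ncb,cb->n", Nmat, dLu))
        return S


def fix_gamma_indices_available(layout: WCLayout, fixed: dict, j: int) -> bool:
    """True unless the factor-j coefficients are already fixed."""
    k = layout.ncat
    return not all(layout.n_growth + 4 * k + j * k + c in fixed
                   for c in range(k))


def wc_loglik(params, shared: SharedParams, spec: GrowthSpec,
              dataset: LongitudinalDataset, nodes: int = 15) -> float:
    """Joint shared-parameter log-likelihood at given growth + shared params."""
    model = WCModel(dataset, spec, shared.coding, nodes=nodes)
    layout = model.layout
    gtheta = layout.growth.pack(params)
    k = layout.ncat
    tau = np.asarray(shared.tau, dtype=float).reshape(4, k)
    gam = np.asarray(shared.gamma, dtype=float).reshape(len(layout.shared), k)
    return float(model.casewise(
        np.concatenate([gtheta, tau.ravel(), gam.ravel()])).sum())


def fit_wc(dataset: LongitudinalDataset, spec: GrowthSpec | None = None,
           coding: str = "survival", information: str = "sandwich",
           nodes: int = 15, compute_se: bool = True,
           maxiter: int = 1000, polish: bool = False,
           fix_gamma: bool = False,
           ftol: float = 1e-11, gtol: float = 1e-7) -> FitResult:
    """Jointly fit growth and shared-parameter coefficients.

    ``information`` chooses the SE flavour used for contrasts and odds ratios
    ("sandwich" or "first_order"); both are always computed, and a >25%
    relative disagreement triggers a warning recommending first_order.
    ``fix_gamma`` keeps the factor coefficients at 0 (the likelihood then
    separates and the growth part reproduces the MAR fit).
    """
    if information not in ("sandwich", "first_order"):
        raise ValueError(f"unknown information matrix type {information!r}")
    spec = spec or GrowthSpec.standard()
    model = WCModel(dataset, spec, coding, nodes=nodes)
    layout = model.layout

    mar = fit_mar(dataset, spec, compute_se=False, polish=False)
    ind = code_missing_indicators(dataset, coding)
    sel0 = _sel_start(dataset, coding, ind)[:4 * layout.ncat]
    theta0 = np.concatenate([mar.theta, sel0,
                             np.zeros(len(layout.shared) * layout.ncat)])

    def grad(th):
        return model.scores(th).sum(axis=0)

    k = layout.ncat
    bounds = layout.growth.bounds()
    # gamma capped just above the degeneracy guard so a diverging fit reaches
    # the guard quickly instead of marching along the flat ridge
    bounds += [(-20.0, 20.0)] * (4 * k) + [(-4.0, 4.0)] * (len(layout.shared) * k)
    fixed = {}
    if fix_gamma:
        for i in range(layout.n_growth + 4 * k, layout.n_params):
            fixed[i] = 0.0

    try:
        theta, conv = _maximise(model.casewise, theta0, model.n, bounds=bounds,
                                fixed=fixed, maxiter=maxiter, polish=polish,
                                grad=grad, ftol=ftol, gtol=gtol)
    except NonConvergenceError:
        frozen = dict(fixed)
        for i in range(layout.n_growth):
            frozen[i] = theta0[i]
        theta_s, _ = _maximise(model.casewise, theta0, model.n, bounds=bounds,
                               fixed=frozen, maxiter=maxiter, polish=False,
                               grad=grad, ftol=ftol, gtol=gtol)
        theta, conv = _maximise(model.casewise, theta_s, model.n, bounds=bounds,
                                fixed=fixed, maxiter=maxiter, polish=polish,
                                grad=grad, ftol=ftol, gtol=gtol)

    # Degenerate-ridge guard. The marginal likelihood of shared-parameter
    # models admits a deterministic-dropout limit (|gamma| -> infinity) that
    # can dominate the interior optimum in finite samples. A coefficient
    # beyond 3 (odds ratio > 20 per factor-unit) is treated as that
    # degeneracy: the offending factor is dropped from the selection
    # regression and the model refitted, echoing the established practice of
    # omitting factors from the regression to achieve credible convergence.
    dropped: list[str] = []
    for _ in range(len(layout.shared)):
        gam = layout.unpack_sel(theta).gamma         # (nj, ncat)
        worst = np.abs(gam).max(axis=1)
        j = int(np.argmax(worst))
        if worst[j] <= 3.0 or not fix_gamma_indices_available(layout, fixed, j):
            break
        factor = layout.shared[j]
        warnings.warn(
            f"shared-parameter coefficient for the {factor} factor diverged "
            f"(|gamma|={worst[j]:.1f}); refitting with that factor omitted "
            f"from the selection regression")
        for c in range(k):
            fixed[layout.n_growth + 4 * k + j * k + c] = 0.0
        dropped.append(factor)
        theta, conv = _maximise(model.casewise, theta0, model.n, bounds=bounds,
                                fixed=fixed, maxiter=maxiter, polish=polish,
                                grad=grad, ftol=ftol, gtol=gtol)

    ll = float(model.casewise(theta).sum())
    cov_sw = cov_fo = None
    if compute_se:
        cov_sw, cov_fo, min_eig = _information_covariances(
            model.casewise, theta, model.n, fixed, scores=model.scores)
        conv.hessian_min_eig = min_eig
        se_sw = np.sqrt(np.maximum(np.diag(cov_sw), 0.0))
        se_fo = np.sqrt(np.maximum(np.diag(cov_fo), 0.0))
        ok = se_fo > 0
        if ok.any():
            rel = np.max(np.abs(se_sw[ok] - se_fo[ok]) / se_fo[ok])
            if rel > 0.25 and information == "sandwich":
                warnings.warn(
                    f"sandwich and first-order standard errors disagree by "
                    f"{100 * rel:.0f}% (information-matrix mismatch); consider "
                    f"information='first_order'")

    fit = FitResult(model=f"wc_{coding}", spec=spec, layout=layout,
                    theta=theta,
                    params=layout.growth.unpack(theta[:layout.n_growth]),
                    loglik=ll, n=model.n,
                    n_params=layout.n_params - len(fixed), convergence=conv,
                    cov_sandwich=cov_sw, cov_first_order=cov_fo)
    fit.estimates = _natural_table(
        layout, theta, cov_sw, cov_fo,
        natural_fn=layout.natural_values).set_axis(
            layout.natural_names_full(), axis=0)
    if "arm" in spec.regressors:
        fit.contrasts = group_contrasts(fit, se=information)
    fit.extra["shared"] = layout.unpack_sel(theta)
    fit.extra["dropped_factors"] = dropped
    fit.extra["information"] = information
    cov_rep = cov_sw if information == "sandwich" else cov_fo
    fit.extra["selection_odds"] = selection_odds_table(layout, theta, cov_rep)
    return fit
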