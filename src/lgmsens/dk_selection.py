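"""Diggle-Kenward selection model: the growth model is joined with wave-wise
logistic (or baseline-category multinomial) regressions of the missing-data
indicators on the concurrent outcome y_t and the previous outcome y_{t-1}.

The joint likelihood per participant multiplies (a) the multivariate-normal
density of the observed outcomes with (b) the selection probability at every
at-risk wave (waves after a dropout event contribute nothing). Selection terms
that involve a missing outcome are integrated against the conditional normal
distribution of those outcomes given the observed ones, by Gauss-Hermite
quadrature centred at the conditional mean and scaled by the conditional
Cholesky factor (adaptive in the empirical-Bayes sense); missing outcomes
entering no selection term are marginalised analytically, which is what the
observed-data Gaussian factor already does.

Under the survival coding the dropout propensity is modelled and intermittent
missingness is treated as ignorable; under the multinomial coding intermittent
missingness, permanent dropout and observation (reference) are three
categories, so observed waves are informative for the selection intercepts.
Slopes on y_t and y_{t-1} are shared across waves (wave-specific intercepts),
matching the single reported coefficient per outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import roots_hermite

from .data_model import LongitudinalDataset, N_WAVES, dropout_wave
from .lgm_core import (Convergence, FitResult, GrowthLayout, GrowthSpec,
                       NonConvergenceError, PatternData, _casewise_gaussian,
                       _information_covariances, _maximise, _natural_table,
                       _start_values, fit_mar, group_contrasts)

_LOGIT_CLIP = 35.0


@dataclass
class SelectionParams:
    """Wave-specific intercepts and shared outcome slopes.

    Survival coding: ``tau`` is (4,), slopes are scalars, the modelled event is
    permanent dropout. Multinomial coding: ``tau`` is (4, 2) and slopes are
    length-2, one per non-reference category in the order (intermittent,
    dropout); the observed-value category is the zero-coefficient reference.
    """

    coding: str
    tau: np.ndarray
    beta_prev: np.ndarray
    beta_curr: np.ndarray


def selection_prob(sel: SelectionParams, wave: int, y_curr: float,
                   y_prev: float) -> dict[int, float]:
    """Category probabilities of the wave-``wave`` indicator (wave in 1..4)."""
    if wave not in (1, 2, 3, 4):
        raise ValueError("wave must be in 1..4")
    t = wave - 1
    if sel.coding == "survival":
        eta = np.clip(np.squeeze(sel.tau[t] + sel.beta_prev * y_prev
                                 + sel.beta_curr * y_curr),
                      -_LOGIT_CLIP, _LOGIT_CLIP)
        p = 1.0 / (1.0 + math.exp(-float(eta)))
        return {0: 1.0 - p, 1: p}
    eta = np.clip(sel.tau[t] + sel.beta_prev * y_prev
                  + sel.beta_curr * y_curr, -_LOGIT_CLIP, _LOGIT_CLIP)
    ex = np.exp(eta)
    denom = 1.0 + ex.sum()
    return {0: float(ex[0] / denom), 1: float(ex[1] / denom),
            2: float(1.0 / denom)}


# ---------------------------------------------------------------------------
# quadrature helpers
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def gauss_hermite_grid(dim: int, nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product probabilist nodes/weights for E[f(Z)], Z ~ N(0, I_dim)."""
    x, w = roots_hermite(nodes)
    z1, w1 = x * math.sqrt(2.0), w / math.sqrt(math.pi)
    grids = np.meshgrid(*([z1] * dim), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    W = np.prod(np.column_stack(
        [g.ravel() for g in np.meshgrid(*([w1] * dim), indexing="ij")]), axis=1)
    return Z, W


def _logistic_logprob(eta: np.ndarray, event: bool) -> np.ndarray:
    """log P(dropout) or log P(no dropout) for logit eta, numerically safe."""
    eta = np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)
    # log sigma(eta) = -log(1+exp(-eta))
    return -np.log1p(np.exp(-eta)) if event else -np.log1p(np.exp(eta))


def _multinomial_logprob(eta0: np.ndarray, eta1: np.ndarray,
                         category: int) -> np.ndarray:
    eta0 = np.clip(eta0, -_LOGIT_CLIP, _LOGIT_CLIP)
    eta1 = np.clip(eta1, -_LOGIT_CLIP, _LOGIT_CLIP)
    lse = np.logaddexp(0.0, np.logaddexp(eta0, eta1))
    if category == 0:
        return eta0 - lse
    if category == 1:
        return eta1 - lse
    return -lse


# ---------------------------------------------------------------------------
# per-pattern selection structure (shared with the Wu-Carroll module)
# ---------------------------------------------------------------------------

@dataclass
class SelStructure:
    """At-risk waves and indicator categories implied by one missing pattern."""

    at_risk: list[int]        # waves t (1..4) contributing a selection term
    category: list[int]       # indicator category at each at-risk wave
    miss: np.ndarray          # wave indices to integrate over (may be empty)


def build_sel_structure(mask_row: np.ndarray, coding: str) -> SelStructure:
    d = dropout_wave(mask_row)
    last = d if d is not None else N_WAVES - 1
    at_risk = list(range(1, last + 1))
    category = []
    for t in at_risk:
        if d is not None and t == d:
            category.append(1)
        elif coding == "survival":
            category.append(0)
        else:
            category.append(2 if mask_row[t] else 0)
    miss = np.array([t for t in range(1, last + 1) if not mask_row[t]],
                    dtype=int)
    return SelStructure(at_risk=at_risk, category=category, miss=miss)


# ---------------------------------------------------------------------------
# layout and likelihood
# ---------------------------------------------------------------------------

class DKLayout:
    """Growth-layout prefix plus selection parameters."""

    def __init__(self, spec: GrowthSpec, coding: str):
        if coding not in ("survival", "multinomial"):
            raise ValueError(f"unknown indicator coding scheme: {coding!r}")
        self.coding = coding
        self.growth = GrowthLayout(spec)
        self.spec = spec
        self.n_alpha = self.growth.n_alpha
        self.n_b = self.growth.n_b
        self.n_chol = self.growth.n_chol
        ncat = 1 if coding == "survival" else 2
        self.ncat = ncat
        sel_names = []
        cats = [""] if ncat == 1 else [",intermittent", ",dropout"]
        for t in range(1, N_WAVES):
            for c in cats:
                sel_names.append(f"sel_tau[t{t}{c}]")
        for c in cats:
            sel_names.append(f"sel_beta_prev[{c.lstrip(',') or 'dropout'}]")
        for c in cats:
            sel_names.append(f"sel_beta_curr[{c.lstrip(',') or 'dropout'}]")
        self.names = self.growth.names + sel_names
        self.n_growth = self.growth.n_params

    @property
    def n_params(self) -> int:
        return len(self.names)

    def unpack_sel(self, theta: np.ndarray) -> SelectionParams:
        s = theta[self.n_growth:]
        k = self.ncat
        tau = s[:4 * k].reshape(4, k)
        bp = s[4 * k:5 * k]
        bc = s[5 * k:6 * k]
        if k == 1:
            tau, bp, bc = tau[:, 0], bp[0], bc[0]
        return SelectionParams(coding=self.coding, tau=tau,
                               beta_prev=np.atleast_1d(bp),
                               beta_curr=np.atleast_1d(bc))

    def natural_names(self):
        return self.names  # selection parameters already natural (log-odds)

    def natural_values(self, theta):
        return np.concatenate([self.growth.natural_values(theta[:self.n_growth]),
                               theta[self.n_growth:]])

    # natural names differ from theta names for the growth prefix
    def natural_names_full(self):
        return self.growth.natural_names() + self.names[self.n_growth:]


class DKModel:
    """Precomputed pattern structure + fused Gaussian/selection evaluator."""

    def __init__(self, dataset: LongitudinalDataset, spec: GrowthSpec,
                 coding: str, nodes: int = 15):
        self.layout = DKLayout(spec, coding)
        self.pdata = PatternData(dataset, spec)
        self.coding = coding
        self.nodes = nodes
        self.n = dataset.n
        self.lam = spec.loadings
        self.blocks = []
        for blk in self.pdata.blocks:
            st = build_sel_structure(dataset.mask[blk.rows[0]], coding)
            o = blk.obs
            m = st.miss
            ypos = {int(t): j for j, t in enumerate(o)}
            mpos = {int(t): j for j, t in enumerate(m)}
            grid = gauss_hermite_grid(len(m), nodes) if len(m) else None
            self.blocks.append((blk, st, ypos, mpos,
                                np.ix_(o, o), np.ix_(m, o), np.ix_(m, m), grid))

    def casewise(self, theta: np.ndarray) -> np.ndarray:
        layout = self.layout
        params = layout.growth.unpack(theta[:layout.n_growth])
        sel = layout.unpack_sel(theta)
        lam = self.lam
        sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
        k = layout.ncat
        out = np.empty(self.n)

        for blk, st, ypos, mpos, ix_oo, ix_mo, ix_mm, grid in self.blocks:
            n_p = len(blk.rows)
            o = blk.obs
            ko = len(o)
            try:
                cf = linalg.cho_factor(sigma[ix_oo], lower=True)
            except linalg.LinAlgError:
                out[:] = -1e10
                return out
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            eta_f = params.alpha[None, :] + blk.X @ params.B.T
            mu = eta_f @ lam.T                       # (n, 5) full implied mean
            resid_o = blk.Y - mu[:, o]
            z = linalg.cho_solve(cf, resid_o.T)
            quad = np.einsum("ij,ji->i", resid_o, z)
            ll = -0.5 * (ko * math.log(2 * math.pi) + logdet + quad)

            m = st.miss
            if len(m):
                W = linalg.cho_solve(cf, sigma[ix_mo].T).T   # Smo @ Soo^-1
                C = sigma[ix_mm] - W @ sigma[ix_mo].T
                C = 0.5 * (C + C.T)
                Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(m)))
                cmean = mu[:, m] + resid_o @ W.T             # (n, |m|)
                Z, Wq = grid
                ynodes = cmean[:, None, :] + (Z @ Lc.T)[None, :, :]
                logg = np.zeros((n_p, Z.shape[0]))
            else:
                logg = None

            def val(t):
                """Outcome at wave t: (n,) if observed, (n, K) if integrated."""
                if t in ypos:
                    return blk.Y[:, ypos[t]]
                return ynodes[:, :, mpos[t]]

            direct = np.zeros(n_p)
            for t, cat in zip(st.at_risk, st.category):
                yc, yp = val(t), val(t - 1)
                integ = (t in mpos) or ((t - 1) in mpos)
                if integ:
                    yc = yc[:, None] if yc.ndim == 1 else yc
                    yp = yp[:, None] if yp.ndim == 1 else yp
                if k == 1:
                    eta = sel.tau[t - 1] + sel.beta_prev[0] * yp \
                        + sel.beta_curr[0] * yc
                    lp = _logistic_logprob(eta, event=cat == 1)
                else:
                    eta0 = sel.tau[t - 1, 0] + sel.beta_prev[0] * yp \
                        + sel.beta_curr[0] * yc
                    eta1 = sel.tau[t - 1, 1] + sel.beta_prev[1] * yp \
                        + sel.beta_curr[1] * yc
                    lp = _multinomial_logprob(eta0, eta1, cat)
                if integ:
                    logg += lp
                else:
                    direct += lp
            ll += direct
            if logg is not None:
                E = np.exp(logg) @ Wq
                ll += np.log(np.maximum(E, 1e-300))
            out[blk.rows] = ll
        return out


    # -- analytic scores ---------------------------------------------------
    def _cov_derivs(self, theta):
        """(theta index, dSigma/dtheta) for the covariance-side growth thetas."""
        gl = self.layout.growth
        lam = self.lam
        nf = gl.spec.n_factors
        a0, b0, c0 = gl.n_alpha, gl.n_b, gl.n_chol
        r = len(gl.free_factors)
        L = np.zeros((r, r))
        L[gl._tri] = theta[a0 + b0:a0 + b0 + c0]
        fi = gl.free_idx
        out = []
        for e, (ia, ib) in enumerate(zip(*gl._tri)):
            dpsi_free = np.zeros((r, r))
            dpsi_free[ia, :] += L[:, ib]
            dpsi_free[:, ia] += L[:, ib]
            dpsi = np.zeros((nf, nf))
            dpsi[np.ix_(fi, fi)] = dpsi_free
            out.append((a0 + b0 + e, lam @ dpsi @ lam.T))
        params = gl.unpack(theta[:gl.n_params])
        for t in range(N_WAVES):
            dS = np.zeros((N_WAVES, N_WAVES))
            dS[t, t] = params.eps[t]
            out.append((a0 + b0 + c0 + t, dS))
        return out

    def scores(self, theta: np.ndarray) -> np.ndarray:
        """(N, p) analytic per-case scores of the joint log-likelihood.

        The Gaussian part reuses the FIML score algebra; the selection part
        differentiates the quadrature approximation itself: node positions
        y = c_i + L_c z move with the conditional mean and Cholesky factor,
        so the chain rule runs through dW, dC and d(chol C).
        """
        layout = self.layout
        gl = layout.growth
        ng = layout.n_growth
        S = np.zeros((self.n, layout.n_params))
        gtheta = theta[:ng]
        from .lgm_core import _gaussian_scores
        S[:, :ng] = _gaussian_scores(gtheta, gl, self.pdata)
        params = gl.unpack(gtheta)
        sel = layout.unpack_sel(theta)
        lam = self.lam
        sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
        k = layout.ncat
        nf, q = gl.spec.n_factors, len(gl.spec.regressors)
        a0 = gl.n_alpha
        cov_derivs = self._cov_derivs(theta)

        def tau_idx(t, c=0):
            return ng + (t - 1) * k + c

        def bp_idx(c=0):
            return ng + 4 * k + c

        def bc_idx(c=0):
            return ng + 5 * k + c

        for blk, st, ypos, mpos, ix_oo, ix_mo, ix_mm, grid in self.blocks:
            rows = blk.rows
            n_p = len(rows)
            o = blk.obs
            m = st.miss
            cf = linalg.cho_factor(sigma[ix_oo], lower=True)
            eta_f = params.alpha[None, :] + blk.X @ params.B.T
            mu = eta_f @ lam.T
            resid_o = blk.Y - mu[:, o]
            if len(m):
                W = linalg.cho_solve(cf, sigma[ix_mo].T).T
                C = sigma[ix_mm] - W @ sigma[ix_mo].T
                C = 0.5 * (C + C.T)
                Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(m)))
                cmean = mu[:, m] + resid_o @ W.T
                Z, Wq = grid
                K = Z.shape[0]
                ynodes = cmean[:, None, :] + (Z @ Lc.T)[None, :, :]
                logg = np.zeros((n_p, K))
                G = np.zeros((n_p, K, len(m)))     # d s / d y_m at each node
            else:
                logg = G = None

            def val(t):
                if t in ypos:
                    return blk.Y[:, ypos[t]]
                return ynodes[:, :, mpos[t]]

            int_terms = []
            for t, cat in zip(st.at_risk, st.category):
                yc, yp = val(t), val(t - 1)
                integ = (t in mpos) or ((t - 1) in mpos)
                if integ:
                    yc = np.broadcast_to(yc[:, None], (n_p, K)) if yc.ndim == 1 else yc
                    yp = np.broadcast_to(yp[:, None], (n_p, K)) if yp.ndim == 1 else yp
                if k == 1:
                    eta = sel.tau[t - 1] + sel.beta_prev[0] * yp \
                        + sel.beta_curr[0] * yc
                    lp = _logistic_logprob(eta, event=cat == 1)
                    sig = 1.0 / (1.0 + np.exp(-np.clip(eta, -_LOGIT_CLIP,
                                                       _LOGIT_CLIP)))
                    dlp = ((1.0 - sig) if cat == 1 else -sig,)
                else:
                    eta0 = sel.tau[t - 1, 0] + sel.beta_prev[0] * yp \
                        + sel.beta_curr[0] * yc
                    eta1 = sel.tau[t - 1, 1] + sel.beta_prev[1] * yp \
                        + sel.beta_curr[1] * yc
                    lp = _multinomial_logprob(eta0, eta1, cat)
                    lse = np.logaddexp(0.0, np.logaddexp(
                        np.clip(eta0, -_LOGIT_CLIP, _LOGIT_CLIP),
                        np.clip(eta1, -_LOGIT_CLIP, _LOGIT_CLIP)))
                    P0 = np.exp(np.clip(eta0, -_LOGIT_CLIP, _LOGIT_CLIP) - lse)
                    P1 = np.exp(np.clip(eta1, -_LOGIT_CLIP, _LOGIT_CLIP) - lse)
                    dlp = ((1.0 if cat == 0 else 0.0) - P0,
                           (1.0 if cat == 1 else 0.0) - P1)
                if not integ:
                    for c, d in enumerate(dlp):
                        S[rows, tau_idx(t, c)] += d
                        S[rows, bp_idx(c)] += d * yp
                        S[rows, bc_idx(c)] += d * yc
                else:
                    logg += lp
                    int_terms.append((t, dlp, yc, yp))
                    for c, d in enumerate(dlp):
                        bcs = sel.beta_curr[c]
                        bps = sel.beta_prev[c]
                        if t in mpos:
                            G[:, :, mpos[t]] += d * bcs
                        if (t - 1) in mpos:
                            G[:, :, mpos[t - 1]] += d * bps

            if logg is None:
                continue
            g = np.exp(logg) * Wq[None, :]
            E = g.sum(axis=1)
            pnode = g / np.maximum(E, 1e-300)[:, None]   # (n, K)
            # selection-parameter scores through the integral
            for t, dlp, yc, yp in int_terms:
                for c, d in enumerate(dlp):
                    wd = pnode * d
                    S[rows, tau_idx(t, c)] += wd.sum(axis=1)
                    S[rows, bp_idx(c)] += (wd * yp).sum(axis=1)
                    S[rows, bc_idx(c)] += (wd * yc).sum(axis=1)
            # growth-parameter scores through the moving nodes
            Gbar = np.einsum("nk,nkm->nm", pnode, G)
            Nmat = np.einsum("nk,nkm,kb->nmb", pnode, G, Z)
            lam_m, lam_o = lam[m], lam[o]
            for f in range(nf):
                const = lam_m[:, f] - W @ lam_o[:, f]
                base = Gbar @ const
                S[rows, f] += base
                for qq in range(q):
                    S[rows, a0 + f * q + qq] += base * blk.X[:, qq]
            Soo_inv = linalg.cho_solve(cf, np.eye(len(o)))
            Smo = sigma[ix_mo]
            for jidx, dSig in cov_derivs:
                dSoo = dSig[ix_oo]
                dSmo = dSig[ix_mo]
                dW = (dSmo - W @ dSoo) @ Soo_inv
                dC = dSig[ix_mm] - dW @ Smo.T - W @ dSmo.T
                dC = 0.5 * (dC + dC.T)
                A = linalg.solve_triangular(Lc, dC, lower=True)
                A = linalg.solve_triangular(Lc, A.T, lower=True).T
                phi = np.tril(A)
                np.fill_diagonal(phi, 0.5 * np.diag(A))
                dLc = Lc @ phi
                dcmean = resid_o @ dW.T
                S[rows, jidx] += (np.einsum("nm,nm->n", Gbar, dcmean)
                                  + np.einsum("nmb,mb->n", Nmat, dLc))
        return S


def dk_loglik(params, sel: SelectionParams, spec: GrowthSpec,
              dataset: LongitudinalDataset, nodes: int = 15) -> float:
    """Joint selection-model log-likelihood at given growth + selection params."""
    model = DKModel(dataset, spec, sel.coding, nodes=nodes)
    layout = model.layout
    gtheta = layout.growth.pack(params)
    k = layout.ncat
    tau = np.asarray(sel.tau, dtype=float).reshape(4, k)
    stheta = np.concatenate([tau.ravel(), np.atleast_1d(sel.beta_prev),
                             np.atleast_1d(sel.beta_curr)])
    return float(model.casewise(np.concatenate([gtheta, stheta])).sum())


def _sel_start(dataset: LongitudinalDataset, coding: str,
               indicators) -> np.ndarray:
    """Empirical per-wave category-frequency logits; slopes start at zero."""
    vals = indicators.values
    k = 1 if coding == "survival" else 2
    tau = np.zeros((4, k))
    for t in range(4):
        col = vals[:, t]
        at_risk = col >= 0
        n_risk = max(at_risk.sum(), 1)
        if coding == "survival":
            h = np.clip((col == 1).sum() / n_risk, 1e-3, 1 - 1e-3)
            tau[t, 0] = math.log(h / (1 - h))
        else:
            n2 = max((col == 2).sum(), 1)
            for c in (0, 1):
                frac = np.clip((col == c).sum() / n2, 1e-3, 1e3)
                tau[t, c] = math.log(frac)
    return np.concatenate([tau.ravel(), np.zeros(2 * k)])


def fit_dk(dataset: LongitudinalDataset, spec: GrowthSpec | None = None,
           coding: str = "survival", nodes: int = 15,
           compute_se: bool = True, se_for_contrasts: str = "sandwich",
           maxiter: int = 1000, polish: bool = False,
           fix_selection_slopes: bool = False,
           ftol: float = 1e-11, gtol: float = 1e-7) -> FitResult:
    """Jointly fit growth and selection parameters by maximum likelihood.

    Staged: the MAR growth fit provides starting values, selection intercepts
    start at empirical hazard logits, then everything is maximised jointly.
    ``fix_selection_slopes`` keeps beta_prev = beta_curr = 0 (the likelihood
    then separates and the growth part reproduces the MAR fit).
    """
    from .data_model import code_missing_indicators

    spec = spec or GrowthSpec.standard()
    model = DKModel(dataset, spec, coding, nodes=nodes)
    layout = model.layout

    mar = fit_mar(dataset, spec, compute_se=False, polish=False)
    ind = code_missing_indicators(dataset, coding)
    theta0 = np.concatenate([mar.theta, _sel_start(dataset, coding, ind)])

    def grad(th):
        return model.scores(th).sum(axis=0)

    bounds = layout.growth.bounds()
    k = layout.ncat
    bounds += [(-20.0, 20.0)] * (4 * k) + [(-10.0, 10.0)] * (2 * k)
    fixed = {}
    if fix_selection_slopes:
        for i in range(layout.n_growth + 4 * k, layout.n_params):
            fixed[i] = 0.0

    try:
        theta, conv = _maximise(model.casewise, theta0, model.n, bounds=bounds,
                                fixed=fixed, maxiter=maxiter, polish=polish,
                                grad=grad, ftol=ftol, gtol=gtol)
    except NonConvergenceError:
        # staged restart: optimise selection with growth frozen, then release
        frozen = dict(fixed)
        for i in range(layout.n_growth):
            frozen[i] = theta0[i]
        theta_s, _ = _maximise(model.casewise, theta0, model.n, bounds=bounds,
                               fixed=frozen, maxiter=maxiter, polish=False,
                               grad=grad, ftol=ftol, gtol=gtol)
        theta, conv = _maximise(model.casewise, theta_s, model.n, bounds=bounds,
                                fixed=fixed, maxiter=maxiter, polish=polish,
                                grad=grad, ftol=ftol, gtol=gtol)

    ll = float(model.casewise(theta).sum())
    cov_sw = cov_fo = None
    if compute_se:
        cov_sw, cov_fo, min_eig = _information_covariances(
            model.casewise, theta, model.n, fixed, scores=model.scores)
        conv.hessian_min_eig = min_eig

    sel = layout.unpack_sel(theta)
    fit = FitResult(model=f"dk_{coding}", spec=spec, layout=layout,
                    theta=theta, params=layout.growth.unpack(theta[:layout.n_growth]),
                    loglik=ll, n=model.n, n_params=layout.n_params - len(fixed),
                    convergence=conv, cov_sandwich=cov_sw, cov_first_order=cov_fo)
    fit.estimates = _dk_natural_table(layout, theta, cov_sw, cov_fo)
    if "arm" in spec.regressors:
        fit.contrasts = group_contrasts(fit, se=se_for_contrasts)
    fit.extra["selection"] = sel
    fit.extra["selection_odds"] = selection_odds_table(layout, theta, cov_sw)
    return fit


def _dk_natural_table(layout: DKLayout, theta, cov_sw, cov_fo) -> pd.DataFrame:
    return _natural_table(
        layout, theta, cov_sw, cov_fo,
        natural_fn=layout.natural_values).set_axis(
            layout.natural_names_full(), axis=0)


def selection_odds_table(layout, theta, cov,
                         z: float = 1.959963984540054) -> pd.DataFrame:
    """Odds ratios with delta-method 95% CIs for the slope parameters."""
    rows = []
    for i, name in enumerate(layout.names):
        if "beta" not in name and "gamma" not in name:
            continue
        est = theta[i]
        se = math.sqrt(max(cov[i, i], 0.0)) if cov is not None else np.nan
        rows.append({"parameter": name, "log_odds": est, "se": se,
                     "or": math.exp(est),
                     "or_ci_low": math.exp(est - z * se) if np.isfinite(se) else np.nan,
                     "or_ci_high": math.exp(est + z * se) if np.isfinite(se) else np.nan})
    return pd.DataFrame(rows).set_index("parameter")
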