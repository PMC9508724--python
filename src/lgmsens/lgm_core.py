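"""Latent growth models with fixed time loadings, estimated by full-information
maximum likelihood (FIML) under a missing-at-random assumption.

Model
-----
For participant i with regressor vector x_i (the trial arm, optionally baseline
covariates), the latent growth factors are

    eta_i = alpha + B x_i + zeta_i,   zeta_i ~ N(0, Psi),

and the five repeated outcomes are

    y_i = Lambda eta_i + e_i,         e_i ~ N(0, diag(eps)),

with Lambda the fixed loading matrix: the intercept column is all ones, the
linear column is (0, 0.1, 0.2, 0.4, 1.2) (one loading unit = 30 months) and the
quadratic column is its elementwise square. The marginal moments are

    mu_i = Lambda (alpha + B x_i),    Sigma = Lambda Psi Lambda' + diag(eps).

FIML sums, over participants, the log multivariate-normal density of the
observed sub-vector under the corresponding sub-mean/sub-covariance; this is
the maximum-likelihood estimator that is consistent under MAR.

Internally Psi is optimised on the Cholesky scale (PSD by construction) and
residual variances on the log scale; everything is reported on the natural
scale. Two standard-error flavours are produced: the sandwich estimator
A^{-1} B A^{-1} (robust) and the first-order inverse outer-product-of-scores
estimator (the "MLF"-style fallback used when observed and expected
information disagree).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data_model import LongitudinalDataset, N_WAVES

FACTOR_ORDER: tuple[str, ...] = ("intercept", "linear", "quadratic")
LINEAR_LOADINGS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 1.2)

_LL_PENALTY = -1e10  # per-case log-likelihood for an infeasible parameter point


class NonConvergenceError(RuntimeError):
    """Optimiser failed; carries the best parameter point seen so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class SingularModelError(RuntimeError):
    """An observed sub-covariance matrix is singular for some pattern."""


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSpec:
    """Growth-factor set, fixed loadings, regressors, variance constraints.

    ``factors`` is an ordered subset of ("intercept", "linear", "quadratic");
    ``regressors`` names the factor-mean predictors ("arm" and/or covariate
    columns); factors listed in ``fixed_zero_variance`` have their whole Psi
    row fixed at zero (e.g. the quadratic factor in the covariate-adjusted
    model, which prevents a non-positive-definite factor covariance matrix).
    """

    factors: tuple[str, ...]
    regressors: tuple[str, ...] = ("arm",)
    fixed_zero_variance: tuple[str, ...] = ()

    def __post_init__(self):
        for f in self.factors:
            if f not in FACTOR_ORDER:
                raise ValueError(f"unknown factor {f!r}")
        if list(self.factors) != [f for f in FACTOR_ORDER if f in self.factors]:
            raise ValueError("factors must follow intercept < linear < quadratic")
        for f in self.fixed_zero_variance:
            if f not in self.factors:
                raise ValueError(f"{f!r} in fixed_zero_variance but not a factor")

    @classmethod
    def standard(cls, factors: str = "ilq", regressors=("arm",),
                 fixed_zero_variance=()) -> "GrowthSpec":
        """Shorthand constructor; ``factors`` is "i", "il" or "ilq"."""
        names = {"i": ("intercept",), "il": ("intercept", "linear"),
                 "ilq": ("intercept", "linear", "quadratic")}[factors]
        return cls(factors=names, regressors=tuple(regressors),
                   fixed_zero_variance=tuple(fixed_zero_variance))

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def loadings(self) -> np.ndarray:
        """(5, n_factors) fixed loading matrix."""
        lam = np.asarray(LINEAR_LOADINGS)
        cols = {"intercept": np.ones(N_WAVES), "linear": lam, "quadratic": lam ** 2}
        return np.column_stack([cols[f] for f in self.factors])

    @property
    def free_cov_factors(self) -> tuple[str, ...]:
        return tuple(f for f in self.factors if f not in self.fixed_zero_variance)


@dataclass
class LGMParams:
    """Natural-scale growth parameters."""

    alpha: np.ndarray          # (nf,) factor intercepts (control-arm values)
    B: np.ndarray              # (nf, q) factor-on-regressor coefficients
    Psi: np.ndarray            # (nf, nf) factor covariance, PSD
    eps: np.ndarray            # (5,) residual variances, >= 0


def implied_moments(params: LGMParams, spec: GrowthSpec,
                    x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (5,) and covariance (5, 5) for regressor vector x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lam = spec.loadings
    eigmin = np.linalg.eigvalsh(params.Psi).min() if params.Psi.size else 0.0
    if eigmin < -1e-10:
        raise ValueError("Psi is not positive semi-definite")
    eta_mean = params.alpha + (params.B @ x if params.B.size else 0.0)
    mu = lam @ eta_mean
    sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
    return mu, sigma


# ---------------------------------------------------------------------------
# parameter layout (theta <-> LGMParams)
# ---------------------------------------------------------------------------

class GrowthLayout:
    """Maps the unconstrained optimisation vector theta onto LGMParams.

    theta = [alpha, vec(B), lower-tri Cholesky of the free Psi block,
             log residual variances]. Factors whose Psi row is fixed
    (``fixed_zero_variance`` or pattern-mixture restrictions via
    ``psi_fixed_rows``) are excluded from the Cholesky block and assembled
    back into Psi as given.
    """

    def __init__(self, spec: GrowthSpec,
                 psi_fixed_rows: dict[str, np.ndarray] | None = None):
        self.spec = spec
        nf, q = spec.n_factors, len(spec.regressors)
        fixed = dict(psi_fixed_rows or {})
        for f in spec.fixed_zero_variance:
            fixed.setdefault(f, np.zeros(nf))
        self.psi_fixed_rows = fixed
        self.free_factors = [f for f in spec.factors if f not in fixed]
        self.free_idx = [spec.factors.index(f) for f in self.free_factors]
        r = len(self.free_factors)
        self._tri = np.tril_indices(r)

        names: list[str] = [f"alpha[{f}]" for f in spec.factors]
        names += [f"B[{f},{x}]" for f in spec.factors for x in spec.regressors]
        names += [f"psi_chol[{self.free_factors[i]},{self.free_factors[j]}]"
                  for i, j in zip(*self._tri)]
        names += [f"log_eps[t{t}]" for t in range(N_WAVES)]
        self.names = names
        self.n_alpha, self.n_b, self.n_chol = nf, nf * q, r * (r + 1) // 2

    @property
    def n_params(self) -> int:
        return len(self.names)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        """Box bounds: free except log residual variances, which are kept in
        [-12, 12] (a zero-variance Heywood boundary without numerical
        underflow)."""
        out: list[tuple[float | None, float | None]] = \
            [(None, None)] * (self.n_alpha + self.n_b + self.n_chol)
        out += [(-12.0, 12.0)] * N_WAVES
        return out

    def unpack(self, theta: np.ndarray) -> LGMParams:
        spec = self.spec
        nf, q = spec.n_factors, len(spec.regressors)
        a, b, c = self.n_alpha, self.n_b, self.n_chol
        alpha = theta[:a]
        B = theta[a:a + b].reshape(nf, q) if q else np.zeros((nf, 0))
        r = len(self.free_factors)
        L = np.zeros((r, r))
        L[self._tri] = theta[a + b:a + b + c]
        psi = np.zeros((nf, nf))
        block = L @ L.T
        for ii, fi in enumerate(self.free_idx):
            for jj, fj in enumerate(self.free_idx):
                psi[fi, fj] = block[ii, jj]
        for f, row in self.psi_fixed_rows.items():
            i = spec.factors.index(f)
            psi[i, :] = row
            psi[:, i] = row
        eps = np.exp(theta[a + b + c:])
        return LGMParams(alpha=alpha, B=B, Psi=psi, eps=eps)

    def pack(self, params: LGMParams) -> np.ndarray:
        a_part = np.asarray(params.alpha, dtype=float)
        b_part = np.asarray(params.B, dtype=float).ravel()
        sub = params.Psi[np.ix_(self.free_idx, self.free_idx)]
        r = len(self.free_idx)
        if r:
            L = np.linalg.cholesky(sub + 1e-12 * np.eye(r))
            c_part = L[self._tri]
        else:
            c_part = np.empty(0)
        e_part = np.log(np.maximum(params.eps, 1e-12))
        return np.concatenate([a_part, b_part, c_part, e_part])

    # natural-scale reporting -------------------------------------------
    def natural_names(self) -> list[str]:
        spec = self.spec
        names = [f"alpha[{f}]" for f in spec.factors]
        names += [f"B[{f},{x}]" for f in spec.factors for x in spec.regressors]
        ff = self.free_factors
        names += [f"psi[{ff[j]},{ff[i]}]" for i in range(len(ff))
                  for j in range(i + 1)]
        names += [f"eps[t{t}]" for t in range(N_WAVES)]
        return names

    def natural_values(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        ff_idx = self.free_idx
        psi_entries = [p.Psi[ff_idx[j], ff_idx[i]]
                       for i in range(len(ff_idx)) for j in range(i + 1)]
        return np.concatenate([p.alpha, p.B.ravel(), psi_entries, p.eps])


def design_matrix(dataset: LongitudinalDataset, spec: GrowthSpec) -> np.ndarray:
    """(N, q) regressor matrix in the order of ``spec.regressors``."""
    cols = []
    for name in spec.regressors:
        if name == "arm":
            cols.append(dataset.arm.astype(float))
        else:
            if dataset.covariates is None or name not in dataset.covariates:
                raise ValueError(f"regressor {name!r} not found in covariates")
            cols.append(dataset.covariates[name].to_numpy(dtype=float))
    if not cols:
        return np.zeros((dataset.n, 0))
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("regressors contain missing values")
    return X


# ---------------------------------------------------------------------------
# pattern-grouped data and the FIML likelihood
# ---------------------------------------------------------------------------

@dataclass
class _PatternBlock:
    key: str
    obs: np.ndarray        # observed wave indices
    rows: np.ndarray       # participant row indices
    Y: np.ndarray          # (n_p, k) observed outcomes
    X: np.ndarray          # (n_p, q) regressors


class PatternData:
    """Dataset grouped by missing-data pattern, with regressors attached."""

    def __init__(self, dataset: LongitudinalDataset, spec: GrowthSpec):
        self.dataset = dataset
        self.spec = spec
        X = design_matrix(dataset, spec)
        keys = dataset.pattern_keys()
        self.n = dataset.n
        self.blocks: list[_PatternBlock] = []
        for key in sorted(set(keys)):
            rows = np.flatnonzero(keys == key)
            obs = np.flatnonzero(dataset.mask[rows[0]])
            self.blocks.append(_PatternBlock(
                key=key, obs=obs, rows=rows,
                Y=dataset.outcome[np.ix_(rows, obs)], X=X[rows]))


def _casewise_gaussian(theta: np.ndarray, layout: GrowthLayout,
                       pdata: PatternData, strict: bool = False) -> np.ndarray:
    """Per-participant FIML log-likelihood contributions (N,)."""
    spec = layout.spec
    params = layout.unpack(theta)
    lam = spec.loadings
    sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
    out = np.empty(pdata.n)
    for blk in pdata.blocks:
        o = blk.obs
        k = len(o)
        sub = sigma[np.ix_(o, o)]
        try:
            cf = linalg.cho_factor(sub, lower=True)
        except linalg.LinAlgError:
            if strict:
                raise SingularModelError(
                    f"singular observed covariance for pattern {blk.key}")
            out[blk.rows] = _LL_PENALTY
            continue
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        eta = params.alpha[None, :] + blk.X @ params.B.T
        mu = eta @ lam[o].T
        resid = blk.Y - mu
        z = linalg.cho_solve(cf, resid.T)
        quad = np.einsum("ij,ji->i", resid, z)
        out[blk.rows] = -0.5 * (k * math.log(2 * math.pi) + logdet + quad)
    return out


def _gaussian_scores(theta: np.ndarray, layout: GrowthLayout,
                     pdata: PatternData) -> np.ndarray:
    """(N, p) analytic per-case score matrix of the FIML log-likelihood.

    Columns follow ``layout.names``. Uses the chain rule through the implied
    moments: with z_i = S_o^{-1} r_i and a_i = Lambda_o' z_i,
    d ll_i/d alpha = a_i, d ll_i/d B = a_i x_i', and the covariance-side score
    is built from 0.5 (a_i a_i' - Lambda_o' S_o^{-1} Lambda_o).
    """
    spec = layout.spec
    params = layout.unpack(theta)
    lam = spec.loadings
    nf, q = spec.n_factors, len(spec.regressors)
    sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
    r_free = len(layout.free_factors)
    L = np.zeros((r_free, r_free))
    a0, b0, c0 = layout.n_alpha, layout.n_b, layout.n_chol
    L[layout._tri] = theta[a0 + b0:a0 + b0 + c0]
    S = np.zeros((pdata.n, layout.n_params))
    for blk in pdata.blocks:
        o = blk.obs
        sub = sigma[np.ix_(o, o)]
        cf = linalg.cho_factor(sub, lower=True)
        lam_o = lam[o]
        eta = params.alpha[None, :] + blk.X @ params.B.T
        resid = blk.Y - eta @ lam_o.T
        z = linalg.cho_solve(cf, resid.T).T            # (n, k)
        a = z @ lam_o                                   # (n, nf)
        S[blk.rows, :a0] = a
        if q:
            S[blk.rows, a0:a0 + b0] = np.einsum(
                "nf,nq->nfq", a, blk.X).reshape(len(blk.rows), -1)
        sub_inv = linalg.cho_solve(cf, np.eye(len(o)))
        P = lam_o.T @ sub_inv @ lam_o                   # (nf, nf)
        if r_free:
            fi = layout.free_idx
            af = a[:, fi]                               # (n, r)
            PL = P[np.ix_(fi, fi)] @ L                  # (r, r)
            aL = af @ L                                 # (n, r)
            grad_L = np.einsum("ni,nj->nij", af, aL) - PL[None, :, :]
            S[blk.rows, a0 + b0:a0 + b0 + c0] = \
                grad_L[:, layout._tri[0], layout._tri[1]]
        # residual variances (log scale): only observed waves contribute
        diag_inv = np.diag(sub_inv)
        g_eps = 0.5 * (z ** 2 - diag_inv[None, :]) * params.eps[o][None, :]
        cols = a0 + b0 + c0 + o
        S[np.ix_(blk.rows, cols)] = g_eps
    return S


def fiml_loglik(params: LGMParams, spec: GrowthSpec,
                dataset: LongitudinalDataset) -> float:
    """FIML log-likelihood of ``params`` on ``dataset`` (observed cells only)."""
    layout = GrowthLayout(spec)
    pdata = PatternData(dataset, spec)
    theta = layout.pack(params)
    return float(_casewise_gaussian(theta, layout, pdata, strict=True).sum())


# ---------------------------------------------------------------------------
# generic optimiser machinery (shared with the MNAR modules)
# ---------------------------------------------------------------------------

def _finite_diff_scores(casewise, theta: np.ndarray, n: int) -> np.ndarray:
    """(N, p) per-case score matrix by central differences."""
    p = len(theta)
    S = np.empty((n, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        S[:, j] = (casewise(tp) - casewise(tm)) / (2 * h)
    return S


def _finite_diff_hessian(total, theta: np.ndarray) -> np.ndarray:
    """(p, p) Hessian of a scalar function by central differences."""
    p = len(theta)
    H = np.empty((p, p))
    hs = np.array([1e-4 * max(1.0, abs(t)) for t in theta])
    f0 = total(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            if i == j:
                fpp = total(theta + ei)
                fmm = total(theta - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / hs[i] ** 2
            else:
                fpp = total(theta + ei + ej)
                fpm = total(theta + ei - ej)
                fmp = total(theta - ei + ej)
                fmm = total(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _finite_diff_jacobian(vecfun, x: np.ndarray) -> np.ndarray:
    """Jacobian of a vector-valued function by central differences."""
    p = len(x)
    f0 = np.asarray(vecfun(x))
    J = np.empty((len(f0), p))
    for j in range(p):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(vecfun(xp)) - np.asarray(vecfun(xm))) / (2 * h)
    return J


@dataclass
class Convergence:
    converged: bool
    iterations: int
    grad_norm: float
    message: str
    hessian_min_eig: float | None = None


def _maximise(casewise, theta0: np.ndarray, n: int,
              bounds=None, fixed: dict[int, float] | None = None,
              maxiter: int = 1000, polish: bool = True, grad=None,
              ftol: float = 1e-13, gtol: float = 1e-9):
    """Maximise sum(casewise(theta)) over the free entries of theta.

    Works on the mean log-likelihood scale so gradient-norm convergence
    thresholds are sample-size free. ``grad``, when given, returns the
    analytic gradient of the summed log-likelihood; otherwise finite
    differences are used. Returns (theta_hat, Convergence).
    """
    theta0 = np.asarray(theta0, dtype=float)
    fixed = fixed or {}
    free = np.array([i for i in range(len(theta0)) if i not in fixed])

    def expand(free_vec):
        th = theta0.copy()
        th[free] = free_vec
        for i, v in fixed.items():
            th[i] = v
        return th

    def neg_mean(free_vec):
        val = casewise(expand(free_vec)).sum() / n
        if not np.isfinite(val):
            return 1e12
        return -val

    if grad is not None:
        def neg_mean_grad(free_vec):
            th = expand(free_vec)
            val = casewise(th).sum() / n
            if not np.isfinite(val):
                return 1e12, np.zeros(len(free))
            return -val, -grad(th)[free] / n
        fun, jac = neg_mean_grad, True
    else:
        fun, jac = neg_mean, "2-point"

    def num_grad(free_vec):
        return optimize.approx_fprime(free_vec, neg_mean, 1e-7)

    def grad_free(free_vec):
        if grad is not None:
            return -grad(expand(free_vec))[free] / n
        return num_grad(free_vec)

    fb = None
    if bounds is not None:
        fb = [bounds[i] for i in free]
    res = optimize.minimize(
        fun, theta0[free], method="L-BFGS-B", jac=jac, bounds=fb,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol,
                 "maxcor": 25})
    xfree = res.x
    # Newton polish: a few damped steps sharpen the optimum so refits from
    # jittered starts land on the same point to tight tolerance.
    if polish:
        for _ in range(4):
            g = grad_free(xfree)
            if np.linalg.norm(g) < 1e-10:
                break
            H = _finite_diff_jacobian(grad_free, xfree) if grad is not None \
                else _finite_diff_hessian(neg_mean, xfree)
            H = 0.5 * (H + H.T)
            try:
                ev = np.linalg.eigvalsh(H)
                if ev.min() <= 1e-10:
                    break
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            f_cur = neg_mean(xfree)
            lam_ = 1.0
            while lam_ > 1e-4:
                cand = xfree - lam_ * step
                if fb is not None:
                    cand = np.clip(cand, [b[0] if b[0] is not None else -np.inf for b in fb],
                                   [b[1] if b[1] is not None else np.inf for b in fb])
                if neg_mean(cand) <= f_cur:
                    xfree = cand
                    break
                lam_ *= 0.25
            else:
                break
    g = grad_free(xfree)
    gnorm = float(np.linalg.norm(g))
    theta_hat = expand(xfree)
    conv = Convergence(converged=bool(res.success or gnorm < 1e-5),
                       iterations=int(res.nit), grad_norm=gnorm,
                       message=str(res.message))
    if not conv.converged and gnorm > 1e-3:
        raise NonConvergenceError(
            f"optimiser did not converge (|grad|={gnorm:.2e}): {res.message}",
            best=theta_hat)
    return theta_hat, conv


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, two SE flavours, log-likelihood and contrasts for one model."""

    model: str
    spec: GrowthSpec
    layout: GrowthLayout
    theta: np.ndarray
    params: LGMParams
    loglik: float
    n: int
    n_params: int
    convergence: Convergence
    cov_sandwich: np.ndarray | None = None      # theta scale
    cov_first_order: np.ndarray | None = None   # theta scale
    estimates: pd.DataFrame | None = None       # natural scale + SEs
    contrasts: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n)

    def arm_beta(self) -> np.ndarray:
        """(nf,) arm coefficients (zero for factors without the arm regressor)."""
        if "arm" not in self.spec.regressors:
            raise ValueError("model has no arm regressor")
        j = self.spec.regressors.index("arm")
        return self.params.B[:, j]


def _natural_table(layout: GrowthLayout, theta: np.ndarray,
                   cov_sw: np.ndarray | None,
                   cov_fo: np.ndarray | None,
                   extra_names: list[str] | None = None,
                   natural_fn=None) -> pd.DataFrame:
    names = layout.natural_names() + (extra_names or [])
    nat = natural_fn if natural_fn is not None else layout.natural_values
    vals = nat(theta)
    # delta method: covariance of natural params via numeric Jacobian
    df = pd.DataFrame({"estimate": vals}, index=names)
    for label, cov in (("se_sandwich", cov_sw), ("se_first_order", cov_fo)):
        if cov is None:
            df[label] = np.nan
            continue
        p = len(theta)
        J = np.empty((len(vals), p))
        for j in range(p):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            J[:, j] = (nat(tp) - nat(tm)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, cov, J)
        df[label] = np.sqrt(np.maximum(var, 0.0))
    return df


def natural_covariance(layout, theta: np.ndarray, cov: np.ndarray,
                       natural_fn=None) -> np.ndarray:
    """Delta-method covariance of the natural parameters."""
    nat = natural_fn if natural_fn is not None else layout.natural_values
    vals0 = nat(theta)
    p = len(theta)
    J = np.empty((len(vals0), p))
    for j in range(p):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (nat(tp) - nat(tm)) / (2 * h)
    return J @ cov @ J.T


def _start_values(dataset: LongitudinalDataset, spec: GrowthSpec,
                  layout: GrowthLayout) -> np.ndarray:
    """Moment-based starting values (robust at high missingness)."""
    y0 = dataset.outcome[:, 0]
    base_mean, base_var = float(np.mean(y0)), float(np.var(y0))
    lam = np.asarray(LINEAR_LOADINGS)
    slopes = np.full(dataset.n, np.nan)
    for i in range(dataset.n):
        o = np.flatnonzero(dataset.mask[i])
        if len(o) >= 2:
            t = lam[o]
            y = dataset.outcome[i, o]
            slopes[i] = np.polyfit(t, y, 1)[0]
    slope_mean = float(np.nanmean(slopes)) if np.isfinite(slopes).any() else 0.0
    slope_var = float(np.nanvar(slopes)) if np.isfinite(slopes).any() else 0.1

    nf = spec.n_factors
    alpha = np.zeros(nf)
    alpha[0] = base_mean
    if nf >= 2:
        alpha[1] = slope_mean
    B = np.zeros((nf, len(spec.regressors)))
    psi = np.zeros((nf, nf))
    diag_start = {"intercept": max(base_var / 2, 0.05),
                  "linear": max(min(slope_var / 2, 1.0), 0.02),
                  "quadratic": 0.02}
    for i, f in enumerate(spec.factors):
        psi[i, i] = diag_start[f]
    eps = np.full(N_WAVES, max(base_var / 2, 0.05))
    params = LGMParams(alpha=alpha, B=B, Psi=psi, eps=eps)
    theta = layout.pack(params)
    return theta


def fit_mar(dataset: LongitudinalDataset, spec: GrowthSpec | None = None,
            compute_se: bool = True, se_for_contrasts: str = "sandwich",
            theta0: np.ndarray | None = None,
            psi_fixed_rows: dict[str, np.ndarray] | None = None,
            fixed: dict[str, float] | None = None,
            maxiter: int = 1000, polish: bool = True) -> FitResult:
    """Fit the growth model by FIML under MAR.

    ``fixed`` maps theta-scale parameter names (see ``GrowthLayout.names``)
    to fixed values; ``psi_fixed_rows`` fixes whole factor rows of Psi on the
    natural scale (pattern-mixture identifying restrictions).
    """
    spec = spec or GrowthSpec.standard()
    layout = GrowthLayout(spec, psi_fixed_rows=psi_fixed_rows)
    pdata = PatternData(dataset, spec)
    if dataset.n <= layout.n_params:
        raise ValueError("more free parameters than participants")

    def casewise(theta):
        return _casewise_gaussian(theta, layout, pdata)

    def grad(theta):
        return _gaussian_scores(theta, layout, pdata).sum(axis=0)

    theta0 = _start_values(dataset, spec, layout) if theta0 is None else theta0
    theta0 = np.clip(theta0, [b[0] if b[0] is not None else -np.inf
                              for b in layout.bounds()],
                     [b[1] if b[1] is not None else np.inf
                      for b in layout.bounds()])
    fixed_idx = {layout.names.index(k): v for k, v in (fixed or {}).items()}
    theta, conv = _maximise(casewise, theta0, dataset.n, fixed=fixed_idx,
                            bounds=layout.bounds(),
                            maxiter=maxiter, polish=polish, grad=grad)
    ll = float(casewise(theta).sum())
    n_free = layout.n_params - len(fixed_idx)

    cov_sw = cov_fo = None
    if compute_se:
        cov_sw, cov_fo, min_eig = _information_covariances(
            casewise, theta, dataset.n, fixed_idx,
            scores=lambda th: _gaussian_scores(th, layout, pdata))
        conv.hessian_min_eig = min_eig

    fit = FitResult(model="mar", spec=spec, layout=layout, theta=theta,
                    params=layout.unpack(theta), loglik=ll, n=dataset.n,
                    n_params=n_free, convergence=conv,
                    cov_sandwich=cov_sw, cov_first_order=cov_fo)
    fit.estimates = _natural_table(layout, theta, cov_sw, cov_fo)
    if "arm" in spec.regressors:
        fit.contrasts = group_contrasts(fit, se=se_for_contrasts)
    return fit


def _information_covariances(casewise, theta, n, fixed_idx, scores=None):
    """Sandwich and first-order covariance matrices on the free-theta scale,
    embedded back into full-theta coordinates (rows/cols of fixed params = 0).

    ``scores``, when given, computes the analytic (N, p) score matrix; the
    Hessian is then the finite-difference Jacobian of the summed scores."""
    p = len(theta)
    free = np.array([i for i in range(p) if i not in fixed_idx])

    def case_free(free_vec):
        th = theta.copy()
        th[free] = free_vec
        return casewise(th)

    if scores is not None:
        S = scores(theta)[:, free]

        def grad_neg(free_vec):
            th = theta.copy()
            th[free] = free_vec
            return -scores(th)[:, free].sum(axis=0)

        H = _finite_diff_jacobian(grad_neg, theta[free])
        H = 0.5 * (H + H.T)
    else:
        S = _finite_diff_scores(case_free, theta[free], n)

        def total_neg(free_vec):
            return -case_free(free_vec).sum()

        H = _finite_diff_hessian(total_neg, theta[free])
    Bmat = S.T @ S
    min_eig = float(np.linalg.eigvalsh(H).min())
    if min_eig < 1e-8:
        warnings.warn("information matrix nearly singular; "
                      "some parameters may be weakly identified")
    cov_sw_free = _psd_solve(H, Bmat @ _psd_solve(H, np.eye(len(free))))
    cov_fo_free = _psd_solve(Bmat, np.eye(len(free)))
    cov_sw = np.zeros((p, p))
    cov_fo = np.zeros((p, p))
    cov_sw[np.ix_(free, free)] = cov_sw_free
    cov_fo[np.ix_(free, free)] = cov_fo_free
    return cov_sw, cov_fo, min_eig


def _psd_solve(A, B):
    try:
        X = linalg.solve(A, B, assume_a="sym")
        if not np.isfinite(X).all():
            raise linalg.LinAlgError("non-finite solution")
        return X
    except (linalg.LinAlgError, ValueError):
        return np.linalg.pinv(np.nan_to_num(A)) @ B


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def group_contrasts(fit: FitResult, se: str = "sandwich",
                    z: float = 1.959963984540054) -> pd.DataFrame:
    """Arm contrasts at t3 and t4 with delta-method 95% CIs.

    * ``diff`` (group difference at wave t) = beta_I + lambda_S(t) beta_S +
      lambda_Q(t) beta_Q; positive = higher outcome in the intervention arm.
    * ``change_diff`` (difference in change at wave t) =
      -(lambda_S(t) beta_S + lambda_Q(t) beta_Q); positive = stronger decrease
      in the intervention arm.
    * ``diff_excl_intercept`` drops beta_I from the group difference (the
      change-only contrast, emitted alongside the primary inclusive one).

    By construction diff(t) + change_diff(t) = beta_I exactly, at every wave.
    """
    spec, layout = fit.spec, fit.layout
    if "arm" not in spec.regressors:
        raise ValueError("model has no arm regressor")
    jarm = spec.regressors.index("arm")
    q = len(spec.regressors)
    lam = spec.loadings
    cov = {"sandwich": fit.cov_sandwich, "first_order": fit.cov_first_order}[se]

    rows = []
    for wave in (3, 4):
        lam_row = lam[wave]
        # c picks the arm column of B inside theta
        c_diff = np.zeros(layout.n_params)
        c_chg = np.zeros(layout.n_params)
        for i, f in enumerate(spec.factors):
            pos = layout.n_alpha + i * q + jarm
            c_diff[pos] = lam_row[i]
            if f != "intercept":
                c_chg[pos] = -lam_row[i]
        c_excl = c_diff.copy()
        ipos = layout.n_alpha + spec.factors.index("intercept") * q + jarm
        c_excl[ipos] = 0.0
        for label, cvec in ((f"diff_t{wave}", c_diff),
                            (f"change_diff_t{wave}", c_chg),
                            (f"diff_excl_intercept_t{wave}", c_excl)):
            est = float(cvec @ fit.theta)
            if cov is not None:
                sd = float(np.sqrt(max(cvec @ cov @ cvec, 0.0)))
            else:
                sd = np.nan
            rows.append({"contrast": label, "estimate": est, "se": sd,
                         "ci_low": est - z * sd, "ci_high": est + z * sd})
    return pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# saturated (unstructured) FIML fit via EM, and the independence baseline
# ---------------------------------------------------------------------------

@dataclass
class SaturatedFit:
    mean_coef: np.ndarray      # (5, q+1): columns = [1, x]; unconditional: (5,1)
    sigma: np.ndarray          # (5, 5)
    loglik: float
    n_params: int
    n_iter: int
    loglik_path: np.ndarray


def _gaussian_ll_blocks(dataset, mu_rows, sigma):
    """FIML log-likelihood given per-case means and a common covariance."""
    keys = dataset.pattern_keys()
    ll = 0.0
    for key in set(keys):
        rows = np.flatnonzero(keys == key)
        o = np.flatnonzero(dataset.mask[rows[0]])
        sub = sigma[np.ix_(o, o)]
        cf = linalg.cho_factor(sub, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        resid = dataset.outcome[np.ix_(rows, o)] - mu_rows[np.ix_(rows, o)]
        z = linalg.cho_solve(cf, resid.T)
        quad = np.einsum("ij,ji->i", resid, z).sum()
        ll += -0.5 * (len(rows) * (len(o) * math.log(2 * math.pi) + logdet) + quad)
    return ll


def saturated_fit(dataset: LongitudinalDataset,
                  regressors: tuple[str, ...] = (),
                  tol: float = 1e-10, maxiter: int = 5000) -> SaturatedFit:
    """Unstructured multivariate-normal FIML fit via EM.

    With ``regressors`` the mean is linear in [1, x] (still unstructured per
    wave); the covariance is a free symmetric PD matrix. The EM log-likelihood
    path is monotone; convergence at relative change < ``tol``.
    """
    spec = GrowthSpec(factors=("intercept",), regressors=tuple(regressors))
    X = design_matrix(dataset, spec) if regressors else np.zeros((dataset.n, 0))
    Xt = np.column_stack([np.ones(dataset.n), X])
    qq = Xt.shape[1]
    Y, M = dataset.outcome, dataset.mask

    # init: per-wave observed means regressed on X, diagonal covariance
    A = np.zeros((N_WAVES, qq))
    for t in range(N_WAVES):
        rows = M[:, t]
        A[t] = np.linalg.lstsq(Xt[rows], Y[rows, t], rcond=None)[0]
    resid_var = np.array([np.var(Y[M[:, t], t] - Xt[M[:, t]] @ A[t]) + 1e-6
                          for t in range(N_WAVES)])
    sigma = np.diag(resid_var)

    keys = dataset.pattern_keys()
    groups = [(np.flatnonzero(keys == k), np.flatnonzero(M[np.flatnonzero(keys == k)[0]]))
              for k in sorted(set(keys))]
    ll_path = []
    ll_old = -np.inf
    it = 0
    for it in range(1, maxiter + 1):
        mu_rows = Xt @ A.T
        ll = _gaussian_ll_blocks(dataset, mu_rows, sigma)
        ll_path.append(ll)
        if ll_old > -np.inf and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
        # E-step
        Ey = Y.copy()
        C_sum = np.zeros((N_WAVES, N_WAVES))
        for rows, o in groups:
            m = np.setdiff1d(np.arange(N_WAVES), o)
            if len(m) == 0:
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            W = Smo @ np.linalg.inv(Soo)
            cond_cov = sigma[np.ix_(m, m)] - W @ Smo.T
            resid = Y[np.ix_(rows, o)] - mu_rows[np.ix_(rows, o)]
            Ey[np.ix_(rows, m)] = mu_rows[np.ix_(rows, m)] + resid @ W.T
            C_sum[np.ix_(m, m)] += len(rows) * cond_cov
        # M-step
        G = Xt.T @ Xt
        A = np.linalg.solve(G, Xt.T @ Ey).T
        resid_full = Ey - Xt @ A.T
        sigma = (resid_full.T @ resid_full + C_sum) / dataset.n
        sigma = 0.5 * (sigma + sigma.T)
        if np.linalg.eigvalsh(sigma).min() < 1e-10:
            sigma += 1e-8 * np.eye(N_WAVES)  # ridge-and-retry
    n_params = N_WAVES * qq + N_WAVES * (N_WAVES + 1) // 2
    return SaturatedFit(mean_coef=A, sigma=sigma, loglik=float(ll_path[-1]),
                        n_params=n_params, n_iter=it,
                        loglik_path=np.asarray(ll_path))


@dataclass
class IndependenceFit:
    loglik: float
    n_params: int


def independence_fit(dataset: LongitudinalDataset,
                     regressors: tuple[str, ...] = ()) -> IndependenceFit:
    """Baseline model: waves independent, per-wave mean (on [1, x]) and variance.

    Under independence the FIML likelihood factorises across waves, so the MLE
    is closed-form per wave on that wave's observed cells (variance divisor n).
    """
    spec = GrowthSpec(factors=("intercept",), regressors=tuple(regressors))
    X = design_matrix(dataset, spec) if regressors else np.zeros((dataset.n, 0))
    Xt = np.column_stack([np.ones(dataset.n), X])
    ll = 0.0
    for t in range(N_WAVES):
        rows = dataset.mask[:, t]
        y = dataset.outcome[rows, t]
        coef = np.linalg.lstsq(Xt[rows], y, rcond=None)[0]
        resid = y - Xt[rows] @ coef
        v = float(np.mean(resid ** 2))
        ll += float(np.sum(stats.norm.logpdf(resid, scale=math.sqrt(v))))
    n_params = N_WAVES * Xt.shape[1] + N_WAVES
    return IndependenceFit(loglik=ll, n_params=n_params)


@dataclass
class FitIndices:
    bic: float
    cfi: float
    rmsea: float | None
    chi2: float
    df: int


def fit_indices(fit: FitResult, saturated: SaturatedFit,
                baseline: IndependenceFit) -> FitIndices:
    """BIC, CFI and RMSEA from the unscaled likelihood-ratio statistic.

    T = 2(LL_sat - LL_model), df = p_sat - p_model;
    CFI = 1 - max(T-df, 0)/max(T_b-df_b, T-df, 0);
    RMSEA = sqrt(max(T-df, 0)/(df * N)) (denominator N, not N-1).
    """
    T = 2.0 * (saturated.loglik - fit.loglik)
    df = saturated.n_params - fit.n_params
    Tb = 2.0 * (saturated.loglik - baseline.loglik)
    dfb = saturated.n_params - baseline.n_params
    num = max(T - df, 0.0)
    denom = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    rmsea = None if df <= 0 else math.sqrt(num / (df * fit.n))
    return FitIndices(bic=fit.bic, cfi=cfi, rmsea=rmsea, chi2=T, df=df)
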