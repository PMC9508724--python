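"""Pattern-mixture models: the growth model is estimated separately within
observed missing-data classes, inestimable parameters are fixed by identifying
restrictions, and overall estimates are proportion-weighted averages.

The sixteen possible missing-data patterns are condensed into three classes:

``complete``
    observed at both active-phase waves t1 and t2 and at least one follow-up;
``intermittent``
    missed at least one active-phase assessment but provided follow-up data;
``no_followup``
    missing at both follow-up waves t3 and t4.

Within a class, some growth parameters cannot be identified from the waves
its members actually provide (e.g. the quadratic rows of the factor
covariance when only three waves are observed, or the residual variance of a
wave nobody in the class reached). Those parameters are fixed to donor values
under one of three identifying restrictions: complete-case (cc — borrow from
the complete class), neighbouring-case (nc — borrow from the nearest richer
class), or available-case (ac — proportion-weighted average over the classes
where the parameter is estimable). Overall estimates are Σ_k π_k θ̂_k with π_k
the sample class proportions; delta-method SEs treat π as fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .data_model import LongitudinalDataset, N_WAVES
from .lgm_core import (FitResult, GrowthLayout, GrowthSpec, LGMParams,
                       PatternData, _casewise_gaussian, fit_mar,
                       natural_covariance)

CLASS_ORDER = ("complete", "intermittent", "no_followup")


@dataclass(frozen=True)
class PatternClass:
    label: str
    count: int
    proportion: float


@dataclass
class RestrictionPlan:
    """Per-class resolution of inestimable parameters."""

    restriction: str                       # cc | nc | ac
    fixes: dict[str, dict[str, float]]     # class -> natural name -> value


def assign_classes(dataset: LongitudinalDataset) -> tuple[np.ndarray,
                                                          list[PatternClass]]:
    """Label each participant complete / intermittent / no_followup."""
    m = dataset.mask
    labels = np.empty(dataset.n, dtype=object)
    no_fu = ~m[:, 3] & ~m[:, 4]
    complete = ~no_fu & m[:, 1] & m[:, 2]
    labels[no_fu] = "no_followup"
    labels[complete] = "complete"
    labels[~no_fu & ~complete] = "intermittent"
    classes = [PatternClass(lbl, int((labels == lbl).sum()),
                            float((labels == lbl).mean()))
               for lbl in CLASS_ORDER if (labels == lbl).any()]
    return labels, classes


# ---------------------------------------------------------------------------
# natural-parameter likelihood (used for the Fisher-information rank test)
# ---------------------------------------------------------------------------

def _natural_layout(spec: GrowthSpec) -> list[str]:
    names = [f"alpha[{f}]" for f in spec.factors]
    names += [f"B[{f},{x}]" for f in spec.factors for x in spec.regressors]
    ff = spec.factors
    names += [f"psi[{ff[j]},{ff[i]}]" for i in range(len(ff))
              for j in range(i + 1)]
    names += [f"eps[t{t}]" for t in range(N_WAVES)]
    return names


def _params_from_natural(nat: np.ndarray, spec: GrowthSpec) -> LGMParams:
    nf, q = spec.n_factors, len(spec.regressors)
    a = nat[:nf]
    B = nat[nf:nf + nf * q].reshape(nf, q)
    ntri = nf * (nf + 1) // 2
    psi = np.zeros((nf, nf))
    pos = nf + nf * q
    idx = 0
    for i in range(nf):
        for j in range(i + 1):
            psi[i, j] = psi[j, i] = nat[pos + idx]
            idx += 1
    eps = nat[pos + ntri:]
    return LGMParams(alpha=a, B=B, Psi=psi, eps=np.asarray(eps))


def detect_inestimable(class_dataset: LongitudinalDataset, spec: GrowthSpec,
                       reference: LGMParams,
                       eig_tol: float = 1e-8) -> list[str]:
    """Natural parameter names not identified by the class's observed waves.

    Two rules combine: a structural rule (residual variances of waves no class
    member reached; growth factors whose polynomial order exceeds what the
    number of distinct observed waves can support) and a Fisher-information
    rank test at the reference point (relative eigenvalue < ``eig_tol``),
    which catches covariance-side under-identification such as the quadratic
    rows of Psi in a class observing only three waves. Deterministic: null
    directions are resolved against a fixed priority (covariances involving
    the highest-order factor first, then residual variances, then means).
    """
    names = _natural_layout(spec)
    observed_waves = np.flatnonzero(class_dataset.mask.any(axis=0))
    k = len(observed_waves)
    flagged: list[str] = []
    # push the reference factor covariance to a PD interior point so that
    # finite-difference scores are well defined in every direction
    mineig = np.linalg.eigvalsh(reference.Psi).min()
    psi_ref = reference.Psi + max(0.0, 0.05 - mineig) * np.eye(spec.n_factors)
    reference = LGMParams(alpha=reference.alpha, B=reference.B,
                          Psi=psi_ref, eps=reference.eps)

    order = {"intercept": 0, "linear": 1, "quadratic": 2}
    for t in range(N_WAVES):
        if t not in observed_waves:
            flagged.append(f"eps[t{t}]")
    # interpolation rule: a polynomial factor of order f needs f+1 distinct
    # waves; saturated-mean rule: when the surviving factors exactly saturate
    # the class's waves, the highest-order one (never the intercept) is
    # borrowed as well — a just-identified mean curve extrapolates follow-up
    # waves from an ill-conditioned design and is practically inestimable
    flagged_factors = [f for f in spec.factors if order[f] >= k]
    surviving = [f for f in spec.factors if f not in flagged_factors]
    while len(surviving) >= k and order[surviving[-1]] >= 1:
        flagged_factors.append(surviving.pop())
    for f in flagged_factors:
        flagged += [n for n in names
                    if f"[{f}]" in n or f"[{f}," in n or f",{f}]" in n]
    flagged = list(dict.fromkeys(flagged))

    # Fisher-information rank test on the remaining free parameters
    pdata = PatternData(class_dataset, spec)
    nf, q = spec.n_factors, len(spec.regressors)
    B_ref = np.zeros((nf, q))
    qq = min(q, reference.B.shape[1])
    B_ref[:, :qq] = reference.B[:, :qq]
    nat0 = np.concatenate([
        reference.alpha, B_ref.ravel(),
        [reference.Psi[j, i] for i in range(nf) for j in range(i + 1)],
        reference.eps])

    def casewise_nat(nat):
        # only the observed-wave covariance needs to be PD, so mildly
        # indefinite Psi perturbations are fine for differentiation
        params = _params_from_natural(nat, spec)
        lam = spec.loadings
        sigma = lam @ params.Psi @ lam.T + np.diag(params.eps)
        out = np.empty(class_dataset.n)
        for blk in pdata.blocks:
            o = blk.obs
            try:
                cf = linalg.cho_factor(sigma[np.ix_(o, o)], lower=True)
            except linalg.LinAlgError:
                return np.full(class_dataset.n, -1e10)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            eta = params.alpha[None, :] + blk.X @ params.B.T
            mu = eta @ lam[o].T
            resid = blk.Y - mu
            z = linalg.cho_solve(cf, resid.T)
            quad = np.einsum("ij,ji->i", resid, z)
            out[blk.rows] = -0.5 * (len(o) * math.log(2 * math.pi)
                                    + logdet + quad)
        return out

    free = [i for i, n in enumerate(names) if n not in flagged]
    S = np.empty((class_dataset.n, len(free)))
    for col, i in enumerate(free):
        h = 1e-5 * max(1.0, abs(nat0[i]))
        natp, natm = nat0.copy(), nat0.copy()
        natp[i] += h
        natm[i] -= h
        S[:, col] = (casewise_nat(natp) - casewise_nat(natm)) / (2 * h)

    def priority(name: str) -> tuple:
        # smaller sorts first = preferred for flagging
        involved = [f for f in spec.factors if f in name]
        max_order = max((order[f] for f in involved), default=-1)
        if name.startswith("psi"):
            kind = 0
        elif name.startswith("eps"):
            kind = 1
        elif name.startswith("B"):
            kind = 2
        else:
            kind = 3
        return (kind, -max_order, name)

    free_names = [names[i] for i in free]
    while free_names:
        F = S.T @ S
        w, V = np.linalg.eigh(F)
        if w[0] > eig_tol * max(w[-1], 1.0):
            break
        v = np.abs(V[:, 0])
        cands = [j for j in range(len(free_names)) if v[j] > 0.3 * v.max()]
        j = min(cands, key=lambda j: priority(free_names[j]))
        flagged.append(free_names[j])
        free_names.pop(j)
        S = np.delete(S, j, axis=1)
    return sorted(flagged, key=lambda n: names.index(n))


# ---------------------------------------------------------------------------
# class-wise fitting with restrictions
# ---------------------------------------------------------------------------

@dataclass
class PMResult:
    restriction: str
    classes: list[PatternClass]
    class_fits: dict[str, FitResult]
    plan: RestrictionPlan
    estimates: pd.DataFrame            # averaged natural parameters
    contrasts: pd.DataFrame            # averaged arm contrasts
    loglik: float
    n: int
    extra: dict = field(default_factory=dict)


def _full_natural(params: LGMParams, spec: GrowthSpec) -> np.ndarray:
    """Natural parameter vector over the full name set (fixed rows included)."""
    nf = spec.n_factors
    psi_entries = [params.Psi[j, i] for i in range(nf) for j in range(i + 1)]
    return np.concatenate([params.alpha, params.B.ravel(), psi_entries,
                           params.eps])


def _natural_from_fit(fit: FitResult) -> dict[str, float]:
    return dict(zip(_natural_layout(fit.spec),
                    _full_natural(fit.params, fit.spec)))


def _fix_arguments(flags: list[str], donor: dict[str, float],
                   spec: GrowthSpec):
    """Translate flagged natural names into fit_mar fixing arguments.

    Psi flags are escalated to whole factor rows (deterministic), alpha/B are
    fixed directly, eps on the log scale.
    """
    fixed: dict[str, float] = {}
    psi_rows: dict[str, np.ndarray] = {}
    psi_factors = _flagged_factors(flags)
    for f in sorted(psi_factors, key=spec.factors.index):
        row = np.zeros(spec.n_factors)
        for g_idx, g in enumerate(spec.factors):
            a, b = sorted((f, g), key=spec.factors.index)
            row[g_idx] = donor.get(f"psi[{a},{b}]", 0.0)
        psi_rows[f] = row
    for name in flags:
        if name.startswith("alpha") or name.startswith("B"):
            fixed[name] = donor[name]
        elif name.startswith("eps"):
            t = name[name.index("[") + 1:-1]
            fixed[f"log_eps[{t}]"] = math.log(max(donor[name], 1e-8))
    return fixed, psi_rows


def fit_pm(dataset: LongitudinalDataset, spec: GrowthSpec | None = None,
           restriction: str = "cc", compute_se: bool = True,
           se: str = "sandwich", **fit_options) -> PMResult:
    """Multiple-group growth model over missing-data classes.

    Classes are fitted in richness order (complete, intermittent,
    no_followup); parameters a class cannot identify are fixed per the chosen
    identifying restriction; the overall estimate is the class-proportion
    weighted average with delta-method SEs (class proportions treated as
    known).
    """
    if restriction not in ("cc", "nc", "ac"):
        raise ValueError(f"unknown restriction {restriction!r}")
    spec = spec or GrowthSpec.standard()
    labels, classes = assign_classes(dataset)
    present = [c.label for c in classes]
    if len(present) < len(CLASS_ORDER):
        missing = sorted(set(CLASS_ORDER) - set(present))
        warnings.warn(f"empty pattern class(es) dropped: {missing}; "
                      f"proportions renormalised")

    class_fits: dict[str, FitResult] = {}
    flags_by_class: dict[str, list[str]] = {}
    fixes: dict[str, dict[str, float]] = {}

    for cls in classes:
        rows = np.flatnonzero(labels == cls.label)
        sub = dataset.subset(rows)
        if cls.label == "complete":
            fit = fit_mar(sub, spec, compute_se=compute_se, **fit_options)
            flags = detect_inestimable(sub, spec, fit.params)
            if flags:
                raise RuntimeError(
                    f"parameters inestimable in the complete class: {flags}")
            flags_by_class[cls.label] = []
            fixes[cls.label] = {}
            class_fits[cls.label] = fit
            continue
        reference = class_fits["complete"].params
        flags = detect_inestimable(sub, spec, reference)
        flags_by_class[cls.label] = flags
        donor = _donor_values(flags, cls.label, restriction, class_fits,
                              flags_by_class, classes)
        fixes[cls.label] = donor
        fixed, psi_rows = _fix_arguments(flags, donor, spec)
        fit = fit_mar(sub, spec, compute_se=compute_se, fixed=fixed,
                      psi_fixed_rows=psi_rows, **fit_options)
        class_fits[cls.label] = fit

    # proportion-weighted averaging ------------------------------------
    pis = {c.label: c.proportion for c in classes}
    full_names = _natural_layout(spec)
    avg_vals = np.zeros(len(full_names))
    avg_var = np.zeros(len(full_names))
    for lbl, fit in class_fits.items():
        vals = _full_natural(fit.params, spec)
        avg_vals += pis[lbl] * vals
        se_full = np.zeros(len(full_names))
        cov = fit.cov_sandwich if se == "sandwich" else fit.cov_first_order
        if cov is not None:
            cn = natural_covariance(fit.layout, fit.theta, cov)
            reduced = fit.layout.natural_names()
            sds = np.sqrt(np.maximum(np.diag(cn), 0.0))
            for name, sd in zip(reduced, sds):
                if name in full_names:
                    se_full[full_names.index(name)] = sd
        # parameters fixed by restriction carry no within-class variance
        vmask = np.array([0.0 if _is_fixed(n, flags_by_class[lbl]) else 1.0
                          for n in full_names])
        avg_var += (pis[lbl] ** 2) * se_full ** 2 * vmask
    z = 1.959963984540054
    estimates = pd.DataFrame(
        {"estimate": avg_vals, "se": np.sqrt(avg_var),
         "ci_low": avg_vals - z * np.sqrt(avg_var),
         "ci_high": avg_vals + z * np.sqrt(avg_var)}, index=full_names)

    contr = None
    if "arm" in spec.regressors and all(
            f.contrasts is not None for f in class_fits.values()):
        first = next(iter(class_fits.values())).contrasts
        est = sum(pis[l] * class_fits[l].contrasts["estimate"]
                  for l in class_fits)
        var = sum(pis[l] ** 2 * class_fits[l].contrasts["se"] ** 2
                  for l in class_fits)
        sd = np.sqrt(var)
        contr = pd.DataFrame({
            "estimate": est, "se": sd,
            "ci_low": est - z * sd, "ci_high": est + z * sd},
            index=first.index)

    ll = float(sum(f.loglik for f in class_fits.values()))
    return PMResult(restriction=restriction, classes=classes,
                    class_fits=class_fits,
                    plan=RestrictionPlan(restriction=restriction, fixes=fixes),
                    estimates=estimates, contrasts=contr, loglik=ll,
                    n=dataset.n)


def _is_fixed(name: str, flags: list[str]) -> bool:
    if name in flags:
        return True
    # psi flags escalate to whole rows
    if name.startswith("psi["):
        inside = name[4:-1].split(",")
        return any(f"psi[{a},{b}]" in flags or a in _flagged_factors(flags)
                   or b in _flagged_factors(flags) for a, b in [inside])
    return False


_FACTOR_ORDER = {"intercept": 0, "linear": 1, "quadratic": 2}


def _flagged_factors(flags: list[str]) -> set[str]:
    """Factors whose whole Psi row is escalated: for each flagged covariance
    entry, the higher-order factor is the inestimable one."""
    out = set()
    for f in flags:
        if f.startswith("psi["):
            a, b = f[4:-1].split(",")
            out.add(max((a, b), key=_FACTOR_ORDER.__getitem__))
    return out


def _donor_values(flags: list[str], label: str, restriction: str,
                  class_fits: dict[str, FitResult],
                  flags_by_class: dict[str, list[str]],
                  classes: list[PatternClass]) -> dict[str, float]:
    """Resolve each flagged parameter to a donor value per the restriction."""
    if not flags:
        return {}
    richer = [c.label for c in classes
              if c.label in class_fits]          # fitted so far, richest first
    nats = {lbl: _natural_from_fit(class_fits[lbl]) for lbl in richer}
    # psi row escalation means donors must cover whole rows too
    needed = set(flags)
    psi_fs = _flagged_factors(flags)
    out: dict[str, float] = {}
    all_names = list(nats[richer[0]])
    for name in all_names:
        involved = name in needed or (
            name.startswith("psi[") and
            any(f in psi_fs for f in name[4:-1].split(",")))
        if not involved:
            continue
        donors = [lbl for lbl in richer
                  if not _is_fixed(name, flags_by_class[lbl])]
        if not donors:
            raise RuntimeError(
                f"no estimable donor class for parameter {name} "
                f"(restriction {restriction})")
        if restriction == "cc":
            chosen = ["complete"]
            if _is_fixed(name, flags_by_class["complete"]):
                raise RuntimeError(
                    f"complete-class donor for {name} is itself inestimable")
        elif restriction == "nc":
            chosen = [donors[-1]]        # nearest (least rich) estimable class
        else:                            # ac: availability-weighted average
            chosen = donors
        pis = {c.label: c.proportion for c in classes}
        wsum = sum(pis[l] for l in chosen)
        out[name] = sum(pis[l] * nats[l][name] for l in chosen) / wsum
    return out


def pm_bootstrap_contrast_se(result: PMResult, n_draws: int = 2000,
                             seed: int = 0) -> pd.Series:
    """Parametric-bootstrap SEs of the averaged contrasts.

    Draws class-wise contrast estimates from normal distributions centred at
    the class estimates with the class delta-method SEs, averages with the
    fixed class proportions, and reports the SD across draws.
    """
    rng = np.random.default_rng(seed)
    pis = {c.label: c.proportion for c in result.classes}
    idx = result.contrasts.index
    draws = np.zeros((n_draws, len(idx)))
    for lbl, fit in result.class_fits.items():
        est = fit.contrasts["estimate"].to_numpy()
        sd = fit.contrasts["se"].to_numpy()
        draws += pis[lbl] * (est[None, :]
                             + rng.standard_normal((n_draws, len(idx)))
                             * sd[None, :])
    return pd.Series(draws.std(axis=0, ddof=1), index=idx)
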