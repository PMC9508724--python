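"""Step-1 missing-data diagnostics: observed descriptives, per-pattern outcome
trajectories, and logistic models of follow-up participation.

These analyses accumulate evidence about the process that generated the
missing data. Baseline covariates that predict participation support a MAR
assumption (the missingness is explainable by observed data); patterns whose
observed trajectories drift before dropout hint at MNAR and motivate the
Step-3 sensitivity models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import LongitudinalDataset, N_WAVES, WAVES, derive_missing_patterns


class SeparationError(RuntimeError):
    """The participation logistic suffered (quasi-)complete separation."""


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


def observed_descriptives(dataset: LongitudinalDataset) -> pd.DataFrame:
    """Observed (per-cell complete-case) outcome summaries per wave and arm.

    Returns a tidy frame with one row per wave x group (total / control /
    intervention): observed mean, SD (n-1 divisor), n observed and % observed.
    A group-wave cell without observations reports NaN mean/SD, not zero.
    """
    rows = []
    groups = {"total": np.ones(dataset.n, dtype=bool),
              "control": dataset.arm == 0,
              "intervention": dataset.arm == 1}
    for t in range(N_WAVES):
        for gname, sel in groups.items():
            obs = sel & dataset.mask[:, t]
            y = dataset.outcome[obs, t]
            n_group = int(sel.sum())
            rows.append({
                "wave": WAVES[t], "group": gname,
                "mean": float(np.mean(y)) if len(y) else np.nan,
                "sd": float(np.std(y, ddof=1)) if len(y) > 1 else
                      (0.0 if len(y) == 1 else np.nan),
                "n_obs": int(len(y)),
                "pct_obs": 100.0 * len(y) / n_group if n_group else np.nan})
    return pd.DataFrame(rows).set_index(["wave", "group"])


def pattern_trajectories(dataset: LongitudinalDataset) -> pd.DataFrame:
    """Mean observed outcome per missing-data pattern, arm and wave.

    Waves missing in a pattern are absent from its sequence. Returns a tidy
    frame indexed by (pattern, arm, wave).
    """
    keys = dataset.pattern_keys()
    rows = []
    for pat in derive_missing_patterns(dataset):
        sel = keys == pat.key
        obs_waves = [t for t in range(N_WAVES) if pat.key[t] == "O"]
        for arm in (0, 1):
            members = sel & (dataset.arm == arm)
            if not members.any():
                continue
            for t in obs_waves:
                rows.append({"pattern": pat.key, "arm": arm, "wave": WAVES[t],
                             "mean": float(dataset.outcome[members, t].mean()),
                             "n": int(members.sum())})
    return pd.DataFrame(rows).set_index(["pattern", "arm", "wave"])


def plot_pattern_trajectories(dataset: LongitudinalDataset, path) -> None:
    """Small-multiple plot of per-pattern mean trajectories (optional artifact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = pattern_trajectories(dataset).reset_index()
    patterns = traj["pattern"].unique()
    ncol = 4
    nrow = int(np.ceil(len(patterns) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             sharey=True, squeeze=False)
    wave_x = {w: i for i, w in enumerate(WAVES)}
    for ax, pat in zip(axes.ravel(), patterns):
        for arm, style in ((0, "k:"), (1, "k-")):
            sub = traj[(traj["pattern"] == pat) & (traj["arm"] == arm)]
            ax.plot([wave_x[w] for w in sub["wave"]], sub["mean"], style)
        ax.set_title(pat, fontsize=9)
        ax.set_xticks(range(N_WAVES), WAVES, fontsize=7)
    for ax in axes.ravel()[len(patterns):]:
        ax.axis("off")
    fig.suptitle("observed outcome by missing-data pattern "
                 "(solid: intervention, dotted: control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


DEFAULT_PREDICTORS = ("sex", "age", "education", "partner", "arm", "health",
                      "smoking", "baseline_risk")


@dataclass
class ParticipationModel:
    wave: str
    table: pd.DataFrame        # per predictor: coef, se, OR, 95% CI, p
    n_used: int
    converged: bool
    loglik: float


def participation_logistic(dataset: LongitudinalDataset, wave: str,
                           predictors=DEFAULT_PREDICTORS,
                           smoking: str = "binary") -> ParticipationModel:
    """Logistic regression of participation (outcome observed) at t3 or t4.

    Participation means the outcome is observed at that wave. Smoking enters
    as a single smoker-vs-non-smoker contrast by default (reference:
    non-smokers, i.e. never/former), or as dummy categories with "never"
    reference when ``smoking="categories"``. Rows with missing covariates are
    dropped (listwise) and the retained count reported. Wald 95% CIs are
    computed on the log-odds scale and exponentiated to odds ratios.
    """
    if wave not in ("t3", "t4"):
        raise ValueError("participation models target wave 't3' or 't4'")
    t = WAVES.index(wave)
    y = dataset.mask[:, t].astype(float)

    cols: dict[str, np.ndarray] = {}
    for name in predictors:
        if name == "arm":
            cols["arm"] = dataset.arm.astype(float)
            continue
        if dataset.covariates is None or name not in dataset.covariates:
            raise ValueError(f"predictor {name!r} not found in covariates")
        v = dataset.covariates[name].to_numpy(dtype=float)
        if name == "smoking":
            if smoking == "binary":
                cols["smoker"] = (v >= 2).astype(float)
            else:
                for code, lbl in ((1, "former"), (2, "occasional"), (3, "daily")):
                    cols[f"smoking_{lbl}"] = (v == code).astype(float)
        else:
            cols[name] = v
    X = pd.DataFrame(cols)
    keep = ~X.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    X = X[keep.to_numpy()]
    yk = y[keep.to_numpy()]

    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR
        r = np.linalg.qr(design.to_numpy(), mode="r")
        bad = [design.columns[i] for i in range(design.shape[1])
               if abs(r[i, i]) < 1e-8] if r.shape[0] >= design.shape[1] else \
              list(design.columns)
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad}")

    try:
        res = sm.Logit(yk, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or \
            np.abs(res.params).max() > 30:
        worst = design.columns[int(np.abs(res.params).argmax())]
        raise SeparationError(
            f"participation model did not converge; predictor {worst!r} "
            f"suggests (quasi-)separation")

    z = 1.959963984540054
    coefs = res.params
    ses = res.bse
    table = pd.DataFrame({
        "coef": coefs, "se": ses,
        "or": np.exp(coefs),
        "or_ci_low": np.exp(coefs - z * ses),
        "or_ci_high": np.exp(coefs + z * ses),
        "pvalue": res.pvalues})
    model = ParticipationModel(wave=wave, table=table, n_used=int(len(yk)),
                               converged=True, loglik=float(res.llf))
    if n_dropped:
        model.table.attrs["n_dropped_missing_covariates"] = n_dropped
    return model
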