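"""Wide-format longitudinal trial data: container, I/O, missing-data patterns,
and missing-data indicator coding.

The canonical object is :class:`LongitudinalDataset`: one row per participant,
a continuous outcome (AUDIT-C-like, 0-12 scale) at five waves t0..t4, a binary
arm assignment (0 = control, 1 = intervention) and baseline covariates.
Baseline (t0) is always observed; the per-cell boolean mask records which
follow-up outcomes were observed.

Two wave-wise missing-data indicator codings are provided for the selection and
shared-parameter models:

``survival``
    0 = at risk, no dropout event (observed or intermittently missing),
    1 = permanent dropout at this wave, sentinel = no longer at risk.
``multinomial``
    0 = intermittent missing, 1 = permanent dropout, 2 = observed (reference),
    sentinel = no longer at risk.

The post-dropout sentinel is the integer -1 internally and is written as "NA"
in CSV output.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WAVES: tuple[str, ...] = ("t0", "t1", "t2", "t3", "t4")
N_WAVES = len(WAVES)
#: months since baseline of the five assessment waves
WAVE_MONTHS: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 36.0)

#: indicator value for waves after a dropout event ("not at risk")
POST_DROPOUT: int = -1

COVARIATE_COLUMNS: tuple[str, ...] = (
    "sex", "age", "education", "partner", "health", "smoking", "baseline_risk",
)

#: mapping of integer smoking codes used throughout the package
SMOKING_LEVELS: tuple[str, ...] = ("never", "former", "occasional", "daily")


class SchemaError(ValueError):
    """A required column is absent or the column map is malformed."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number or the missing sentinel."""


class ValidationError(ValueError):
    """The data violate a dataset invariant (e.g. missing baseline outcome)."""


@dataclass
class LongitudinalDataset:
    """Wide-format two-arm trial with five outcome waves.

    Parameters
    ----------
    outcome
        (N, 5) float array; ``np.nan`` where the outcome is missing.
    mask
        (N, 5) boolean array, True exactly where the outcome is observed.
    arm
        (N,) integer array with values in {0, 1}.
    covariates
        Optional DataFrame of baseline covariates (numeric columns).
    schedule
        Months since baseline per wave; strictly increasing.
    latent
        Optional (N, n_factors) array of true latent growth factors, carried
        along by the simulator so MNAR shared-parameter mechanisms can be
        imposed after the fact.
    complete_outcome
        Optional (N, 5) array of the pre-masking outcomes (simulator only).
    """

    outcome: np.ndarray
    mask: np.ndarray
    arm: np.ndarray
    covariates: pd.DataFrame | None = None
    schedule: np.ndarray = field(
        default_factory=lambda: np.asarray(WAVE_MONTHS, dtype=float))
    latent: np.ndarray | None = None
    complete_outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.arm = np.asarray(self.arm, dtype=int)
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.outcome.ndim != 2 or self.outcome.shape[1] != N_WAVES:
            raise ValidationError(
                f"outcome must be (N, {N_WAVES}); got {self.outcome.shape}")
        if self.mask.shape != self.outcome.shape:
            raise ValidationError("mask and outcome shapes differ")
        if self.arm.shape != (self.outcome.shape[0],):
            raise ValidationError("arm must be one value per participant")
        if not np.isin(self.arm, (0, 1)).all():
            raise ValidationError("arm must be coded 0 (control) / 1 (intervention)")
        if not np.all(np.diff(self.schedule) > 0):
            raise ValidationError("wave schedule must be strictly increasing")
        if not self.mask[:, 0].all():
            bad = np.flatnonzero(~self.mask[:, 0]).tolist()
            raise ValidationError(
                f"baseline outcome missing for rows {bad}; t0 must be observed")
        obs_ok = ~np.isnan(self.outcome) == self.mask
        if not obs_ok.all():
            raise ValidationError("mask inconsistent with NaN cells in outcome")
        if self.covariates is not None and len(self.covariates) != self.n:
            raise ValidationError("covariates row count differs from outcome")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def observed_counts(self) -> np.ndarray:
        """Number of observed outcomes per wave."""
        return self.mask.sum(axis=0)

    def pattern_keys(self) -> np.ndarray:
        """Per-row observed/missing key, e.g. ``"OOOMM"``."""
        chars = np.where(self.mask, "O", "M")
        return np.array(["".join(row) for row in chars])

    def subset(self, rows: np.ndarray) -> "LongitudinalDataset":
        cov = self.covariates.iloc[rows].reset_index(drop=True) \
            if self.covariates is not None else None
        return LongitudinalDataset(
            outcome=self.outcome[rows], mask=self.mask[rows],
            arm=self.arm[rows], covariates=cov, schedule=self.schedule,
            latent=None if self.latent is None else self.latent[rows],
            complete_outcome=None if self.complete_outcome is None
            else self.complete_outcome[rows])

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.outcome, columns=[f"y{t}" for t in range(N_WAVES)])
        df.insert(0, "arm", self.arm)
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = self.covariates[c].to_numpy()
        return df

    def to_csv(self, path) -> None:
        # %.17g guarantees an exact float64 round trip through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


DEFAULT_SCHEMA: dict[str, str] = {
    **{f"y{t}": f"y{t}" for t in range(N_WAVES)}, "arm": "arm",
    **{c: c for c in COVARIATE_COLUMNS},
}


def load_wide_dataset(path, schema: dict[str, str] | None = None,
                      missing_sentinel: str = "") -> LongitudinalDataset:
    """Read a wide CSV (header row required) into a :class:`LongitudinalDataset`.

    ``schema`` maps canonical names (``y0``..``y4``, ``arm``, covariate names)
    to the column names present in the file; unmapped covariates are simply not
    loaded. Cells equal to ``missing_sentinel`` (default: empty cell) are
    treated as missing.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    if isinstance(path, (str, bytes)) or hasattr(path, "read"):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(str(path), dtype=str, keep_default_na=False)

    required = [f"y{t}" for t in range(N_WAVES)] + ["arm"]
    missing_cols = [schema.get(k, k) for k in required
                    if schema.get(k, k) not in df.columns]
    if missing_cols:
        raise SchemaError(f"required columns absent from file: {missing_cols}")

    def numeric(col: str, allow_missing: bool) -> tuple[np.ndarray, np.ndarray]:
        raw = df[col].str.strip()
        is_missing = (raw == missing_sentinel) | (raw == "NA") | (raw == "")
        vals = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = vals.isna() & ~is_missing
        if bad.any():
            rows = np.flatnonzero(bad.to_numpy()).tolist()
            raise ParseError(
                f"non-numeric, non-sentinel cells in column {col!r} at rows {rows}")
        if not allow_missing and is_missing.any():
            rows = np.flatnonzero(is_missing.to_numpy()).tolist()
            raise ValidationError(
                f"column {col!r} has missing values at rows {rows}")
        # re-parse through Python's float for an exact round trip (the fast
        # pandas parser can be one ulp off)
        miss = is_missing.to_numpy()
        exact = np.array([np.nan if m else float(s)
                          for s, m in zip(raw.to_numpy(), miss)])
        return exact, miss

    outcome = np.empty((len(df), N_WAVES))
    mask = np.empty((len(df), N_WAVES), dtype=bool)
    for t in range(N_WAVES):
        col = schema.get(f"y{t}", f"y{t}")
        vals, miss = numeric(col, allow_missing=t > 0)
        if t == 0 and miss.any():  # unreachable; numeric() raised already
            raise ValidationError("baseline outcome missing")
        outcome[:, t] = vals
        mask[:, t] = ~miss

    arm, _ = numeric(schema.get("arm", "arm"), allow_missing=False)

    cov_frames = {}
    for name in COVARIATE_COLUMNS:
        col = schema.get(name, name)
        if col in df.columns:
            vals, miss = numeric(col, allow_missing=True)
            cov_frames[name] = np.where(miss, np.nan, vals)
    covariates = pd.DataFrame(cov_frames) if cov_frames else None

    return LongitudinalDataset(outcome=outcome, mask=mask,
                               arm=arm.astype(int), covariates=covariates)


# ---------------------------------------------------------------------------
# missing-data patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingPattern:
    key: str          # e.g. "OOOMM"
    index: int        # 1-based; fully observed pattern first
    count: int
    percentage: float


def derive_missing_patterns(dataset: LongitudinalDataset) -> list[MissingPattern]:
    """Distinct observed/missing configurations over t0..t4 with counts.

    Ordering is deterministic: the fully observed pattern (if present) comes
    first, remaining patterns follow in lexicographic order of their key
    ('M' < 'O', so patterns with earlier missingness sort first).
    """
    counts = Counter(dataset.pattern_keys())
    complete = "O" * N_WAVES
    keys = sorted(counts)
    if complete in counts:
        keys.remove(complete)
        keys = [complete] + keys
    n = dataset.n
    return [MissingPattern(key=k, index=i + 1, count=counts[k],
                           percentage=100.0 * counts[k] / n)
            for i, k in enumerate(keys)]


def patterns_to_frame(patterns: list[MissingPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {"pattern": [p.key for p in patterns],
         "index": [p.index for p in patterns],
         "n": [p.count for p in patterns],
         "percent": [p.percentage for p in patterns]})


# ---------------------------------------------------------------------------
# indicator coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorMatrix:
    """Wave-wise missing-data indicators m1..m4 for t1..t4.

    ``values`` is an (N, 4) int array in the declared coding scheme, with
    :data:`POST_DROPOUT` (-1) marking not-at-risk waves after a dropout event.
    """

    scheme: str
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"m{t}" for t in range(1, N_WAVES)])
        return df.astype("Int64").mask(df == POST_DROPOUT)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def dropout_wave(mask_row: np.ndarray) -> int | None:
    """First wave of the terminal run of missing waves; None if observed at t4."""
    if mask_row[-1]:
        return None
    k = int(np.max(np.flatnonzero(mask_row)))  # last observed wave (>= 0)
    return k + 1


def code_missing_indicators(dataset: LongitudinalDataset,
                            scheme: str) -> IndicatorMatrix:
    """Code wave-wise indicators under the ``survival`` or ``multinomial`` scheme.

    The dropout event happens at the first wave of the terminal run of missing
    waves; all later waves carry the not-at-risk sentinel; missing waves before
    the dropout wave are intermittent.
    """
    if scheme not in ("survival", "multinomial"):
        raise ValueError(f"unknown indicator coding scheme: {scheme!r}")
    n = dataset.n
    vals = np.empty((n, N_WAVES - 1), dtype=int)
    for i in range(n):
        row = dataset.mask[i]
        d = dropout_wave(row)
        for t in range(1, N_WAVES):
            if d is not None and t > d:
                vals[i, t - 1] = POST_DROPOUT
            elif d is not None and t == d:
                vals[i, t - 1] = 1
            elif scheme == "survival":
                vals[i, t - 1] = 0
            else:  # multinomial, before any dropout
                vals[i, t - 1] = 2 if row[t] else 0
    return IndicatorMatrix(scheme=scheme, values=vals)
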