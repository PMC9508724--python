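import numpy as np
import pandas as pd
import pytest

from lgmsens import (observed_descriptives, participation_logistic,
                     pattern_trajectories)
from lgmsens.diagnostics import CollinearityError
from .conftest import make_dataset


class TestObservedDescriptives:
    def test_constant_data(self):
        ds = make_dataset(np.full((6, 5), 3.0))
        tab = observed_descriptives(ds)
        assert (tab["mean"] == 3.0).all()
        assert (tab["sd"] == 0.0).all()
        assert (tab["pct_obs"] == 100.0).all()

    def test_hand_computed_values(self):
        y = np.array([[1.0, 2, 3, 4, 5],
                      [3.0, 4, 5, 6, 7],
                      [2.0, np.nan, 4, 5, 6],
                      [4.0, 6, np.nan, 7, 8]])
        ds = make_dataset(y, arm=[0, 0, 1, 1])
        tab = observed_descriptives(ds)
        t0 = tab.loc[("t0", "total")]
        assert t0["mean"] == pytest.approx(2.5)
        assert t0["sd"] == pytest.approx(np.std([1, 3, 2, 4], ddof=1))
        t1 = tab.loc[("t1", "total")]
        assert t1["mean"] == pytest.approx(np.mean([2, 4, 6]))
        assert t1["n_obs"] == 3 and t1["pct_obs"] == 75.0
        assert tab.loc[("t2", "intervention"), "n_obs"] == 1
        assert tab.loc[("t2", "intervention"), "mean"] == pytest.approx(4.0)

    def test_masking_changes_counts_not_surviving_means(self):
        y = np.array([[1.0, 2, 3, 4, 5],
                      [3.0, 4, 5, 6, 7],
                      [5.0, 6, 7, 8, 9]])
        full = observed_descriptives(make_dataset(y, arm=[0, 0, 0]))
        y2 = y.copy()
        y2[2, 3] = np.nan
        masked = observed_descriptives(make_dataset(y2, arm=[0, 0, 0]))
        assert masked.loc[("t3", "total"), "n_obs"] == 2
        assert masked.loc[("t3", "total"), "mean"] == pytest.approx(5.0)
        assert full.loc[("t1", "total"), "mean"] == \
            masked.loc[("t1", "total"), "mean"]

    def test_empty_cell_reports_nan_not_zero(self):
        y = np.full((2, 5), 2.0)
        y[:, 4] = np.nan
        tab = observed_descriptives(make_dataset(y, arm=[0, 0]))
        assert np.isnan(tab.loc[("t4", "total"), "mean"])
        assert tab.loc[("t4", "total"), "n_obs"] == 0


class TestPatternTrajectories:
    def test_flat_single_pattern(self):
        ds = make_dataset(np.full((8, 5), 2.0))
        traj = pattern_trajectories(ds)
        assert set(traj.reset_index()["pattern"]) == {"OOOOO"}
        assert (traj["mean"] == 2.0).all()
        assert len(traj) == 10  # 5 waves x 2 arms

    def test_pattern_sequence_length_matches_observed_waves(self):
        y = np.full((4, 5), 1.0)
        y[:, (3, 4)] = np.nan
        traj = pattern_trajectories(make_dataset(y)).reset_index()
        assert set(traj["wave"]) == {"t0", "t1", "t2"}

    def test_arm_shift_appears_at_every_wave(self):
        y = np.full((10, 5), 3.0)
        arm = np.array([0, 1] * 5)
        y[arm == 1] += 0.7
        traj = pattern_trajectories(make_dataset(y, arm=arm))
        for wave in ("t0", "t1", "t2", "t3", "t4"):
            d = traj.loc[("OOOOO", 1, wave), "mean"] - \
                traj.loc[("OOOOO", 0, wave), "mean"]
            assert d == pytest.approx(0.7)


def participation_toy(n_expose=50, k_expose=30, n_ref=50, k_ref=20, seed=0):
    """Binary predictor, participation at t3 given by the 2x2 table."""
    n = n_expose + n_ref
    y = np.full((n, 5), 3.0)
    exposed = np.zeros(n)
    exposed[:n_expose] = 1.0
    miss = np.ones(n, dtype=bool)
    miss[:k_expose] = False                       # exposed participants seen
    miss[n_expose:n_expose + k_ref] = False       # reference participants seen
    y[miss, 3] = np.nan
    rng = np.random.default_rng(seed)
    cov = {"sex": exposed, "age": np.full(n, 30.0),
           "education": rng.integers(0, 2, n).astype(float),
           "partner": np.zeros(n), "health": np.full(n, 3.0),
           "smoking": np.zeros(n), "baseline_risk": np.zeros(n)}
    return make_dataset(y, arm=np.zeros(n), covariates=cov)


class TestParticipationLogistic:
    def test_single_predictor_or_matches_cross_product_ratio(self):
        ds = participation_toy()
        model = participation_logistic(ds, "t3", predictors=("sex",))
        # 30/20 participating vs 20/30 not: OR = (30*30)/(20*20) = 2.25
        assert model.table.loc["sex", "or"] == pytest.approx(2.25, rel=1e-4)

    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(5)
        n = 400
        y = np.full((n, 5), 3.0)
        y[rng.random(n) < 0.3, 3] = np.nan
        cov = {"sex": rng.integers(0, 2, n).astype(float)}
        ds = make_dataset(y, covariates={**cov, "age": np.full(n, 30.0)})
        model = participation_logistic(ds, "t3", predictors=("sex",))
        row = model.table.loc["sex"]
        assert row["or_ci_low"] < 1.0 < row["or_ci_high"]

    def test_reversed_outcome_flips_log_odds(self):
        ds = participation_toy()
        m = participation_logistic(ds, "t3", predictors=("sex",))
        flipped = ds.mask.copy()
        flipped[:, 3] = ~flipped[:, 3]
        ds2 = make_dataset(np.where(flipped, np.nan_to_num(ds.outcome, nan=3.0),
                                    np.nan),
                           arm=ds.arm, covariates=ds.covariates)
        m2 = participation_logistic(ds2, "t3", predictors=("sex",))
        assert m2.table.loc["sex", "coef"] == pytest.approx(
            -m.table.loc["sex", "coef"], abs=1e-6)

    def test_collinear_design_rejected(self):
        ds = participation_toy()
        ds.covariates["partner"] = ds.covariates["sex"]
        with pytest.raises(CollinearityError):
            participation_logistic(ds, "t3", predictors=("sex", "partner"))

    def test_emulated_trial_recovers_mar_drivers(self, emulated_trial):
        model = participation_logistic(emulated_trial, "t4")
        tab = model.table
        # the MAR mechanism favours participation of older, better educated,
        # non-smoking, low-risk participants
        assert tab.loc["age", "or"] > 1.0
        assert tab.loc["education", "or"] > 1.0
        assert tab.loc["smoker", "or"] < 1.0
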