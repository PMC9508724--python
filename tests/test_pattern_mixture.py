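import numpy as np
import pytest

from lgmsens import (GrowthSpec, assign_classes, detect_inestimable, fit_mar,
                     fit_pm, trial_emulation_defaults, simulate_trial)
from lgmsens.pattern_mixture import pm_bootstrap_contrast_se
from .conftest import make_dataset

SPEC = GrowthSpec.standard()


def mask_to_outcome(masks, fill=3.0):
    y = np.full((len(masks), 5), fill)
    for i, m in enumerate(masks):
        for t, obs in enumerate(m):
            if not obs:
                y[i, t] = np.nan
    return y


class TestAssignClasses:
    def test_worked_examples(self):
        masks = [
            (1, 1, 1, 1, 1),   # fully observed -> complete
            (1, 1, 1, 0, 0),   # no follow-up data
            (1, 0, 1, 1, 1),   # missed an active-phase wave -> intermittent
            (1, 0, 0, 1, 0),   # missing t1, observed t3 -> intermittent
            (1, 1, 1, 0, 1),   # observed a follow-up -> complete
        ]
        labels, classes = assign_classes(make_dataset(mask_to_outcome(masks)))
        assert labels.tolist() == ["complete", "no_followup", "intermittent",
                                   "intermittent", "complete"]
        assert sum(c.count for c in classes) == 5
        assert sum(c.proportion for c in classes) == pytest.approx(1.0)

    def test_classes_partition_emulated_trial(self, emulated_trial):
        labels, classes = assign_classes(emulated_trial)
        assert sum(c.count for c in classes) == emulated_trial.n
        assert set(labels) == {c.label for c in classes}


class TestDetectInestimable:
    @pytest.fixture(scope="class")
    def reference(self, emulated_trial):
        return fit_mar(emulated_trial, compute_se=False).params

    def test_all_waves_observed_nothing_flagged(self, emulated_trial,
                                                reference):
        flags = detect_inestimable(emulated_trial, SPEC, reference)
        assert flags == []

    def test_three_wave_class_flags_quadratic_and_unseen_residuals(
            self, reference):
        rng = np.random.default_rng(4)
        y = np.full((300, 5), np.nan)
        y[:, :3] = 3.0 + rng.standard_normal((300, 3))
        ds = make_dataset(y)
        flags = detect_inestimable(ds, SPEC, reference)
        assert "alpha[quadratic]" in flags
        assert "psi[quadratic,quadratic]" in flags
        assert "psi[intercept,quadratic]" in flags
        assert "eps[t3]" in flags and "eps[t4]" in flags
        assert "alpha[intercept]" not in flags
        assert "alpha[linear]" not in flags
        assert "psi[intercept,linear]" not in flags

    def test_baseline_only_class_keeps_intercept_mean_and_total_variance(
            self, reference):
        rng = np.random.default_rng(5)
        y = np.full((200, 5), np.nan)
        y[:, 0] = 3.0 + rng.standard_normal(200)
        spec = GrowthSpec.standard("ilq", regressors=())
        flags = detect_inestimable(make_dataset(y), spec, reference)
        free = [n for n in
                ["alpha[intercept]", "alpha[linear]", "alpha[quadratic]",
                 "psi[intercept,intercept]", "eps[t0]"] if n not in flags]
        # only the intercept mean and one variance (the total baseline
        # variance) remain identifiable
        assert "alpha[intercept]" in free
        assert "alpha[linear]" not in free and "alpha[quadratic]" not in free
        assert len([f for f in free
                    if f in ("psi[intercept,intercept]", "eps[t0]")]) == 1


class TestFitPm:
    def test_single_class_degenerates_to_mar_fit(self, complete_trial):
        pm = fit_pm(complete_trial, restriction="cc", compute_se=True)
        mar = fit_mar(complete_trial, compute_se=True)
        assert len(pm.classes) == 1
        np.testing.assert_allclose(
            pm.contrasts["estimate"], mar.contrasts["estimate"], atol=1e-10)
        assert pm.loglik == pytest.approx(mar.loglik)

    @pytest.fixture(scope="class")
    def two_class_toy(self):
        """Two equal classes with slope means +0.2 / -0.2; everything
        estimable (the intermittent class still spans all five waves)."""
        rng = np.random.default_rng(11)
        n = 400
        spec = GrowthSpec.standard("il")
        lam = spec.loadings
        y = np.empty((n, 5))
        arm = np.tile([0, 1], n // 2)
        for i in range(n):
            slope = 0.2 if i < n // 2 else -0.2
            eta = np.array([3.0 + 0.5 * rng.standard_normal(),
                            slope + 0.3 * rng.standard_normal()])
            y[i] = lam @ eta + 0.5 * rng.standard_normal(5)
        y[n // 2:, 1] = np.nan     # second half becomes "intermittent"
        return make_dataset(y, arm=arm), spec

    def test_weighted_average_identity_and_restriction_equivalence(
            self, two_class_toy):
        ds, spec = two_class_toy
        results = {r: fit_pm(ds, spec, restriction=r, compute_se=True)
                   for r in ("cc", "nc", "ac")}
        pm = results["cc"]
        labels = [c.label for c in pm.classes]
        assert labels == ["complete", "intermittent"]
        # averaged estimate is exactly the proportion-weighted class mean
        pis = {c.label: c.proportion for c in pm.classes}
        for name in pm.estimates.index:
            manual = sum(
                pis[lbl] * dict(zip(pm.estimates.index,
                                    _full_natural(pm.class_fits[lbl])))[name]
                for lbl in labels)
            assert pm.estimates.loc[name, "estimate"] == pytest.approx(
                manual, abs=1e-12)
        # averaged slope mean is the mean of +0.2 and -0.2
        assert pm.estimates.loc["alpha[linear]", "estimate"] == pytest.approx(
            0.0, abs=0.06)
        # with nothing inestimable, cc / nc / ac coincide exactly
        for r in ("nc", "ac"):
            np.testing.assert_allclose(results[r].estimates["estimate"],
                                       pm.estimates["estimate"], atol=1e-12)
            np.testing.assert_allclose(results[r].contrasts["estimate"],
                                       pm.contrasts["estimate"], atol=1e-12)

    def test_average_lies_in_convex_hull(self, emulated_trial):
        pm = fit_pm(emulated_trial, restriction="cc", compute_se=False)
        for name in pm.estimates.index:
            vals = [dict(zip(pm.estimates.index,
                             _full_natural(pm.class_fits[lbl])))[name]
                    for lbl in pm.class_fits]
            est = pm.estimates.loc[name, "estimate"]
            assert min(vals) - 1e-9 <= est <= max(vals) + 1e-9

    def test_delta_se_matches_parametric_bootstrap(self, two_class_toy):
        ds, spec = two_class_toy
        pm = fit_pm(ds, spec, restriction="cc", compute_se=True)
        boot = pm_bootstrap_contrast_se(pm, n_draws=4000, seed=2)
        for name in pm.contrasts.index:
            assert pm.contrasts.loc[name, "se"] == pytest.approx(
                boot[name], abs=0.01)

    def test_unknown_restriction_rejected(self, complete_trial):
        with pytest.raises(ValueError):
            fit_pm(complete_trial, restriction="jumping")


def _full_natural(fit):
    from lgmsens.pattern_mixture import _full_natural as fn
    return fn(fit.params, fit.spec)
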