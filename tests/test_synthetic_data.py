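import numpy as np
import pytest
from scipy import stats

from lgmsens import (MCARMechanism, MNARDKMechanism, MNARWCMechanism,
                     SimConfig, impose_missingness, trial_emulation_defaults,
                     simulate_trial)


class TestSimulateTrial:
    def test_same_seed_reproduces_different_seed_differs(self):
        a = simulate_trial(trial_emulation_defaults(n=200, seed=4))
        b = simulate_trial(trial_emulation_defaults(n=200, seed=4))
        c = simulate_trial(trial_emulation_defaults(n=200, seed=5))
        np.testing.assert_array_equal(a.outcome, b.outcome)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert not np.array_equal(a.outcome, c.outcome)

    def test_noiseless_config_sits_on_the_mean_curve(self):
        cfg = SimConfig(n=50, psi=tuple(map(tuple, np.zeros((3, 3)))),
                        eps=(0.0,) * 5, mechanism=None, seed=0)
        ds = simulate_trial(cfg)
        lam = cfg.growth_spec.loadings
        expected = (lam @ (np.asarray(cfg.alpha)[:, None] +
                           np.asarray(cfg.arm_effects)[:, None] * ds.arm)).T
        np.testing.assert_allclose(ds.outcome, expected, atol=1e-10)

    def test_non_psd_psi_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(psi=((1.0, 0, 0), (0, -0.5, 0), (0, 0, 0.1)))

    def test_emulation_marginals_at_large_n(self):
        cfg = trial_emulation_defaults(n=100_000, seed=12, mechanism="MAR")
        ds = simulate_trial(cfg)
        y0 = ds.outcome[:, 0]
        assert abs(y0.mean() - 3.5) < 0.02
        assert abs(y0.std() - 1.78) < 0.02
        retention = ds.mask[:, 1:].mean(axis=0) * 100
        for got, target in zip(retention, (85, 81, 80, 65)):
            assert abs(got - target) < 2.0
        # declining mean outcome over time in both arms (observed cells)
        for arm in (0, 1):
            sel = ds.arm == arm
            m0 = ds.outcome[sel, 0].mean()
            m4 = ds.outcome[sel & ds.mask[:, 4], 4].mean()
            assert m4 < m0

    def test_null_arm_effect_gives_coincident_curves(self):
        cfg = SimConfig(n=60_000, arm_effects=(0.0, 0.0, 0.0),
                        mechanism=None, seed=3)
        ds = simulate_trial(cfg)
        diff = ds.outcome[ds.arm == 1].mean(axis=0) - \
            ds.outcome[ds.arm == 0].mean(axis=0)
        assert np.max(np.abs(diff)) < 0.05

    def test_default_config_satisfies_invariants(self):
        cfg = trial_emulation_defaults()
        assert np.linalg.eigvalsh(np.asarray(cfg.psi)).min() > -1e-12
        assert 0 < cfg.allocation < 1
        assert isinstance(cfg.seed, int)


class TestImposeMissingness:
    def test_zero_probability_masks_nothing(self):
        ds = simulate_trial(trial_emulation_defaults(n=300, seed=1,
                                                     mechanism="none"))
        out = impose_missingness(ds, MCARMechanism(p=(0, 0, 0, 0)), seed=0)
        assert out.mask.all()

    def test_mcar_fraction_matches_binomial(self):
        ds = simulate_trial(trial_emulation_defaults(n=50_000, seed=2,
                                                     mechanism="none"))
        out = impose_missingness(ds, MCARMechanism(p=(0.2, 0.2, 0.2, 0.2)),
                                 seed=9)
        frac = 1 - out.mask[:, 1:].mean(axis=0)
        np.testing.assert_allclose(frac, 0.2, atol=0.01)
        assert out.mask[:, 0].all()

    def test_mnar_dk_masks_higher_values(self):
        ds = simulate_trial(trial_emulation_defaults(n=30_000, seed=3,
                                                     mechanism="none"))
        mech = MNARDKMechanism(tau=(-2.5, -2.5, -2.5, -2.5), beta_prev=0.0,
                               beta_curr=0.6)
        out = impose_missingness(ds, mech, seed=11)
        for t in (1, 2, 3, 4):
            masked = ~out.mask[:, t]
            assert out.complete_outcome[masked, t].mean() > \
                out.complete_outcome[~masked, t].mean()

    def test_mnar_wc_requires_latent_factors(self):
        ds = simulate_trial(trial_emulation_defaults(n=100, seed=4,
                                                     mechanism="none"))
        stripped = ds
        stripped.latent = None
        with pytest.raises(ValueError):
            impose_missingness(stripped, MNARWCMechanism(tau=(-2,) * 4),
                               seed=0)

    def test_incomplete_input_rejected(self):
        ds = simulate_trial(trial_emulation_defaults(n=100, seed=5,
                                                     mechanism="MAR"))
        with pytest.raises(ValueError):
            impose_missingness(ds, MCARMechanism(), seed=0)

    def test_mcar_label_is_truthful(self):
        # under MCAR, masked and observed cells share the same distribution
        nonsig = 0
        reps = 20
        for r in range(reps):
            ds = simulate_trial(trial_emulation_defaults(n=2000, seed=100 + r,
                                                         mechanism="none"))
            out = impose_missingness(ds, MCARMechanism((0.3, 0.3, 0.3, 0.3)),
                                     seed=200 + r)
            masked = ~out.mask[:, 4]
            _, p = stats.ttest_ind(out.complete_outcome[masked, 4],
                                   out.complete_outcome[~masked, 4])
            nonsig += p > 0.05
        assert nonsig >= reps * 0.85

    def test_mechanism_swap_holds_outcomes_fixed(self):
        cfg_a = trial_emulation_defaults(n=500, seed=6, mechanism="MAR")
        cfg_b = trial_emulation_defaults(n=500, seed=6, mechanism="MNAR_DK")
        a, b = simulate_trial(cfg_a), simulate_trial(cfg_b)
        np.testing.assert_array_equal(a.complete_outcome, b.complete_outcome)
        assert not np.array_equal(a.mask, b.mask)

    def test_bounded_outcomes_respect_scale(self):
        cfg = SimConfig(n=5000, bounding="round", mechanism=None, seed=8)
        ds = simulate_trial(cfg)
        assert ds.outcome.min() >= 0.0 and ds.outcome.max() <= 12.0
        assert np.allclose(ds.outcome, np.round(ds.outcome))
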