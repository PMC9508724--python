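import numpy as np
import pandas as pd
import pytest

from lgmsens import LongitudinalDataset, trial_emulation_defaults, simulate_trial


def make_dataset(outcome, arm=None, covariates=None, latent=None):
    """Build a dataset from a (N, 5) array with NaN marking missing cells."""
    outcome = np.asarray(outcome, dtype=float)
    mask = ~np.isnan(outcome)
    if arm is None:
        arm = np.zeros(outcome.shape[0], dtype=int)
        arm[1::2] = 1
    cov = pd.DataFrame(covariates) if covariates is not None else None
    return LongitudinalDataset(outcome=outcome, mask=mask,
                               arm=np.asarray(arm, dtype=int),
                               covariates=cov, latent=latent)


@pytest.fixture(scope="session")
def emulated_trial():
    """A moderately sized trial with MAR attrition, shared across tests."""
    cfg = trial_emulation_defaults(n=1200, seed=7, mechanism="MAR")
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def complete_trial():
    """Same generator without any missingness imposed."""
    cfg = trial_emulation_defaults(n=800, seed=13, mechanism="none")
    return simulate_trial(cfg)
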