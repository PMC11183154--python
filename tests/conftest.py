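import numpy as np
import pytest
from hypothesis import settings

import lifttensor as lt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_planted():
    """A small planted rank-3 ground truth shared by cheap tests."""
    return lt.generate_planted_model(
        (12, 40, 2, 12, 10), R=3, group_effect_d=1.0, trial_slope=-0.02,
        seed=42, n_young=6)


@pytest.fixture(scope="session")
def small_noisy_tensor(small_planted):
    mt, metas = lt.generate_tensor_dataset(small_planted, snr_db=15, seed=42)
    return mt, metas


@pytest.fixture(scope="session")
def raw_trial_batch():
    """Two participants x two objects x two trials of raw signals."""
    metas = lt.generate_participants(2, 2, seed=7)
    trials = lt.generate_raw_trials(metas, trials_per_object=2, seed=7)
    return metas, trials


def random_nonneg_model(rng, dims, R):
    return lt.FactorModel(tuple(rng.uniform(0.0, 1.0, (d, R)) for d in dims))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
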