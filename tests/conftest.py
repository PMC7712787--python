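import numpy as np
import pytest

from nacresp import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort: ground truth propagates exactly."""
    config = CohortConfig(n_responders=3, n_nonresponders=5,
                          grid_shape=(32, 32, 32), noise_sigma=0.0, seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    config = CohortConfig(n_responders=3, n_nonresponders=5,
                          grid_shape=(32, 32, 32), noise_sigma=0.05, seed=43)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
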