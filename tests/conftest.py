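import numpy as np
import pytest

import meiqxkin as mk


@pytest.fixture(scope="session")
def nominal_params():
    """Dose-dependent reference parameter set used across tests."""
    return mk.default_true_params()


@pytest.fixture(scope="session")
def saturation_params():
    return mk.default_true_params(mode="saturation")


@pytest.fixture(scope="session")
def hl1_obs():
    return mk.hl1_dataset()


@pytest.fixture(scope="session")
def noise_free_obs(nominal_params):
    """Synthetic observations generated without noise from the nominal truth."""
    cfg = mk.GeneratorConfig(true_params=nominal_params, noise_sd_log=0.0, seed=123)
    return mk.generate_observations(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
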