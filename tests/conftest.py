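import numpy as np
import pytest

from thermacclim.fvcb import KineticConstants
from thermacclim.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def constants() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(sigma_a=0.0, cv_capacity=0.0,
                           sigma_topt_plot=0.0, sigma_topt_tree=0.0,
                           climate_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_config):
    """One noiseless two-species experiment, shared across tests."""
    return generate_experiment(noiseless_config, seed=101)


@pytest.fixture(scope="session")
def noisy_experiment():
    """One default-condition experiment, shared across tests."""
    return generate_experiment(SyntheticConfig(), seed=202)
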