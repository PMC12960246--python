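import numpy as np
import pandas as pd
import pytest

from acrotype.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default synthetic cohort shared across tests."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with perfect caller sensitivity and no false positives."""
    cfg = SimulationConfig(seed=23)
    return simulate_cohort(cfg, no_variant_noise=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
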