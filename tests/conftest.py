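import numpy as np
import pytest

from otquant import ValidationStudy, default_config, simulate_default_study


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def sim_study():
    """One complete synthetic study (records, profiles, truth, config)."""
    return simulate_default_study(1)


@pytest.fixture(scope="session")
def study_results(sim_study):
    records, profiles, truth, config = sim_study
    return ValidationStudy(records, config, profiles).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
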