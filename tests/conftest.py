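import numpy as np
import pytest

from fieldshift.reporting import prepare_cohorts
from fieldshift.synthetic import CohortConfig


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """Probe-trained cohort bundle at the study conditions (shared: training
    the probe once is enough for every evaluation-side test)."""
    return prepare_cohorts(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
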