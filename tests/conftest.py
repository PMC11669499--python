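import numpy as np
import pytest

from pedstriss.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """5,000 records whose outcomes are drawn exactly from the default
    coefficient set (no mortality offset): the well-specified case."""
    return generate_cohort(default_config(n=5000, seed=42, mortality_logit_offset=0.0))


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default (mortality-calibrated) configuration."""
    return generate_cohort(default_config(n=2000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
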