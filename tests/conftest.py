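import numpy as np
import pytest

from hncprog.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient default-process cohort shared across read-only tests."""
    return generate_cohort(default_config(n_patients=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
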