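import numpy as np
import pytest

from dfcdtx.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort with a planted effect, shared across tests."""
    config = SimConfig(n_per_group=4, T=150, seed=42)
    subjects, atlas, table = generate_cohort(config)
    return config, subjects, atlas, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
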