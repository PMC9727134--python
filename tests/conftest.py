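import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tsage.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """Default-parameter cohort used by read-only tests."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def fast_config():
    """Small cohort for Monte-Carlo loops: stats CpGs only."""
    return SimConfig(n_background_cpgs=1, n_dlk1_cpgs=1, beta_noise_sd=0.03, seed=0)


@pytest.fixture
def noise_free_config():
    return SimConfig(
        n_background_cpgs=1, n_dlk1_cpgs=1, beta_noise_sd=0.0,
        sperm_accel_oligo=0.0, blood_accel_oligo=0.0, seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
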