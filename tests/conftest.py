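import numpy as np
import pytest
from hypothesis import settings

import connpredict as cp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atlas40():
    """8-network, 40-node atlas with canonical labels."""
    return cp.scaled_canonical_atlas(40)


@pytest.fixture(scope="session")
def atlas60():
    return cp.scaled_canonical_atlas(60)


@pytest.fixture(scope="session")
def cohort60(atlas60):
    """Default-conditions synthetic cohort: 300 subjects, 60 nodes."""
    spec = cp.default_spec(atlas60, 300, noise_sd=0.5, seed=11)
    phen, edges = cp.simulate_cohort(spec)
    return spec, phen, edges


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
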