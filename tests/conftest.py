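import numpy as np
import pytest

from ursa.simulate import SimConfig, make_pedigree_panel, make_stack_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stack_fixture():
    """Planted-truth stack records, hits and outcome labels (seeded)."""
    return make_stack_fixtures(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pedigree_panel():
    """A small genotyped pedigree: 2 trios + 8 unrelated (seeded)."""
    return make_pedigree_panel(SimConfig(seed=11))
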