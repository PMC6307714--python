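import numpy as np
import pytest

from cgfold.fixtures import FixtureSpec, make_backbone
from cgfold.potentials import ParameterSet


@pytest.fixture(scope="session")
def random_pset():
    """One random smooth parameter set shared across tests (read-only)."""
    return ParameterSet.random(seed=3, scale=0.6)


@pytest.fixture(scope="session")
def helix10():
    return make_backbone(FixtureSpec(kind="helix", n_res=10))


@pytest.fixture(scope="session")
def helix20():
    return make_backbone(FixtureSpec(kind="helix", n_res=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
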