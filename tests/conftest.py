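import numpy as np
import pytest

from bars import (
    FixtureSpec,
    MCConfig,
    TOY_SCHEMA,
    WeightVector,
    make_native,
)


@pytest.fixture(scope="session")
def helix():
    """16-residue helical native, verified local minimum of the toy energy."""
    return make_native(FixtureSpec("helix", 16, 0))


@pytest.fixture(scope="session")
def helix_native(helix):
    return helix[1]


@pytest.fixture(scope="session")
def uniform_w():
    return WeightVector.uniform(TOY_SCHEMA)


@pytest.fixture
def quick_mc():
    """Small Monte Carlo budget for fast unit tests."""
    return MCConfig(max_steps=40, max_fail=15, window=3, sigma=10.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
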