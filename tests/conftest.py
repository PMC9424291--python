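import numpy as np
import pytest

from nafc import BoundarySpec, CostSpec, HypothesisModel


@pytest.fixture(scope="session")
def model3():
    return HypothesisModel.create(3)


@pytest.fixture(scope="session")
def model2():
    return HypothesisModel.create(2)


@pytest.fixture(scope="session")
def model4():
    return HypothesisModel.create(4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_spec():
    return BoundarySpec(family="flat", theta=0.9)


@pytest.fixture
def costs():
    return CostSpec(W=1.0, c=0.04)


def random_beliefs(rng, n, size):
    """Uniform (Dirichlet(1)) belief vectors on the (n-1)-simplex."""
    return rng.dirichlet(np.ones(n), size=size)
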