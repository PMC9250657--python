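import numpy as np
import pytest

from hexahwe import GenotypeCounts
from hexahwe.fixtures import WORKED_EXAMPLE_COUNTS


@pytest.fixture
def worked_counts() -> GenotypeCounts:
    return GenotypeCounts(np.asarray(WORKED_EXAMPLE_COUNTS, float))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_simplex(rng, size):
    return rng.dirichlet(np.ones(size))
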