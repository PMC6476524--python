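import itertools

import numpy as np
import pytest

from fitscape.landscape import CliffFunction, GroundTruthLandscape
from fitscape.library import build_library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_library():
    """3-site library with synonymous redundancy and a stop-producing site."""
    return build_library(
        [["Y", "Q"], ["L", "V", "M"], ["A", "V"]], segment_id="toy"
    )


@pytest.fixture
def two_state_vocab():
    return [["A", "V"], ["L", "I"], ["S", "T"], ["K", "R"], ["D", "E"]]


@pytest.fixture
def two_state_genotypes(two_state_vocab):
    return ["".join(c) for c in itertools.product(*two_state_vocab)]


@pytest.fixture
def additive_cliff_landscape(two_state_vocab):
    """Unidimensional cliff landscape with fixed, hand-set penalties."""
    coeffs = {}
    for i, states in enumerate(two_state_vocab):
        for s in states[1:]:
            coeffs[(i + 1, s)] = 0.8
    return GroundTruthLandscape(
        coefficients=coeffs,
        threshold_function=CliffFunction(plateau=1.0, threshold=2.0, steepness=0.1),
    )
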