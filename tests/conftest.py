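import numpy as np
import pytest

from phyloimpute import DistanceMatrix, make_instance


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def additive8():
    """Noise-free additive instance on 8 OTUs (fixed seed)."""
    return make_instance(8, seed=81)


@pytest.fixture
def small_matrix():
    """Hand-built symmetric 4x4 distance matrix."""
    v = np.array(
        [
            [0.0, 2.0, 4.0, 6.0],
            [2.0, 0.0, 4.5, 6.5],
            [4.0, 4.5, 0.0, 3.0],
            [6.0, 6.5, 3.0, 0.0],
        ]
    )
    return DistanceMatrix(("A", "B", "C", "D"), v)
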