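import numpy as np
import pytest

from gammamap import synth


@pytest.fixture(scope="session")
def mesh_small():
    """Coarse icosphere (162 vertices), 4 contiguous regions."""
    return synth.make_mesh(2, 4, seed=0)


@pytest.fixture(scope="session")
def mesh_fine():
    """Fine icosphere (2562 vertices, ~2.6 mm edges) for smoothing tests."""
    return synth.make_mesh(4, 5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
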