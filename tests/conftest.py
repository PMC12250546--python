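import numpy as np
import pytest

import plstomo as pt


@pytest.fixture(scope="session")
def small_system():
    """8-view parallel-beam projector on a 16x16 grid."""
    geom = pt.make_geometry(8, (0.0, np.pi), grid_size=16)
    A = pt.build_system_matrix(geom, 16)
    return geom, A


@pytest.fixture(scope="session")
def small_dictionary():
    return pt.build_dictionary(16, gammas=(0.15,))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
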