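import numpy as np
import pytest

import ggcflow as gf


@pytest.fixture(scope="session")
def icosphere2():
    return gf.make_icosphere(2)


@pytest.fixture(scope="session")
def icosphere3():
    return gf.make_icosphere(3)


@pytest.fixture(scope="session")
def icosphere4():
    return gf.make_icosphere(4)


@pytest.fixture(scope="session")
def bumpy3():
    """Asymmetric folded test surface with a non-degenerate low spectrum."""
    return gf.make_bumpy_surface(3, amplitude=0.3, frequency=6)


@pytest.fixture(scope="session")
def bumpy3_modes(bumpy3):
    return gf.solve_eigenmodes(bumpy3, n_modes=20)


@pytest.fixture(scope="session")
def sphere4_modes(icosphere4):
    return gf.solve_eigenmodes(icosphere4, n_modes=12)


@pytest.fixture
def single_triangle():
    return gf.TriangleMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )
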