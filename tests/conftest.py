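import numpy as np
import pytest

from ctgenome import build_topology_matrix, lloop_fixture, trefoil_series


@pytest.fixture(scope="session")
def lloop():
    """The canonical nine-contact L-loop contact set."""
    return lloop_fixture()


@pytest.fixture(scope="session")
def lloop_matrix(lloop):
    return build_topology_matrix(lloop)


@pytest.fixture(scope="session")
def trefoils5():
    return trefoil_series(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
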