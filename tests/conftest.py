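import numpy as np
import pytest
import scipy.sparse as sp

import polargcn as pg


@pytest.fixture(scope="session")
def grid():
    return pg.PolarGrid()


@pytest.fixture(scope="session")
def polar_graph():
    return pg.build_polar_adjacency()


@pytest.fixture(scope="session")
def hierarchy():
    return pg.polar_hierarchy(n_levels=3, seed=0)


def random_connected_graph(n: int, rng: np.random.Generator, p: float = 0.35) -> pg.Graph:
    """Random symmetric 0/1 graph with a guaranteed spanning path."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    for i in range(n - 1):  # spanning path keeps lambda_max > 0
        A[i, i + 1] = 1.0
    A = A + A.T
    return pg.make_graph(sp.csr_matrix(A))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
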