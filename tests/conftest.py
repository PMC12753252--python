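import numpy as np
import pytest

from dominet.network import BinaryNetwork


def binary_net(A: np.ndarray, weights: np.ndarray | None = None) -> BinaryNetwork:
    A = np.asarray(A)
    return BinaryNetwork(A=A.astype(int), weights=A.astype(float) if weights is None else weights)


@pytest.fixture
def complete_k4() -> BinaryNetwork:
    return binary_net(np.ones((4, 4)) - np.eye(4))


@pytest.fixture
def complete_k5() -> BinaryNetwork:
    return binary_net(np.ones((5, 5)) - np.eye(5))


@pytest.fixture
def star_k14() -> BinaryNetwork:
    """Star: node 0 is the hub, nodes 1-4 are leaves."""
    A = np.zeros((5, 5))
    A[0, 1:] = A[1:, 0] = 1
    return binary_net(A)


@pytest.fixture
def path_p4() -> BinaryNetwork:
    A = np.zeros((4, 4))
    for i in range(3):
        A[i, i + 1] = A[i + 1, i] = 1
    return binary_net(A)


def random_connected_net(rng: np.random.Generator, n: int, p: float = 0.3) -> BinaryNetwork:
    """Erdos-Renyi graph conditioned on connectivity (resampled until connected)."""
    import networkx as nx

    while True:
        A = (rng.random((n, n)) < p).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        g = nx.from_numpy_array(A)
        if A.sum() > 0 and nx.is_connected(g):
            return binary_net(A)
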