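import numpy as np
import pytest

from nmflink.net_core import Network, karate_network, read_edge_list


def network_from_edges(edges, n=None):
    """Build a Network from (i, j) integer pairs; labels are the indices."""
    nodes = {u for e in edges for u in e}
    size = n if n is not None else (max(nodes) + 1 if nodes else 0)
    a = np.zeros((size, size), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return Network(adjacency=a, labels=tuple(range(size)))


@pytest.fixture(scope="session")
def karate():
    return karate_network()


@pytest.fixture
def triangle():
    return read_edge_list(["a b", "b c", "c a"])


@pytest.fixture
def path3():
    # a - b - c
    return network_from_edges([(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return network_from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)])
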