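import numpy as np
import pytest

from netnonind import Network, generate_pa_network


@pytest.fixture
def rng():
    return np.random.default_rng(20230812)


@pytest.fixture
def path3() -> Network:
    return Network.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def tree20() -> Network:
    return generate_pa_network(20, 1, seed=7)


@pytest.fixture
def tree100() -> Network:
    return generate_pa_network(100, 1, seed=11)


def make_clique_pair(size: int, bridged: bool = True) -> Network:
    """Two cliques of ``size`` nodes, optionally joined by one bridge edge."""
    n = 2 * size
    edges = []
    for block in (range(size), range(size, n)):
        block = list(block)
        edges += [(i, j) for k, i in enumerate(block) for j in block[k + 1 :]]
    if bridged:
        edges.append((0, size))
    return Network.from_edges(n, edges)
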