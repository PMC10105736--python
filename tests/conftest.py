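import numpy as np
import pytest

from y2hnet.netcore import Network, Pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_net():
    """Small hand-checkable network: a 5-node module plus a pendant."""
    return Network.from_edges(
        [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
    )


def random_network(rng: np.random.Generator, n_nodes: int, n_edges: int) -> Network:
    """Uniform random simple graph used by property tests."""
    genes = [f"N{i:03d}" for i in range(n_nodes)]
    net = Network()
    for g in genes:
        net.add_node(g)
    attempts = 0
    while net.n_edges < n_edges and attempts < 50 * n_edges + 100:
        attempts += 1
        i, j = rng.choice(n_nodes, size=2, replace=False)
        net.add_edge(Pair(genes[i], genes[j]))
    return net
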