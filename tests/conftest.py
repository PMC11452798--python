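import numpy as np
import pytest

from innodiff.network import (
    SocialNetwork,
    distance_matrix,
    generate_constrained_network,
    path_laplacian_set,
)


@pytest.fixture(scope="session")
def net31():
    """Study-scale fixture network: 31 nodes, every node with ≥2 peers at
    distances 1 and 4 (the display-protocol constraints)."""
    return generate_constrained_network(31, seed=1)


@pytest.fixture(scope="session")
def dist31(net31):
    return distance_matrix(net31)


@pytest.fixture(scope="session")
def laps31(net31):
    return path_laplacian_set(net31)


@pytest.fixture()
def u0_4(net31):
    """Binary initial state with 4 innovation seeds (the 4/31 minority)."""
    rng = np.random.default_rng(42)
    u0 = np.zeros(net31.n)
    u0[rng.choice(net31.n, size=4, replace=False)] = 1.0
    return u0


def random_connected_graph(n, rng, p=None):
    """Erdős–Rényi conditioned on connectivity (resampled until connected)."""
    import networkx as nx

    p = p if p is not None else min(1.0, 2.5 / n)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return SocialNetwork.from_networkx(g, order=list(range(n)))
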