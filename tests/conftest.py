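import numpy as np
import pytest

import strepnet
from strepnet.network_metrics import InhibitionNetwork


def net_from_edges(edges, labels):
    """Small labeled digraph from an explicit edge list."""
    index = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=bool)
    for u, v in edges:
        adj[index[u], index[v]] = True
    return InhibitionNetwork(labels=tuple(labels), adjacency=adj)


@pytest.fixture
def rng():
    return np.random.default_rng(20231031)


@pytest.fixture
def chain_abc():
    return net_from_edges([("A", "B"), ("B", "C")], "ABC")


@pytest.fixture
def cycle_abc():
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "A")], "ABC")


@pytest.fixture
def complete_mutual_3():
    labels = "ABC"
    adj = np.ones((3, 3), dtype=bool)
    return InhibitionNetwork(labels=tuple(labels), adjacency=adj)


@pytest.fixture(scope="session")
def reference_communities():
    """Deterministic 3-community synthetic fixture (emulates A/B/C structure)."""
    return strepnet.synthetic_data.simulate_reference_communities(seed=20231031)


@pytest.fixture(scope="session")
def reference_networks(reference_communities):
    return {k: strepnet.build_network(m) for k, m in reference_communities.items()}


def random_network(rng, n_min=4, n_max=8):
    n = int(rng.integers(n_min, n_max + 1))
    m = int(rng.integers(0, n * (n - 1) + 1))
    return strepnet.sample_er(n, m, rng)
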