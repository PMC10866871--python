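import networkx as nx
import numpy as np
import pytest

from seqstack.temporal_graph import TemporalNetwork
from seqstack.tsbm import TSBMParams, generate_edge_correlated_tsbm


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_214)


@pytest.fixture
def path_graph():
    g = nx.path_graph(3)
    return g


@pytest.fixture
def random_net(rng):
    """A 50-node, 4-layer temporal network of independent G(n, p) layers."""
    layers = [
        nx.gnp_random_graph(50, 0.12, seed=int(rng.integers(2**31)))
        for _ in range(4)
    ]
    return TemporalNetwork(n=50, layers=layers)


@pytest.fixture(scope="session")
def small_tsbm_net():
    """One 60-node edge-correlated T-SBM realization shared across tests."""
    params = TSBMParams(
        n=60, L_plus_1=10, k=3, p=0.8, mu=0.1, c=8.0, variant="edge_correlated"
    )
    rng = np.random.default_rng(7)
    net, labels, used = generate_edge_correlated_tsbm(params, rng)
    return net, labels, used


@pytest.fixture
def er_null_net():
    """Ten independent Erdos-Renyi layers: no temporal signal at all."""
    layers = [nx.gnp_random_graph(60, 0.12, seed=1000 + t) for t in range(10)]
    return TemporalNetwork(n=60, layers=layers)
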