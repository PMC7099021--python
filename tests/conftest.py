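import warnings

import networkx as nx
import numpy as np
import pytest

import biasnet as bn


@pytest.fixture(autouse=True)
def _quiet_degenerate_mix_warnings():
    # many stress tests deliberately create tied mixes; keep output readable
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*degenerate.*")
        warnings.filterwarnings("ignore", message=".*exactly 1/2.*")
        yield


@pytest.fixture
def small_regular():
    """Connected 4-regular network on 30 nodes with a biased minority."""
    net, signals = bn.make_model_network(
        bn.ModelConfig(n=30, k=4, f=0.3, q=0.7, p=0.6, seed=42)
    )
    return net, signals


@pytest.fixture
def triangle_unbiased():
    """Fully connected 3-node unbiased network."""
    return bn.Network(graph=nx.complete_graph(3))


def make_custom_network(edges, biased=(), n=None):
    g = nx.Graph(edges)
    if n is not None:
        g.add_nodes_from(range(n))
    return bn.Network(graph=g, biased=frozenset(biased))


@pytest.fixture
def chamber_graph():
    """Seven nodes: pair {0,1} enclosed by biased {2,3}; bulk {4,5,6} unbiased.

    0-1 is an echo chamber (its only external contacts are biased); {4,5,6}
    is the larger, open part of the unbiased population.
    """
    edges = [(0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 5), (4, 6), (5, 6)]
    return make_custom_network(edges, biased={2, 3})
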