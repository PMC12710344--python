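import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mnetclass.netbuild import CorrelationNetwork
from mnetclass.preprocess import AbundanceTable


def make_network(edges, extra_nodes=()):
    """CorrelationNetwork from (u, v, rho) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, rho=float(w), p_adj=0.0)
    for n in extra_nodes:
        g.add_node(n)
    return CorrelationNetwork(graph=g, threshold=0.0, alpha=1.0)


def clique_edges(nodes, rho=1.0):
    nodes = list(nodes)
    return [
        (nodes[i], nodes[j], rho)
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]


@pytest.fixture
def counts_table():
    df = pd.DataFrame(
        {
            "s1": [2.0, 3.0, 5.0],
            "s2": [1.0, 1.0, 2.0],
            "s3": [4.0, 0.0, 6.0],
        },
        index=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(df)


@pytest.fixture
def random_relative_table():
    rng = np.random.default_rng(7)
    x = rng.gamma(2.0, 1.0, size=(12, 20))
    x /= x.sum(axis=0)
    df = pd.DataFrame(
        x,
        index=[f"t{i:02d}" for i in range(12)],
        columns=[f"s{j:02d}" for j in range(20)],
    )
    return AbundanceTable(df, is_relative=True)


@pytest.fixture
def two_cliques_network():
    edges = clique_edges(range(5)) + clique_edges(range(5, 10))
    edges.append((0, 5, 1.0))
    return make_network(edges)
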