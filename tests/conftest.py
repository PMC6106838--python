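import networkx as nx
import numpy as np
import pytest

import coremod as cm


@pytest.fixture(scope="session")
def example_net():
    return cm.example_network()


def net_from(edges):
    return cm.WeightedNetwork.from_edges(edges)


@pytest.fixture
def triangle():
    return net_from([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])


@pytest.fixture
def path_abc():
    return net_from([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def bowtie():
    # two triangles sharing node c
    return net_from(
        [
            ("a", "b", 1.0),
            ("a", "c", 1.0),
            ("b", "c", 1.0),
            ("c", "d", 1.0),
            ("c", "e", 1.0),
            ("d", "e", 1.0),
        ]
    )


def random_network(seed, n_max=12, p=0.35):
    """Random weighted network for property tests (connectedness not required)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    edges = [
        (f"n{u}", f"n{v}", float(rng.uniform(0.05, 1.0))) for u, v in g.edges()
    ]
    if not edges:
        edges = [("n0", "n1", 0.5)]
    return cm.WeightedNetwork.from_edges(edges)
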