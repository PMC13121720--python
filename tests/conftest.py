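"""Shared fixtures: small deterministic graphs used across the unit tests."""

import networkx as nx
import numpy as np
import pytest

from qnetcoloc.graph import Network


@pytest.fixture
def two_node_net() -> Network:
    g = nx.Graph([("A", "B")])
    return Network(g)


@pytest.fixture
def path_net() -> Network:
    """Path A–B–C–D–E."""
    return Network(nx.path_graph(["A", "B", "C", "D", "E"]))


@pytest.fixture
def star_net() -> Network:
    """Star with center C and leaves X, Y."""
    return Network(nx.Graph([("C", "X"), ("C", "Y")]))


def random_connected_net(n_nodes: int, seed: int, p: float = 0.05) -> Network:
    """Random connected graph for property tests (LCC of a G(n, p))."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31 - 1)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    return Network(nx.relabel_nodes(g, {i: f"N{i:04d}" for i in g.nodes}))


@pytest.fixture(scope="session")
def small_net() -> Network:
    """A 300-node scale-free-ish network shared by the slower unit tests."""
    g = nx.barabasi_albert_graph(300, 3, seed=11)
    return Network(nx.relabel_nodes(g, {i: f"N{i:04d}" for i in g.nodes}))
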