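"""Shared fixtures: small hand-built networks with known properties."""

import networkx as nx
import numpy as np
import pytest

from anatnet import AnatomicalNetwork, AnatomicalNode


@pytest.fixture
def two_triangles() -> AnatomicalNetwork:
    """Two triangles joined by a single bridge edge; the canonical
    two-module network (m=7, Q of the triangle split = 5/14)."""
    nodes = [
        AnatomicalNode("A1", "bone"),
        AnatomicalNode("A2", "bone"),
        AnatomicalNode("A3", "muscle"),
        AnatomicalNode("B1", "muscle"),
        AnatomicalNode("B2", "bone"),
        AnatomicalNode("B3", "muscle"),
    ]
    edges = [
        ("A1", "A2"), ("A2", "A3"), ("A1", "A3"),
        ("B1", "B2"), ("B2", "B3"), ("B1", "B3"),
        ("A3", "B1"),
    ]
    return AnatomicalNetwork(nodes, edges)


@pytest.fixture
def star4() -> AnatomicalNetwork:
    """4-node star: degrees (3,1,1,1), L = 1.5, H = sqrt(3)/3."""
    return AnatomicalNetwork(
        ["hub", "x", "y", "z"], [("hub", "x"), ("hub", "y"), ("hub", "z")]
    )


@pytest.fixture
def path4() -> AnatomicalNetwork:
    """4-node path: L = 5/3."""
    return AnatomicalNetwork(["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d")])


def random_network(n: int, p: float, seed: int, ensure_edge: bool = True) -> AnatomicalNetwork:
    """Seeded Erdős–Rényi network with mixed tissues/sides."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    if ensure_edge and g.number_of_edges() == 0:
        g.add_edge(0, 1 % n)
    tissues = ["bone", "muscle", "other"]
    sides = ["left", "right", "midline", "unspecified"]
    net = AnatomicalNetwork(
        [
            AnatomicalNode(
                f"n{i:02d}",
                tissues[int(rng.integers(3))],
                sides[int(rng.integers(4))],
            )
            for i in range(n)
        ]
    )
    for u, v in g.edges():
        net.add_edge(f"n{u:02d}", f"n{v:02d}")
    return net
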