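import random

import pytest

from pathminer.network_core import PPINetwork, build_network
from pathminer.string_io import ScoredInteraction, SeedSet


def net_from_edges(edges) -> PPINetwork:
    """Build a network from (a, b, score) triples."""
    return build_network([ScoredInteraction(a, b, s) for a, b, s in edges])


def random_edges(rng: random.Random, n_nodes: int, p: float = 0.25):
    """Random undirected scored edge list over nodes N00..N<n-1>, plus a
    spanning chain so the graph is connected."""
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [
        (a, b, rng.randint(150, 999))
        for a, b in zip(nodes, nodes[1:])
    ]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], rng.randint(150, 999)))
    return edges


@pytest.fixture
def triangle():
    """A-B (10), B-C (10), A-C (30): the two-hop route wins."""
    return net_from_edges([("A", "B", 990), ("B", "C", 990), ("A", "C", 970)])


@pytest.fixture
def star():
    """Hub H bridging four leaf seeds at score 999; leaves otherwise linked
    only by expensive scaffold edges."""
    leaves = ["S1", "S2", "S3", "S4"]
    edges = [("H", leaf, 999) for leaf in leaves]
    edges += [(a, b, 150) for a, b in zip(leaves, leaves[1:])]
    return net_from_edges(edges), SeedSet(frozenset(leaves))


@pytest.fixture
def chain():
    """S1 - X - S2 with a single intermediate connector."""
    return (
        net_from_edges([("S1", "X", 999), ("X", "S2", 999)]),
        SeedSet(frozenset(["S1", "S2"])),
    )
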