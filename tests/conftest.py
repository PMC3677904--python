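"""Shared fixtures: structured graphs with known optimal divisions and
seeded random graphs.  Everything is generated in-process; no data files."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from btseek import Network, Partition, default_spec, generate_planted


@pytest.fixture(scope="session")
def two_k5():
    """Two disjoint 5-cliques; the planted division is the two cliques."""
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    net = Network(a + b, list(combinations(a, 2)) + list(combinations(b, 2)))
    return net, Partition.from_groups([a, b])


@pytest.fixture(scope="session")
def k44():
    """Complete bipartite K_{4,4}; the planted division is the two sides."""
    left = [f"l{i}" for i in range(4)]
    right = [f"r{i}" for i in range(4)]
    net = Network(left + right, [(u, v) for u in left for v in right])
    return net, Partition.from_groups([left, right])


@pytest.fixture(scope="session")
def two_k3_bridge():
    """Two triangles joined by a single edge."""
    a = ["a0", "a1", "a2"]
    b = ["b0", "b1", "b2"]
    edges = list(combinations(a, 2)) + list(combinations(b, 2)) + [("a0", "b0")]
    return Network(a + b, edges), Partition.from_groups([a, b])


@pytest.fixture(scope="session")
def two_k4_bridge():
    """Two 4-cliques joined by a single edge (8 nodes, 13 edges)."""
    a = [f"p{i}" for i in range(4)]
    b = [f"q{i}" for i in range(4)]
    edges = list(combinations(a, 2)) + list(combinations(b, 2)) + [("p0", "q0")]
    return Network(a + b, edges), Partition.from_groups([a, b])


@pytest.fixture(scope="session")
def planted():
    """One realization of the default planted benchmark (seed 1)."""
    return generate_planted(default_spec(), seed=1)


@pytest.fixture(scope="session")
def random_graph_factory():
    """Seeded Erdos-Renyi generator returning (Network, rng)."""

    def make(n: int, p: float, seed: int) -> Network:
        rng = np.random.default_rng(seed)
        nodes = [f"v{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        return Network(nodes, edges)

    return make


def random_partition(nodes, k, seed):
    """Uniform random assignment of nodes into at most k modules."""
    rng = np.random.default_rng(seed)
    return Partition({v: int(rng.integers(1, k + 1)) for v in nodes})
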