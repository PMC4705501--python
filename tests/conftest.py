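"""Shared fixtures and independent oracles for the test suite.

The oracles recompute every quantity from the raw edge list with plain
arithmetic (no use of the package's incremental caches), so they stay
independent of the code paths they check.
"""

from __future__ import annotations

import itertools
import random

import pytest

from adm.graph_io import PPINetwork

TRIANGLES_EDGES = [("a", "b"), ("b", "c"), ("a", "c"),
                   ("x", "y"), ("y", "z"), ("x", "z")]
BRIDGE_EDGES = TRIANGLES_EDGES + [("c", "x")]


@pytest.fixture
def two_triangles() -> PPINetwork:
    return PPINetwork.from_edges(TRIANGLES_EDGES)


@pytest.fixture
def triangle_bridge() -> PPINetwork:
    return PPINetwork.from_edges(BRIDGE_EDGES)


# -- oracles -------------------------------------------------------------


def oracle_density(nodes, edges, blocks) -> float:
    """Density modularity evaluated term by term from the raw edge list."""
    L = len(edges)
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    D = 0.0
    for block in blocks:
        b = set(block)
        n = len(b)
        l = sum(1 for u, v in edges if u in b and v in b)
        d = sum(deg[x] for x in b)
        D += l * l / (n * n * L) - d ** 4 / (n * n * L ** 3)
    return D


def oracle_phi(edges, blocks) -> float:
    """Proportional objective sum l_i^2 / n_i^2 from the raw edge list."""
    total = 0.0
    for block in blocks:
        b = set(block)
        l = sum(1 for u, v in edges if u in b and v in b)
        total += l * l / (len(b) * len(b))
    return total


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number many)."""
    from sympy.utilities.iterables import multiset_partitions

    return multiset_partitions(sorted(items))


def random_graph(seed: int, max_nodes: int = 7):
    """Small Erdos-Renyi-style graph with at least one edge."""
    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    nodes = [f"v{i}" for i in range(n)]
    edges = [(u, v) for u, v in itertools.combinations(nodes, 2)
             if rng.random() < 0.5]
    if not edges:
        edges = [(nodes[0], nodes[1])]
    return nodes, edges


def random_membership(seed: int, nodes) -> dict[str, int]:
    """Random assignment of nodes to 1..n modules with no empty module."""
    rng = random.Random(seed)
    k = rng.randint(1, len(nodes))
    while True:
        memb = {v: rng.randrange(k) for v in nodes}
        used = sorted(set(memb.values()))
        if used:
            relabel = {m: i for i, m in enumerate(used)}
            return {v: relabel[m] for v, m in memb.items()}
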