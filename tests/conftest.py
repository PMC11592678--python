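"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from itertools import combinations

import networkx as nx
import pytest

from glhc import canonical_edge, fixture_fig1a, fixture_fig1e


@pytest.fixture
def fig1a():
    return fixture_fig1a()


@pytest.fixture
def fig1e():
    return fixture_fig1e()


def random_simple_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded G(n, p) with at least one edge (re-seeds until non-empty)."""
    for bump in range(100):
        g = nx.gnp_random_graph(n, p, seed=seed + 1000 * bump)
        if g.number_of_edges() > 0:
            return g
    raise RuntimeError("could not draw a non-empty graph")


def brute_force_edge_betweenness(g: nx.Graph) -> dict:
    """Oracle: exact-rational EB by enumerating every geodesic of every pair.

    Uses networkx's all_shortest_paths (independent of the package's BFS
    accumulation) and Fraction arithmetic throughout.
    """
    n = g.number_of_nodes()
    acc = {canonical_edge(u, v): Fraction(0) for u, v in g.edges()}
    for s, t in combinations(list(g), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        share = Fraction(1, len(paths))
        for path in paths:
            for a, b in zip(path, path[1:]):
                acc[canonical_edge(a, b)] += share
    denom = Fraction(n * (n - 1), 2)
    return {e: v / denom for e, v in acc.items()}


def brute_force_geodesic_count(g: nx.Graph, s, t) -> int:
    """Oracle: number of geodesics from s to t by exhaustive enumeration."""
    if s == t:
        return 1
    if not nx.has_path(g, s, t):
        return 0
    return sum(1 for _ in nx.all_shortest_paths(g, s, t))
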