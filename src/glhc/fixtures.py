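"""The two 13-node worked-example networks used throughout the docs and tests.

Both are small sparse graphs in which the edge (1, 2) is the single most
critical edge: it bridges two communities of comparable size.  The first
network contains one triangle {1, 2, 7}; the second is the same graph with
edge (2, 7) deleted, leaving no triangles at all — the regime in which purely
neighbourhood-overlap scores degenerate to zero on every edge.
"""

from __future__ import annotations

import networkx as nx

from .graph import validate_graph

__all__ = ["fixture_fig1a", "fixture_fig1e", "FIXTURES"]

# 13 nodes, 14 edges, one triangle {1, 2, 7}
_FIG1A_EDGES = [
    ("1", "7"), ("2", "7"), ("1", "4"), ("1", "5"), ("1", "6"),
    ("1", "13"), ("1", "2"), ("2", "8"), ("2", "9"), ("2", "11"),
    ("4", "3"), ("13", "3"), ("9", "10"), ("11", "12"),
]


def fixture_fig1a() -> nx.Graph:
    """Worked example 1: 13 nodes, 14 edges, triangle {1,2,7} bridged by (1,2)."""
    g = nx.Graph()
    g.add_edges_from(_FIG1A_EDGES)
    return validate_graph(g)


def fixture_fig1e() -> nx.Graph:
    """Worked example 2: the first network minus edge (2,7) — triangle-free."""
    g = fixture_fig1a()
    g.remove_edge("2", "7")
    return validate_graph(g)


FIXTURES = {"fig1a": fixture_fig1a, "fig1e": fixture_fig1e}
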