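"""Graph container, edge-list I/O and shortest-path machinery.

Graphs are undirected and simple (no self-loops, no parallel edges) and are
held as :class:`networkx.Graph` objects with opaque node labels.  Edges are
addressed everywhere through a canonical key — the pair ordered
lexicographically on the string form of the labels — so that rankings and
tie-breaks are deterministic regardless of insertion order.
"""

from __future__ import annotations

import os
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "canonical_edge",
    "load_edge_list",
    "write_edge_list",
    "validate_graph",
    "connected_components",
    "largest_component_fraction",
    "shortest_path_counts",
    "PathCountTable",
    "GraphValidationError",
    "EdgeListParseError",
]


class GraphValidationError(ValueError):
    """A graph violates the simple-undirected contract."""


class EdgeListParseError(ValueError):
    """An edge-list file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


def canonical_edge(u, v) -> tuple:
    """Return the edge ``{u, v}`` as a canonically ordered pair.

    Order is lexicographic on ``str(label)``; idempotent and symmetric:
    ``canonical_edge(u, v) == canonical_edge(v, u)``.
    """
    if u == v:
        raise GraphValidationError(f"self-loop on node {u!r} has no canonical edge key")
    return (u, v) if str(u) <= str(v) else (v, u)


def edge_sort_key(e: tuple) -> tuple[str, str]:
    """Total order on canonical edge keys (string-lexicographic)."""
    return (str(e[0]), str(e[1]))


def validate_graph(g: nx.Graph) -> nx.Graph:
    """Check the simple-undirected contract and return ``g`` unchanged.

    Raises :class:`GraphValidationError` on directed/multi graphs, self-loops
    or an empty node set.
    """
    if g.is_directed() or g.is_multigraph():
        raise GraphValidationError("graph must be undirected and simple")
    if g.number_of_nodes() < 1:
        raise GraphValidationError("graph must have at least one node")
    loops = list(nx.nodes_with_selfloops(g))
    if loops:
        raise GraphValidationError(f"self-loops found on nodes: {loops!r}")
    return g


def load_edge_list(path, delimiter: str | None = None, dedupe: bool = True) -> nx.Graph:
    """Read an undirected simple graph from a plain-text edge list.

    One edge per line, two whitespace- (or ``delimiter``-) separated node
    labels; lines starting with ``#`` and blank lines are skipped.  Duplicate
    lines and reversed duplicates collapse to a single edge when ``dedupe``
    is true (the default) and raise otherwise.  Self-loop lines always raise.
    Labels are kept as opaque strings, never coerced to numbers.

    Files ending in ``.graphml``/``.gml`` are read with the corresponding
    networkx reader instead.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".graphml":
        return validate_graph(nx.Graph(nx.read_graphml(path)))
    if ext == ".gml":
        return validate_graph(nx.Graph(nx.read_gml(path, label="label")))

    g = nx.Graph()
    seen: set[tuple] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            tokens = line.split(delimiter) if delimiter else line.split()
            tokens = [t for t in tokens if t]
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected two node labels, got {line!r}", lineno
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                raise GraphValidationError(f"line {lineno}: self-loop {u!r}-{v!r}")
            key = canonical_edge(u, v)
            if key in seen and not dedupe:
                raise EdgeListParseError(f"line {lineno}: duplicate edge {key!r}", lineno)
            seen.add(key)
            g.add_edge(u, v)
    if n_lines == 0:
        raise EdgeListParseError("empty edge list: no edges found")
    return validate_graph(g)


def write_edge_list(g: nx.Graph, path, header: str | None = None) -> None:
    """Write ``g`` as one canonical edge per line, sorted; round-trips with
    :func:`load_edge_list`."""
    validate_graph(g)
    edges = sorted((canonical_edge(u, v) for u, v in g.edges()), key=edge_sort_key)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in edges:
            fh.write(f"{u} {v}\n")


def connected_components(g: nx.Graph) -> list[set]:
    """Partition of the nodes into connected components, largest first."""
    validate_graph(g)
    return sorted(nx.connected_components(g), key=len, reverse=True)


def largest_component_fraction(g: nx.Graph, total_nodes: int) -> float:
    """Largest-component size divided by ``total_nodes``.

    ``total_nodes`` is the ORIGINAL network's node count: during percolation
    the normaliser stays fixed while the graph fragments.  Isolated nodes
    count as components of size one.
    """
    if total_nodes < 1:
        raise ValueError("total_nodes must be >= 1")
    if g.number_of_nodes() == 0:
        raise GraphValidationError("graph must have at least one node")
    largest = max(len(c) for c in nx.connected_components(g))
    if largest > total_nodes:
        raise ValueError("total_nodes smaller than the largest component")
    return largest / total_nodes


@dataclass
class PathCountTable:
    """Per-source geodesic bookkeeping from a breadth-first sweep.

    ``dist`` maps each reachable node to its geodesic distance from
    ``source``; ``sigma`` to its number of distinct shortest paths;
    ``predecessors`` to the nodes immediately preceding it on those paths.
    Unreachable nodes are simply absent from ``dist``.  ``bfs_order`` lists
    reachable nodes in non-decreasing distance — the reverse order needed by
    dependency accumulation.
    """

    source: object
    dist: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    predecessors: dict = field(default_factory=dict)
    bfs_order: list = field(default_factory=list)

    def is_reachable(self, node) -> bool:
        return node in self.dist


def shortest_path_counts(g: nx.Graph, source) -> PathCountTable:
    """BFS shortest-path counting from ``source`` (sigma/predecessor table)."""
    if source not in g:
        raise KeyError(f"source node {source!r} not in graph")
    table = PathCountTable(source=source)
    dist, sigma, preds = table.dist, table.sigma, table.predecessors
    dist[source] = 0
    sigma[source] = 1
    preds[source] = set()
    queue = deque([source])
    while queue:
        u = queue.popleft()
        table.bfs_order.append(u)
        du = dist[u]
        for w in g[u]:
            if w not in dist:  # first visit: fix the distance
                dist[w] = du + 1
                sigma[w] = 0
                preds[w] = set()
                queue.append(w)
            if dist[w] == du + 1:  # u lies on a geodesic to w
                sigma[w] += sigma[u]
                preds[w].add(u)
    return table
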