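"""Edge-percolation evaluation: ranking, removal curves, R and M.

A scoring method is judged by how fast the network falls apart when its
edges are deleted in descending order of importance.  Three summary
quantities are computed:

* the percolation curve ``xi_1 .. xi_E`` — the fraction of nodes in the
  largest connected component after each cumulative removal (the
  connectivity-degradation curve when plotted against the removed
  fraction);
* robustness ``R = mean(xi_l)`` — the area under that curve; LOWER R means
  the ranking dismantles the network faster, i.e. identifies critical
  edges better;
* monotonicity ``M = (1 - sum_i b_i (b_i - 1) / (E (E - 1)))**2`` over the
  tie-group sizes ``b_i`` of the score table — 1 when every edge gets a
  distinct score, 0 when all scores tie.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .graph import canonical_edge, edge_sort_key, largest_component_fraction, validate_graph
from .indices import EdgeScoreTable, score_all_edges

__all__ = [
    "RankedEdgeList",
    "PercolationCurve",
    "MonotonicityResult",
    "MethodReport",
    "rank_edges",
    "percolate",
    "robustness",
    "degradation_curve",
    "monotonicity",
    "evaluate_method",
]

#: Tie groups for M use exact equality at this tolerance on full-precision scores.
TIE_TOLERANCE = 1e-9


@dataclass
class RankedEdgeList:
    """Total removal order on a graph's edges, most important first."""

    order: list
    scores: EdgeScoreTable
    tie_policy: str = "canonical"

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order)


def rank_edges(scores: EdgeScoreTable, tie_policy: str = "canonical",
               seed: int | None = None) -> RankedEdgeList:
    """Order edges by descending score with a deterministic tie-break.

    ``tie_policy='canonical'`` (default) breaks ties by ascending canonical
    edge key; ``'shuffle'`` breaks them by a seeded random permutation, for
    sensitivity analysis on tie-heavy methods.
    """
    if len(scores) == 0:
        raise ValueError("cannot rank an empty score table")
    if tie_policy == "canonical":
        order = sorted(scores.scores,
                       key=lambda e: (-scores.scores[e], edge_sort_key(e)))
    elif tie_policy == "shuffle":
        rng = random.Random(seed)
        edges = list(scores.scores)
        rng.shuffle(edges)
        jitter = {e: r for r, e in enumerate(edges)}
        order = sorted(scores.scores, key=lambda e: (-scores.scores[e], jitter[e]))
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return RankedEdgeList(order=order, scores=scores, tie_policy=tie_policy)


@dataclass
class PercolationCurve:
    """Largest-component fractions after each cumulative edge removal."""

    xi: list
    E: int
    N: int
    xi0: float = 1.0  # intact-network fraction (< 1 on disconnected inputs)

    @property
    def removed_fraction(self) -> list:
        return [(l + 1) / self.E for l in range(self.E)]


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, a, b) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return self.size[ra]
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return self.size[ra]


def percolate(g: nx.Graph, order: RankedEdgeList | list) -> PercolationCurve:
    """Remove edges in the given static order, recording xi after each step.

    ``g`` is not mutated.  Computed backwards with a union-find: starting
    from the edgeless graph, edges are re-added in reverse removal order and
    the running largest-component size is recorded, which turns the whole
    curve into near-linear work in E.
    """
    validate_graph(g)
    seq = [canonical_edge(*e) for e in order]
    graph_edges = {canonical_edge(u, v) for u, v in g.edges()}
    if len(seq) != len(graph_edges) or set(seq) != graph_edges:
        raise ValueError("removal order is not a permutation of the graph's edges")
    n = g.number_of_nodes()
    uf = _UnionFind(g.nodes())
    largest = 1  # edgeless graph: all singletons
    # sizes_after_adding[k] = largest component with the last k edges present
    sizes = [largest]
    for e in reversed(seq):
        largest = max(largest, uf.union(*e))
        sizes.append(largest)
    E = len(seq)
    xi = [sizes[E - l] / n for l in range(1, E + 1)]
    return PercolationCurve(xi=xi, E=E, N=n, xi0=sizes[E] / n)


def robustness(curve: PercolationCurve) -> float:
    """R: the mean of xi_1 .. xi_E (area under the degradation curve)."""
    if curve.E == 0:
        raise ValueError("robustness undefined for an edgeless graph")
    return sum(curve.xi) / curve.E


def degradation_curve(g: nx.Graph, order: RankedEdgeList | list) -> list[tuple[float, float]]:
    """(removed fraction, largest-component fraction) pairs, with the intact
    network prepended at fraction 0."""
    curve = percolate(g, order)
    start = largest_component_fraction(g, curve.N)
    return [(0.0, start)] + list(zip(curve.removed_fraction, curve.xi))


@dataclass
class MonotonicityResult:
    """Monotonicity M with the tie-group sizes it was computed from."""

    M: float
    tie_group_sizes: list
    E: int


def monotonicity(scores: EdgeScoreTable, tolerance: float = TIE_TOLERANCE) -> MonotonicityResult:
    """M over the tie structure of the full-precision scores.

    Edges whose scores differ by at most ``tolerance`` (transitively, after
    sorting) fall in one tie group; rounding for display never manufactures
    ties here.
    """
    E = len(scores)
    if E < 2:
        raise ValueError("monotonicity needs at least 2 edges")
    vals = sorted(scores.scores.values(), reverse=True)
    groups = []
    current = 1
    for prev, cur in zip(vals, vals[1:]):
        if abs(prev - cur) <= tolerance:
            current += 1
        else:
            groups.append(current)
            current = 1
    groups.append(current)
    penalty = sum(b * (b - 1) for b in groups) / (E * (E - 1))
    return MonotonicityResult(M=(1.0 - penalty) ** 2, tie_group_sizes=groups, E=E)


@dataclass
class MethodReport:
    """One-shot evaluation of a method on a graph: R, M and the curve."""

    method: str
    R: float
    M: float
    curve: PercolationCurve
    ranking: RankedEdgeList = field(repr=False, default=None)

    def summary(self) -> dict:
        return {"method": self.method, "R": self.R, "M": self.M,
                "E": self.curve.E, "N": self.curve.N}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def curve_frame(self) -> pd.DataFrame:
        pts = [(0.0, self.curve.xi0)] + list(
            zip(self.curve.removed_fraction, self.curve.xi))
        return pd.DataFrame(pts, columns=["fraction_removed", "lcc_fraction"])


def evaluate_method(g: nx.Graph, method: str, tie_policy: str = "canonical",
                    seed: int | None = None, **weights) -> MethodReport:
    """Score -> rank -> percolate -> {R, M, curve} for one method on one graph."""
    table = score_all_edges(g, method, **weights)
    ranking = rank_edges(table, tie_policy=tie_policy, seed=seed)
    curve = percolate(g, ranking)
    m = monotonicity(table).M if len(table) >= 2 else None  # undefined on 1 edge
    return MethodReport(method=table.method, R=robustness(curve),
                        M=m, curve=curve, ranking=ranking)
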