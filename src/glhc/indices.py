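"""Edge-importance indices.

Implements the full family of edge scorers compared in the critical-edge
literature, on undirected simple graphs:

* ``DP`` — degree product, ``k_i * k_j``.
* ``EB`` — edge betweenness: the mean, over unordered node pairs, of the
  fraction of geodesics between the pair that traverse the edge.  Computed
  in one pass by dependency accumulation over per-source BFS path counts.
* ``BN`` — bridgeness, ``S_i * S_j / S_e`` where ``S_x`` is the size of the
  largest clique containing node (or edge) ``x``.
* ``DI`` — diffusion intensity: the mean number of exclusive neighbours of
  the two endpoints (neighbours of one endpoint not adjacent to the other).
* ``EI`` — a motif/path-length composite (triangles and three quadrilateral
  classes through the edge, times the change in mean geodesic distance when
  the edge is contracted).
* ``FN`` — first-order neighbourhood: Jaccard overlap of the endpoint
  neighbour sets after removing each other.
* ``SN`` — second-order neighbourhood: Jaccard overlap of the sets of nodes
  reachable by a two-step walk whose intermediate node is not the opposite
  endpoint.
* ``EN`` — enhanced neighbourhood, ``2*SN + 3*FN``.
* ``GLHC`` — global-local hybrid centrality, ``3*EB + SN + 1.5*FN``, the
  composite that couples the global bridge signal of betweenness with the
  local community signal of neighbourhood overlap.

All indices point the same way: a HIGHER score means a MORE important edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .graph import canonical_edge, edge_sort_key, shortest_path_counts, validate_graph

__all__ = [
    "EdgeLocalContext",
    "CliqueSizes",
    "EIComponents",
    "EdgeScoreTable",
    "local_context",
    "first_order_index",
    "second_order_index",
    "enhanced_neighborhood",
    "edge_betweenness",
    "degree_product",
    "bridgeness",
    "diffusion_intensity",
    "ei_components",
    "edge_importance_EI",
    "glhc",
    "score_all_edges",
    "METHODS",
    "round_half_up",
]

#: Recognised method names, in the order the comparison tables list them.
METHODS = ("EB", "DP", "DI", "BN", "EI", "SN", "FN", "EN", "GLHC")

#: Default mixing weights: EN = 2*SN + 3*FN; GLHC = 3*EB + 1*SN + (3/2)*FN.
EN_WEIGHTS = (2.0, 3.0)
GLHC_WEIGHTS = (3.0, 1.0, 1.5)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how score tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_edge(g: nx.Graph, e) -> tuple:
    u, v = e
    if not g.has_edge(u, v):
        raise KeyError(f"edge {e!r} not in graph")
    return u, v


# ---------------------------------------------------------------------------
# Local neighbourhood context
# ---------------------------------------------------------------------------

@dataclass
class EdgeLocalContext:
    """First- and second-order neighbourhood structure around one edge.

    ``N_i_excl_j`` is the neighbour set of ``i`` with ``j`` removed; the
    second-order set ``NN_i_excl_j`` contains every node ``w != i`` reachable
    by a length-2 walk ``i -> u -> w`` whose intermediate ``u`` is not ``j``
    (the endpoint ``w`` may be ``j`` itself, or a first-order neighbour).
    ``n_i_ex_j`` counts neighbours of ``i`` (excluding ``j``) that are not
    adjacent to ``j``.
    """

    edge: tuple
    N_i_excl_j: frozenset
    N_j_excl_i: frozenset
    NN_i_excl_j: frozenset
    NN_j_excl_i: frozenset
    n_i_ex_j: int
    n_j_ex_i: int


def _second_order_set(g: nx.Graph, i, j) -> frozenset:
    # walks i -> u -> w with u != j; w may equal j, w never equals i
    out: set = set()
    for u in g[i]:
        if u == j:
            continue
        out.update(g[u])
    out.discard(i)
    return frozenset(out)


def local_context(g: nx.Graph, e) -> EdgeLocalContext:
    """Compute the :class:`EdgeLocalContext` of edge ``e`` in ``g``."""
    i, j = _require_edge(g, e)
    n_i = frozenset(w for w in g[i] if w != j)
    n_j = frozenset(w for w in g[j] if w != i)
    adj_j = set(g[j])
    adj_i = set(g[i])
    return EdgeLocalContext(
        edge=canonical_edge(i, j),
        N_i_excl_j=n_i,
        N_j_excl_i=n_j,
        NN_i_excl_j=_second_order_set(g, i, j),
        NN_j_excl_i=_second_order_set(g, j, i),
        n_i_ex_j=sum(1 for w in n_i if w not in adj_j),
        n_j_ex_i=sum(1 for w in n_j if w not in adj_i),
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0  # empty-union convention
    return len(a & b) / union


def first_order_index(g: nx.Graph, e) -> float:
    """FN: Jaccard of the two reduced neighbour sets; 0 on an empty union."""
    ctx = local_context(g, e)
    return _jaccard(ctx.N_i_excl_j, ctx.N_j_excl_i)


def second_order_index(g: nx.Graph, e) -> float:
    """SN: Jaccard of the two second-order walk sets; 0 on an empty union."""
    ctx = local_context(g, e)
    return _jaccard(ctx.NN_i_excl_j, ctx.NN_j_excl_i)


def enhanced_neighborhood(g: nx.Graph, e, w_sn: float = EN_WEIGHTS[0],
                          w_fn: float = EN_WEIGHTS[1]) -> float:
    """EN: the weighted local composite ``w_sn*SN + w_fn*FN`` (defaults 2, 3)."""
    if w_sn < 0 or w_fn < 0:
        raise ValueError("weights must be non-negative")
    ctx = local_context(g, e)
    return (w_sn * _jaccard(ctx.NN_i_excl_j, ctx.NN_j_excl_i)
            + w_fn * _jaccard(ctx.N_i_excl_j, ctx.N_j_excl_i))


# ---------------------------------------------------------------------------
# Global index: edge betweenness
# ---------------------------------------------------------------------------

def edge_betweenness(g: nx.Graph, normalized: bool = True) -> "EdgeScoreTable":
    """Edge betweenness of every edge, by dependency accumulation.

    One BFS + reverse accumulation per source node.  The raw accumulation
    counts each unordered pair from both ends, so the per-pair sum of
    geodesic fractions is ``raw / 2``; with ``normalized`` (the default) it
    is further divided by the ``N(N-1)/2`` unordered pairs, giving scores in
    ``[0, 1]``.  Pairs in different components contribute nothing, while
    ``N`` stays the full node count.
    """
    validate_graph(g)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("edge betweenness needs at least 2 nodes")
    acc = {canonical_edge(u, v): 0.0 for u, v in g.edges()}
    for s in g.nodes():
        table = shortest_path_counts(g, s)
        sigma, preds = table.sigma, table.predecessors
        delta = dict.fromkeys(table.bfs_order, 0.0)
        for w in reversed(table.bfs_order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for p in preds[w]:
                c = sigma[p] * coeff
                acc[canonical_edge(p, w)] += c
                delta[p] += c
    denom = float(n * (n - 1)) if normalized else 2.0
    scores = {e: val / denom for e, val in acc.items()}
    return EdgeScoreTable(method="EB", scores=scores)


# ---------------------------------------------------------------------------
# Other baselines
# ---------------------------------------------------------------------------

def degree_product(g: nx.Graph, e) -> float:
    """DP: product of the endpoint degrees."""
    i, j = _require_edge(g, e)
    return float(g.degree[i] * g.degree[j])


@dataclass
class CliqueSizes:
    """Largest-clique sizes at the two endpoints and through the edge."""

    S_i: int
    S_j: int
    S_e: int


def clique_sizes(g: nx.Graph, e) -> CliqueSizes:
    """Exact largest-clique sizes via maximal-clique enumeration.

    Uses Bron-Kerbosch with pivoting (exponential worst case; fine at the
    sparse desk scales this package targets).
    """
    i, j = _require_edge(g, e)
    s_i = s_j = 1
    s_e = 2  # the edge itself is a 2-clique
    for clique in nx.find_cliques(g):
        size = len(clique)
        members = set(clique)
        if i in members:
            s_i = max(s_i, size)
        if j in members:
            s_j = max(s_j, size)
        if i in members and j in members:
            s_e = max(s_e, size)
    return CliqueSizes(S_i=s_i, S_j=s_j, S_e=s_e)


def bridgeness(g: nx.Graph, e) -> float:
    """BN: ``S_i * S_j / S_e`` from exact clique sizes."""
    cs = clique_sizes(g, e)
    return cs.S_i * cs.S_j / cs.S_e


def diffusion_intensity(g: nx.Graph, e) -> float:
    """DI: mean count of endpoint-exclusive neighbours, ``(n_i_ex_j + n_j_ex_i)/2``."""
    ctx = local_context(g, e)
    return (ctx.n_i_ex_j + ctx.n_j_ex_i) / 2.0


# ---------------------------------------------------------------------------
# EI: motif + path-length composite
# ---------------------------------------------------------------------------

@dataclass
class EIComponents:
    """Motif counts and mean-geodesic terms entering the EI score.

    Actual counts enumerate 3- and 4-node subgraphs through the edge:
    triangles; chordless 4-cycles ("empty quadrilaterals"); 4-cycles with
    one chord, split by whether the edge is the chord (``diag_quad_inner``)
    or a cycle edge (``diag_quad_outer``); and K4s.  Maxima are degree
    bounds: ``min(k_i, k_j) - 1`` for triangles, ``(k_i-1)(k_j-1)`` for each
    quadrilateral class.  ``L``/``L_prime`` are mean geodesic distances over
    connected node pairs before/after contracting the edge.
    """

    tri_act: int
    empty_quad_act: int
    diag_quad_outer_act: int
    diag_quad_inner_act: int
    full_quad_act: int
    tri_max: int
    empty_quad_max: int
    diag_quad_outer_max: int
    diag_quad_inner_max: int
    full_quad_max: int
    L: float
    L_prime: float

    @property
    def actual_total(self) -> int:
        return (self.tri_act + self.empty_quad_act + self.diag_quad_outer_act
                + self.diag_quad_inner_act + self.full_quad_act)

    @property
    def max_total(self) -> int:
        return (self.tri_max + self.empty_quad_max + self.diag_quad_outer_max
                + self.diag_quad_inner_max + self.full_quad_max)


def mean_geodesic_distance(g: nx.Graph) -> float:
    """Mean geodesic distance over connected node pairs; 0 if no such pair."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    adj = nx.to_scipy_sparse_array(g, format="csr", dtype=np.int8)
    dist = _csgraph_sp(adj, method="D", unweighted=True, directed=False)
    finite = np.isfinite(dist) & (dist > 0)
    if not finite.any():
        return 0.0
    return float(dist[finite].mean())  # each pair twice; mean unaffected


def ei_components(g: nx.Graph, e) -> EIComponents:
    """Enumerate the motif counts and path-length terms for EI at edge ``e``."""
    i, j = _require_edge(g, e)
    adj_i, adj_j = set(g[i]), set(g[j])
    tri_act = len((adj_i & adj_j) - {i, j})

    others = [w for w in g.nodes() if w != i and w != j]
    empty = outer = inner = full = 0
    # classify the induced subgraph on {i, j, x, y} for every pair {x, y}
    for a in range(len(others)):
        x = others[a]
        x_i, x_j = x in adj_i, x in adj_j
        adj_x = set(g[x])
        for b in range(a + 1, len(others)):
            y = others[b]
            y_i, y_j = y in adj_i, y in adj_j
            xy = y in adj_x
            n_edges = 1 + x_i + x_j + y_i + y_j + xy
            if n_edges < 4:
                continue
            deg_i = 1 + x_i + y_i
            deg_j = 1 + x_j + y_j
            deg_x = x_i + x_j + xy
            deg_y = y_i + y_j + xy
            if n_edges == 4:
                # chordless 4-cycle iff 2-regular
                if deg_i == deg_j == deg_x == deg_y == 2:
                    empty += 1
            elif n_edges == 5:
                # one-chord 4-cycle; the chord joins the two degree-3 nodes
                if deg_i == 3 and deg_j == 3:
                    inner += 1
                else:
                    outer += 1
            else:
                full += 1

    k_i, k_j = g.degree[i], g.degree[j]
    quad_max = (k_i - 1) * (k_j - 1)
    L = mean_geodesic_distance(g)
    merged = nx.contracted_nodes(g, i, j, self_loops=False)
    L_prime = mean_geodesic_distance(nx.Graph(merged))
    return EIComponents(
        tri_act=tri_act, empty_quad_act=empty, diag_quad_outer_act=outer,
        diag_quad_inner_act=inner, full_quad_act=full,
        tri_max=min(k_i, k_j) - 1, empty_quad_max=quad_max,
        diag_quad_outer_max=quad_max, diag_quad_inner_max=quad_max,
        full_quad_max=quad_max, L=L, L_prime=L_prime,
    )


def edge_importance_EI(g: nx.Graph, e) -> float:
    """EI: (actual motifs / maximal motifs) x |L - L'|; 0 when no motif is possible."""
    c = ei_components(g, e)
    if c.max_total <= 0:
        return 0.0
    return (c.actual_total / c.max_total) * abs(c.L - c.L_prime)


# ---------------------------------------------------------------------------
# GLHC composite and the score table
# ---------------------------------------------------------------------------

@dataclass
class EdgeScoreTable:
    """Scores of every edge of one graph under one method.

    ``scores`` maps canonical edge keys to full-precision floats;
    ``weights`` records any mixing constants in force (EN, GLHC).
    """

    method: str
    scores: dict = field(default_factory=dict)
    weights: tuple | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, e) -> float:
        return self.scores[canonical_edge(*e)]

    def rounded(self, ndigits: int = 2) -> dict:
        """Half-away-from-zero rounded copy of the score map (presentation)."""
        return {e: round_half_up(s, ndigits) for e, s in self.scores.items()}

    def to_frame(self, round_to: int | None = None) -> pd.DataFrame:
        """Ranked DataFrame with columns node_u, node_v, score, rank.

        Descending by score; ties broken by canonical edge key ascending.
        """
        items = sorted(self.scores.items(),
                       key=lambda kv: (-kv[1], edge_sort_key(kv[0])))
        rows = [
            {"node_u": str(e[0]), "node_v": str(e[1]),
             "score": round_half_up(s, round_to) if round_to is not None else s,
             "rank": r}
            for r, (e, s) in enumerate(items, start=1)
        ]
        return pd.DataFrame(rows, columns=["node_u", "node_v", "score", "rank"])

    def to_csv(self, path, round_to: int | None = None) -> None:
        self.to_frame(round_to=round_to).to_csv(path, index=False)


def glhc(g: nx.Graph, w_eb: float = GLHC_WEIGHTS[0], w_sn: float = GLHC_WEIGHTS[1],
         w_fn: float = GLHC_WEIGHTS[2]) -> EdgeScoreTable:
    """GLHC score of every edge: ``w_eb*EB + w_sn*SN + w_fn*FN``.

    Defaults (3, 1, 3/2) blend the global betweenness signal with the two
    local overlap signals; a single betweenness pass is shared by all edges.
    """
    if min(w_eb, w_sn, w_fn) < 0:
        raise ValueError("weights must be non-negative")
    eb = edge_betweenness(g)
    scores = {}
    for e in eb.scores:
        ctx = local_context(g, e)
        scores[e] = (w_eb * eb.scores[e]
                     + w_sn * _jaccard(ctx.NN_i_excl_j, ctx.NN_j_excl_i)
                     + w_fn * _jaccard(ctx.N_i_excl_j, ctx.N_j_excl_i))
    return EdgeScoreTable(method="GLHC", scores=scores, weights=(w_eb, w_sn, w_fn))


_PER_EDGE = {
    "FN": first_order_index,
    "SN": second_order_index,
    "DP": degree_product,
    "BN": bridgeness,
    "DI": diffusion_intensity,
    "EI": edge_importance_EI,
}


def score_all_edges(g: nx.Graph, method: str, **weights) -> EdgeScoreTable:
    """Score every edge of ``g`` under ``method`` (one of :data:`METHODS`).

    ``weights`` forwards mixing constants to EN (``w_sn``, ``w_fn``) and
    GLHC (``w_eb``, ``w_sn``, ``w_fn``).
    """
    name = method.upper()
    if name not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    validate_graph(g)
    if name == "EB":
        return edge_betweenness(g)
    if name == "GLHC":
        return glhc(g, **weights)
    if name == "EN":
        scores = {canonical_edge(u, v): enhanced_neighborhood(g, (u, v), **weights)
                  for u, v in g.edges()}
        w = (weights.get("w_sn", EN_WEIGHTS[0]), weights.get("w_fn", EN_WEIGHTS[1]))
        return EdgeScoreTable(method="EN", scores=scores, weights=w)
    fn = _PER_EDGE[name]
    scores = {canonical_edge(u, v): fn(g, (u, v)) for u, v in g.edges()}
    return EdgeScoreTable(method=name, scores=scores)
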