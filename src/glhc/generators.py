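"""Seeded random-graph families (ER, BA, WS) and topology summaries.

The three classical ensembles let the percolation evaluation run without any
external network downloads:

* Erdős–Rényi G(n, p): every node pair is an edge independently with
  probability p (Poisson-like degree distribution).
* Barabási–Albert: growth with preferential attachment from m isolated seed
  nodes, each arrival wiring m edges to distinct existing nodes with
  probability proportional to degree, so E = m(n - m) exactly (power-law
  degrees).
* Watts–Strogatz: ring lattice with k neighbours per node, each lattice
  edge rewired with probability p, so E = nk/2 exactly (small-world).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx

from .graph import validate_graph

__all__ = [
    "GeneratorSpec",
    "NetworkSummary",
    "erdos_renyi",
    "barabasi_albert",
    "watts_strogatz",
    "generate",
    "network_summary",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """A reproducible recipe for one random graph.

    ``p`` is the edge probability (ER) or rewiring probability (WS); ``m``
    the edges per arriving node (BA); ``k`` the even ring-neighbour count
    (WS).  Same spec + same seed => identical graph.
    """

    model: str
    n: int
    p: float | None = None
    m: int | None = None
    k: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def erdos_renyi(n: int, p: float, seed: int | None = None) -> nx.Graph:
    """G(n, p) random graph."""
    if n < 1 or not 0.0 <= p <= 1.0:
        raise ValueError("ER requires n >= 1 and 0 <= p <= 1")
    g = nx.gnp_random_graph(n, p, seed=seed)
    return validate_graph(g)


def barabasi_albert(n: int, m: int, seed: int | None = None) -> nx.Graph:
    """Preferential-attachment graph with exactly m(n - m) edges."""
    if not 1 <= m < n:
        raise ValueError("BA requires 1 <= m < n")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return validate_graph(g)


def watts_strogatz(n: int, k: int, p: float, seed: int | None = None) -> nx.Graph:
    """Rewired ring lattice with exactly nk/2 edges."""
    if k % 2 != 0 or not 0 < k < n or not 0.0 <= p <= 1.0:
        raise ValueError("WS requires even k with 0 < k < n and 0 <= p <= 1")
    g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    return validate_graph(g)


def generate(spec: GeneratorSpec) -> nx.Graph:
    """Build the graph a :class:`GeneratorSpec` describes."""
    model = spec.model.upper()
    if model == "ER":
        return erdos_renyi(spec.n, spec.p, seed=spec.seed)
    if model == "BA":
        return barabasi_albert(spec.n, spec.m, seed=spec.seed)
    if model == "WS":
        return watts_strogatz(spec.n, spec.k, spec.p, seed=spec.seed)
    raise ValueError(f"unknown model {spec.model!r}; valid: ER, BA, WS")


@dataclass
class NetworkSummary:
    """Topology summary: N, E, mean degree, clustering C, assortativity r.

    ``clustering`` is the average LOCAL clustering coefficient (nodes of
    degree < 2 contribute 0); ``assortativity`` is the Pearson correlation
    of endpoint degrees over edges, ``None`` when degree variance is zero
    (regular graphs), where it is undefined.
    """

    N: int
    E: int
    mean_degree: float
    clustering: float
    assortativity: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def network_summary(g: nx.Graph) -> NetworkSummary:
    """Compute the :class:`NetworkSummary` of ``g``."""
    validate_graph(g)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2 or e < 1:
        raise ValueError("summary needs at least 2 nodes and 1 edge")
    degrees = {d for _, d in g.degree()}
    if len(degrees) == 1:
        r = None  # regular graph: zero degree variance
    else:
        r = float(nx.degree_assortativity_coefficient(g))
    return NetworkSummary(
        N=n, E=e, mean_degree=2.0 * e / n,
        clustering=float(nx.average_clustering(g)),
        assortativity=r,
    )


def transitivity(g: nx.Graph) -> float:
    """Global clustering (3 x triangles / triads), the other C convention."""
    return float(nx.transitivity(g))
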