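"""Edge-importance indices: worked examples, oracles and invariants."""

from itertools import combinations

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from glhc import (
    METHODS,
    bridgeness,
    canonical_edge,
    degree_product,
    diffusion_intensity,
    edge_betweenness,
    edge_importance_EI,
    enhanced_neighborhood,
    first_order_index,
    glhc,
    local_context,
    round_half_up,
    score_all_edges,
    second_order_index,
)
from glhc.indices import clique_sizes, ei_components, mean_geodesic_distance
from .conftest import random_simple_graph


def isolated_edge():
    return nx.Graph([("a", "b")])


class TestLocalContext:
    def test_fig1a_edge_1_2(self, fig1a):
        ctx = local_context(fig1a, ("1", "2"))
        assert ctx.N_i_excl_j == frozenset("4 5 6 7 13".split())
        assert ctx.N_j_excl_i == frozenset("7 8 9 11".split())
        assert ctx.n_i_ex_j == 4  # node 7 is adjacent to 2
        assert ctx.n_j_ex_i == 3

    def test_fig1a_edge_1_7_second_order_sets(self, fig1a):
        ctx = local_context(fig1a, ("1", "7"))
        assert ctx.NN_i_excl_j == frozenset("3 7 8 9 11".split())
        assert ctx.NN_j_excl_i == frozenset("1 8 9 11".split())

    def test_isolated_edge_is_empty(self):
        ctx = local_context(isolated_edge(), ("a", "b"))
        assert not ctx.N_i_excl_j and not ctx.N_j_excl_i
        assert not ctx.NN_i_excl_j and not ctx.NN_j_excl_i
        assert ctx.n_i_ex_j == 0 and ctx.n_j_ex_i == 0

    def test_missing_edge_raises(self, fig1a):
        with pytest.raises(KeyError):
            local_context(fig1a, ("5", "6"))


class TestFirstOrderIndex:
    def test_triangle_is_one(self):
        assert first_order_index(nx.complete_graph(3), (0, 1)) == 1.0

    def test_isolated_edge_empty_union_is_zero(self):
        assert first_order_index(isolated_edge(), ("a", "b")) == 0.0

    def test_fig1a_edge_1_2(self, fig1a):
        assert first_order_index(fig1a, ("1", "2")) == pytest.approx(1 / 8)


class TestSecondOrderIndex:
    @pytest.mark.parametrize("edge,expected", [(("1", "7"), 0.5), (("2", "7"), 0.5),
                                               (("1", "2"), 0.0)])
    def test_fig1a_printed_values(self, fig1a, edge, expected):
        assert second_order_index(fig1a, edge) == pytest.approx(expected)

    def test_bare_path_is_zero(self):
        g = nx.path_graph(["a", "b", "c"])
        assert second_order_index(g, ("a", "b")) == 0.0


class TestEnhancedNeighborhood:
    def test_fig1a_printed_values(self, fig1a):
        assert enhanced_neighborhood(fig1a, ("2", "7")) == pytest.approx(1.75)
        assert enhanced_neighborhood(fig1a, ("1", "7")) == pytest.approx(1.6)
        assert enhanced_neighborhood(fig1a, ("1", "2")) == pytest.approx(0.375)
        assert round_half_up(0.375) == 0.38

    def test_isolated_edge_is_zero(self):
        assert enhanced_neighborhood(isolated_edge(), ("a", "b")) == 0.0

    def test_weight_override(self, fig1a):
        assert enhanced_neighborhood(fig1a, ("1", "7"), w_sn=1, w_fn=0) == pytest.approx(0.5)

    def test_negative_weight_rejected(self, fig1a):
        with pytest.raises(ValueError):
            enhanced_neighborhood(fig1a, ("1", "7"), w_sn=-1)


class TestEdgeBetweenness:
    def test_fig1e_bridge_exact_fraction(self, fig1e):
        # 7x6 cross pairs over 78 unordered pairs
        assert edge_betweenness(fig1e)[("1", "2")] == pytest.approx(42 / 78)

    def test_fig1a_top_edge(self, fig1a):
        assert round_half_up(edge_betweenness(fig1a)[("1", "2")]) == 0.46

    def test_triangle_symmetry(self):
        table = edge_betweenness(nx.complete_graph(3))
        assert all(v == pytest.approx(1 / 3) for v in table.scores.values())

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            edge_betweenness(nx.empty_graph(1))

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")  # N=3 => 3 pairs, only one connected
        assert edge_betweenness(g)[("a", "b")] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_networkx(self, seed):
        g = random_simple_graph(40, 0.1, seed)
        ours = edge_betweenness(g)
        theirs = nx.edge_betweenness_centrality(g, normalized=True)
        for (u, v), val in theirs.items():
            assert ours[(u, v)] == pytest.approx(val, abs=1e-12)

    def test_conservation_of_geodesic_length(self):
        """Unnormalized EB totals the geodesic distances over connected pairs."""
        g = random_simple_graph(60, 0.06, seed=11)
        total_eb = sum(edge_betweenness(g, normalized=False).scores.values())
        total_dist = 0
        for s, lengths in nx.all_pairs_shortest_path_length(g):
            total_dist += sum(lengths.values())
        assert total_eb == pytest.approx(total_dist / 2, rel=1e-9)


class TestDegreeProduct:
    @pytest.mark.parametrize("edge,expected", [(("1", "2"), 30), (("9", "10"), 2)])
    def test_fig1a(self, fig1a, edge, expected):
        assert degree_product(fig1a, edge) == expected

    def test_triangle(self):
        assert degree_product(nx.complete_graph(3), (0, 1)) == 4


class TestBridgeness:
    def test_triangle(self):
        assert bridgeness(nx.complete_graph(3), (0, 1)) == pytest.approx(3.0)

    def test_fig1a(self, fig1a):
        assert bridgeness(fig1a, ("1", "2")) == pytest.approx(3.0)
        assert bridgeness(fig1a, ("9", "10")) == pytest.approx(2.0)

    def test_clique_sizes_in_k4_plus_pendant(self):
        g = nx.complete_graph(4)
        g.add_edge(3, "p")
        cs = clique_sizes(g, (3, "p"))
        assert (cs.S_i, cs.S_j, cs.S_e) == (4, 2, 2)


class TestDiffusionIntensity:
    def test_fig1a(self, fig1a):
        assert diffusion_intensity(fig1a, ("1", "2")) == pytest.approx(3.5)
        assert diffusion_intensity(fig1a, ("9", "10")) == pytest.approx(0.5)

    def test_triangle_all_shared(self):
        assert diffusion_intensity(nx.complete_graph(3), (0, 1)) == 0.0


def _brute_force_ei(g, e):
    """Independent EI implementation: classify induced 4-node subgraphs with
    networkx and take geodesic means from explicit distance dicts."""
    i, j = e
    tri = sum(1 for w in g if w not in e and g.has_edge(i, w) and g.has_edge(j, w))
    empty = outer = inner = full = 0
    rest = [w for w in g if w not in e]
    for pair in combinations(rest, 2):
        sub = g.subgraph([i, j, *pair])
        m = sub.number_of_edges()
        degs = dict(sub.degree())
        if m == 4 and set(degs.values()) == {2}:
            empty += 1
        elif m == 5:
            if degs[i] == 3 and degs[j] == 3:
                inner += 1
            else:
                outer += 1
        elif m == 6:
            full += 1
    k_i, k_j = g.degree[i], g.degree[j]
    max_total = (min(k_i, k_j) - 1) + 4 * (k_i - 1) * (k_j - 1)

    def mean_dist(h):
        if h.number_of_nodes() < 2:
            return 0.0
        dists = [d for _, row in nx.all_pairs_shortest_path_length(h)
                 for d in row.values() if d > 0]
        return sum(dists) / len(dists) if dists else 0.0

    contracted = nx.Graph(nx.contracted_nodes(g, i, j, self_loops=False))
    if max_total <= 0:
        return 0.0
    actual = tri + empty + outer + inner + full
    return actual / max_total * abs(mean_dist(g) - mean_dist(contracted))


class TestEdgeImportanceEI:
    def test_isolated_edge_conventions(self):
        c = ei_components(isolated_edge(), ("a", "b"))
        assert c.actual_total == 0
        assert c.L == pytest.approx(1.0) and c.L_prime == 0.0
        assert edge_importance_EI(isolated_edge(), ("a", "b")) == 0.0

    def test_k4_motifs(self):
        c = ei_components(nx.complete_graph(4), (0, 1))
        assert c.full_quad_act == 1 and c.tri_act == 2

    def test_four_cycle_motifs(self):
        c = ei_components(nx.cycle_graph(4), (0, 1))
        assert c.empty_quad_act == 1 and c.tri_act == 0

    def test_diamond_chord_roles(self):
        g = nx.complete_graph(4)
        g.remove_edge(2, 3)  # chord is (0, 1)
        chord = ei_components(g, (0, 1))
        side = ei_components(g, (0, 2))
        assert chord.diag_quad_inner_act == 1 and chord.diag_quad_outer_act == 0
        assert side.diag_quad_outer_act == 1 and side.diag_quad_inner_act == 0

    def test_mean_geodesic_distance_path(self):
        # path of 3 nodes: distances 1,1,2 -> mean 4/3
        assert mean_geodesic_distance(nx.path_graph(3)) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_brute_force(self, seed):
        g = random_simple_graph(7, 0.5, seed)
        for e in g.edges():
            assert edge_importance_EI(g, e) == pytest.approx(
                _brute_force_ei(g, e), abs=1e-12)


class TestGLHC:
    def test_fig1a_top_edge(self, fig1a):
        assert round_half_up(glhc(fig1a)[("1", "2")]) == 1.57

    def test_fig1e_top_edge(self, fig1e):
        assert round_half_up(glhc(fig1e)[("1", "2")]) == 1.62

    def test_two_node_graph(self):
        assert glhc(isolated_edge())[("a", "b")] == pytest.approx(3.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            glhc(nx.empty_graph(1))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_compositional_identities(self, seed):
        """EN == 2*SN + 3*FN and GLHC == 3*EB + SN + 1.5*FN edge by edge."""
        g = random_simple_graph(25, 0.15, seed)
        eb = edge_betweenness(g)
        en = score_all_edges(g, "EN")
        hyb = glhc(g)
        for e in eb.scores:
            sn = second_order_index(g, e)
            fn = first_order_index(g, e)
            assert en[e] == pytest.approx(2 * sn + 3 * fn, abs=1e-12)
            assert hyb[e] == pytest.approx(3 * eb[e] + sn + 1.5 * fn, abs=1e-12)

    def test_triangle_free_network_reduces_to_betweenness(self, fig1e):
        """With no triangles every local overlap is empty, so GLHC == 3*EB."""
        eb = edge_betweenness(fig1e)
        hyb = glhc(fig1e)
        for e in eb.scores:
            assert hyb[e] == pytest.approx(3 * eb[e], abs=1e-12)


class TestScoreAllEdges:
    def test_unknown_method_lists_valid_names(self, fig1a):
        with pytest.raises(ValueError, match="GLHC"):
            score_all_edges(fig1a, "xyz")

    def test_sn_table_descending_starts_with_the_triangle_edges(self, fig1a):
        frame = score_all_edges(fig1a, "SN").to_frame()
        top2 = {tuple(r) for r in frame.loc[:1, ["node_u", "node_v"]].itertuples(index=False)}
        assert top2 == {("1", "7"), ("2", "7")}
        assert list(frame.loc[:1, "score"]) == [0.5, 0.5]

    def test_en_all_zero_on_triangle_free_network(self, fig1e):
        scores = score_all_edges(fig1e, "EN").scores
        assert len(scores) == 13 and all(s == 0.0 for s in scores.values())

    def test_dp_scores_are_positive_integers(self, fig1a):
        assert all(s > 0 and s == int(s)
                   for s in score_all_edges(fig1a, "DP").scores.values())

    def test_every_method_covers_every_edge_finitely(self, fig1a):
        import math
        edges = {canonical_edge(u, v) for u, v in fig1a.edges()}
        for m in METHODS:
            table = score_all_edges(fig1a, m)
            assert set(table.scores) == edges
            assert all(math.isfinite(s) and s >= 0 for s in table.scores.values())

    def test_fn_sn_eb_bounded_by_one(self, fig1a):
        for m in ("FN", "SN", "EB"):
            assert all(0 <= s <= 1 for s in score_all_edges(fig1a, m).scores.values())

    @pytest.mark.parametrize("method", METHODS)
    def test_label_invariance(self, method):
        """Every index is unchanged by a node relabelling."""
        g = random_simple_graph(12, 0.3, seed=5)
        perm = {n: f"n{(n * 5 + 3) % 12:02d}" for n in g}
        h = nx.relabel_nodes(g, perm)
        sg = score_all_edges(g, method)
        sh = score_all_edges(h, method)
        for e, val in sg.scores.items():
            assert sh[canonical_edge(perm[e[0]], perm[e[1]])] == pytest.approx(
                val, abs=1e-12)

    def test_csv_serialization_columns(self, fig1a, tmp_path):
        p = tmp_path / "scores.csv"
        score_all_edges(fig1a, "GLHC").to_csv(p, round_to=2)
        import pandas as pd
        frame = pd.read_csv(p, dtype={"node_u": str, "node_v": str})
        assert list(frame.columns) == ["node_u", "node_v", "score", "rank"]
        assert frame.iloc[0][["node_u", "node_v"]].tolist() == ["1", "2"]
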