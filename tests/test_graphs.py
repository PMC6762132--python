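"""Unit and property tests for the network-statistics layer."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitonet.graphs import (
    branch_lengths,
    cluster_size_distribution,
    cycle_rank,
    giant_cluster,
    loop_sizes,
    mean_degree,
    network_stats,
    read_graphml,
    skeleton_to_graph,
    write_graphml,
)
from mitonet.synthetic import ToyGraphSpec, make_toy_graph


# ---------------------------------------------------------------------------
# independent oracle: minimum-weight cycle basis by exhaustive GF(2) greedy
# ---------------------------------------------------------------------------

def brute_force_loop_sizes(g: nx.MultiGraph):
    """Enumerate every even-degree edge subset and build a minimum-weight
    basis of the cycle space greedily -- exponential, for <= 14 edges."""
    edges = list(g.edges(keys=True))
    m = len(edges)
    assert m <= 14, "oracle is exponential"
    candidates = []
    for bits in range(1, 2 ** m):
        deg = {}
        for i in range(m):
            if bits >> i & 1:
                u, v, _ = edges[i]
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
        if all(d % 2 == 0 for d in deg.values()):
            candidates.append((bin(bits).count("1"), bits))
    candidates.sort()
    basis, space = [], []
    for w, bits in candidates:
        v = bits
        for b in space:
            v = min(v, v ^ b)
        if v:
            space.append(v)
            space.sort(reverse=True)
            basis.append(w)
    return sorted(basis)


def _multigraph(edge_list):
    g = nx.MultiGraph()
    g.add_edges_from(edge_list)
    return g


LOLLIPOP = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 10), (10, 11), (11, 12)]
THETA222 = [(0, 1), (1, 5), (0, 2), (2, 5), (0, 3), (3, 5)]
SHARED_EDGE_TRIANGLES = [(0, 1), (1, 2), (2, 0), (1, 3), (3, 2)]


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

class TestSkeletonToGraph:
    def test_straight_line(self):
        sk = np.zeros((3, 5), bool)
        sk[1, 1:4] = True
        g = skeleton_to_graph(sk)
        assert (g.number_of_nodes(), g.number_of_edges()) == (3, 2)
        assert sorted(d for _, d in g.degree()) == [1, 1, 2]

    def test_t_junction_prunes_diagonals(self):
        sk = np.zeros((4, 4), bool)
        for r, c in [(0, 1), (1, 1), (2, 1), (1, 0)]:
            sk[r, c] = True
        g = skeleton_to_graph(sk)
        degs = sorted(d for _, d in g.degree())
        assert g.number_of_edges() == 3
        assert degs == [1, 1, 1, 3]

    def test_pixel_ring(self):
        sk = np.zeros((6, 6), bool)
        sk[1, 1:5] = sk[4, 1:5] = sk[1:5, 1] = sk[1:5, 4] = True
        g = skeleton_to_graph(sk)
        p = int(sk.sum())
        assert g.number_of_nodes() == p
        assert g.number_of_edges() == p
        assert all(d == 2 for _, d in g.degree())

    def test_diagonal_staircase_is_a_path(self):
        sk = np.zeros((5, 5), bool)
        for i in range(4):
            sk[i, i] = True
        g = skeleton_to_graph(sk)
        assert g.number_of_edges() == 3
        assert cycle_rank(g) == 0


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

class TestScalars:
    def test_mean_degree_path(self):
        assert mean_degree(nx.path_graph(3, nx.MultiGraph)) == pytest.approx(4 / 3)

    def test_mean_degree_triangle(self):
        assert mean_degree(nx.cycle_graph(3, nx.MultiGraph)) == 2.0

    def test_mean_degree_counts_isolated_nodes(self):
        g = nx.path_graph(3, nx.MultiGraph)
        g.add_node("lonely")
        assert mean_degree(g) == 1.0
        assert mean_degree(g, include_isolated=False) == pytest.approx(4 / 3)

    def test_mean_degree_empty_graph_errors(self):
        with pytest.raises(ValueError):
            mean_degree(nx.MultiGraph())

    def test_giant_cluster(self):
        g = nx.disjoint_union(nx.path_graph(4), nx.path_graph(8))
        ng, frac = giant_cluster(nx.MultiGraph(g))
        assert (ng, frac) == (7, 0.7)

    def test_giant_cluster_single_component(self):
        assert giant_cluster(nx.cycle_graph(5, nx.MultiGraph))[1] == 1.0

    def test_giant_cluster_edgeless_errors(self):
        with pytest.raises(ValueError):
            giant_cluster(nx.MultiGraph())


# ---------------------------------------------------------------------------
# loops and branches
# ---------------------------------------------------------------------------

class TestLoopsAndBranches:
    @pytest.mark.parametrize("edges,expected", [
        ([(0, 1), (1, 2), (2, 3), (3, 0)], [4]),        # isolated 4-cycle
        ([(0, 1), (1, 2), (2, 3)], []),                 # pure path
        (THETA222, [4, 4]),                             # theta, chains 2/2/2
        (LOLLIPOP, [4]),
        (SHARED_EDGE_TRIANGLES, [3, 3]),                # rank-2 fused triangles
        ([(0, 0)], [1]),                                # unit self-loop
        ([(0, 1), (0, 1)], [2]),                        # parallel pair
    ])
    def test_loop_sizes(self, edges, expected):
        assert loop_sizes(_multigraph(edges)) == expected

    @pytest.mark.parametrize("edges", [THETA222, LOLLIPOP,
                                       SHARED_EDGE_TRIANGLES,
                                       [(0, 0)], [(0, 1), (0, 1)]])
    def test_loop_sizes_match_exhaustive_basis(self, edges):
        g = _multigraph(edges)
        assert loop_sizes(g) == brute_force_loop_sizes(g)

    @pytest.mark.parametrize("edges,expected", [
        ([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)], [5]),       # path of 5
        ([(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (5, 6)], [2, 2, 2]),  # star
        (LOLLIPOP, [3]),
        ([(0, 1), (1, 2), (2, 3), (3, 0)], []),                # pure cycle
    ])
    def test_branch_lengths(self, edges, expected):
        assert branch_lengths(_multigraph(edges)) == expected

    def test_branch_and_loop_edges_disjoint(self):
        g = _multigraph(LOLLIPOP)
        assert sum(loop_sizes(g)) + sum(branch_lengths(g)) == g.number_of_edges()


# ---------------------------------------------------------------------------
# distributions and the full bundle
# ---------------------------------------------------------------------------

class TestDistributionsAndStats:
    def test_cumulative_distribution(self):
        g = nx.MultiGraph()
        nx.add_path(g, [0, 1, 2])
        nx.add_path(g, [10, 11, 12])
        nx.add_path(g, [20, 21, 22, 23, 24, 25, 26])
        sizes, (uniq, cum) = cluster_size_distribution(g)
        assert sorted(sizes) == [2, 2, 6]
        assert dict(zip(uniq.tolist(), cum.tolist())) == {2: pytest.approx(2 / 3),
                                                          6: pytest.approx(1.0)}

    def test_single_cluster_step_function(self):
        _, (uniq, cum) = cluster_size_distribution(nx.path_graph(5, nx.MultiGraph))
        assert uniq.tolist() == [4] and cum.tolist() == [1.0]

    def test_network_stats_mixed_spec(self):
        g = make_toy_graph(ToyGraphSpec((("path", 3), ("cycle", 4),
                                         ("isolated-edge", 1))))
        st_ = network_stats(g)
        assert st_.n_edges == 8
        assert st_.n_clusters == 3
        assert st_.avg_cluster_size == pytest.approx(8 / 3)
        assert (st_.giant_size, st_.giant_frac) == (4, 0.5)
        assert st_.loop_sizes == [4]

    def test_graphml_round_trip(self, tmp_path):
        g = make_toy_graph(ToyGraphSpec((("theta", 8), ("path", 2))))
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        g2 = read_graphml(path)
        assert g2.number_of_edges() == g.number_of_edges()
        assert sorted(d for _, d in g2.degree()) == sorted(d for _, d in g.degree())


# ---------------------------------------------------------------------------
# properties over random toy networks
# ---------------------------------------------------------------------------

component_st = st.one_of(
    st.tuples(st.just("path"), st.integers(1, 8)),
    st.tuples(st.just("cycle"), st.integers(1, 8)),
    st.tuples(st.just("star"), st.integers(3, 9)),
    st.tuples(st.just("theta"), st.integers(3, 9)),
    st.tuples(st.just("isolated-edge"), st.just(1)),
)


@given(st.lists(component_st, min_size=1, max_size=6))
def test_stats_invariants(components):
    """Conservation and rank identities on arbitrary toy networks."""
    g = make_toy_graph(ToyGraphSpec(tuple(components)))
    st_ = network_stats(g)
    assert sum(st_.cluster_sizes) == st_.n_edges
    assert st_.giant_size == max(st_.cluster_sizes)
    assert 0 < st_.giant_frac <= 1
    assert st_.avg_cluster_size * st_.n_clusters == pytest.approx(st_.n_edges)
    # number of reported loops == cycle rank, component by component
    assert len(st_.loop_sizes) == cycle_rank(g)
    # branches never overlap: total branch length bounded by non-loop edges
    assert sum(st_.branch_lengths) <= st_.n_edges
    # identical statistics on a relabeled copy (provenance independence)
    relabeled = nx.convert_node_labels_to_integers(g)
    st2 = network_stats(relabeled)
    assert st2.loop_sizes == st_.loop_sizes
    assert st2.branch_lengths == st_.branch_lengths
    assert st2.mean_degree == pytest.approx(st_.mean_degree)


@given(st.lists(component_st, min_size=1, max_size=5))
def test_loops_match_exhaustive_oracle_on_small_graphs(components):
    g = make_toy_graph(ToyGraphSpec(tuple(components)))
    if g.number_of_edges() > 12:
        g = g.subgraph(next(iter(nx.connected_components(g))))
        if g.number_of_edges() > 12:
            return
    assert loop_sizes(g) == brute_force_loop_sizes(g)
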