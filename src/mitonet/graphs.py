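"""Topology metrics for mitochondrial networks.

A mitochondrial network is represented as an undirected multigraph
(:class:`networkx.MultiGraph`) whose edges are the minimal, indivisible
units of the organelle: for an image-derived network every skeleton pixel
is a node and every (pruned) 8-adjacency is a unit edge; for a simulated
network every node is a cluster of fused tube tips and every tube
contributes one unit edge.  Self-loops and parallel edges are legitimate
(a tube whose two tips fused with each other is a one-edge loop).

This module converts labeled skeleton rasters into such graphs and
computes the morphology metrics used to compare conditions:

* ``N`` -- total unit edges,
* mean degree ``<k>`` -- average number of nearest neighbours per node,
* cluster statistics -- connected components with at least one edge,
* giant cluster ``N_g`` and its normalized size ``N_g / N``,
* loop sizes -- minimum-weight cycle basis of each component, in unit
  edges, after collapsing degree-2 chains,
* branch lengths -- maximal degree-2 chains with at least one open
  (degree-1) end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkStats",
    "skeleton_to_graph",
    "mean_degree",
    "giant_cluster",
    "loop_sizes",
    "branch_lengths",
    "cluster_size_distribution",
    "network_stats",
    "collapse_chains",
    "cycle_rank",
    "write_graphml",
    "read_graphml",
    "stats_to_json",
    "stats_frame",
]


@dataclass
class NetworkStats:
    """Bundle of the morphology metrics of one network.

    Sizes are counted in unit edges throughout.  ``n_clusters`` counts only
    components that contain at least one edge, so isolated degree-0 nodes
    (single skeleton pixels) contribute to ``n_nodes`` and to the mean
    degree but not to the cluster statistics.
    """

    n_edges: int
    n_nodes: int
    mean_degree: float
    n_clusters: int
    avg_cluster_size: float
    giant_size: int
    giant_frac: float
    loop_sizes: list = field(default_factory=list)
    branch_lengths: list = field(default_factory=list)
    cluster_sizes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

def skeleton_to_graph(skeleton: np.ndarray) -> nx.MultiGraph:
    """Convert a one-pixel-thick skeleton raster to a pixel graph.

    Every foreground pixel becomes a node ``(row, col)`` and every
    8-adjacent pixel pair an edge, except that a diagonal adjacency is
    dropped when the two pixels already share a foreground 4-neighbour:
    raw 8-adjacency would otherwise create a spurious 3-cycle at every
    diagonal step of the skeleton, inflating the loop count.

    ``skeleton`` may be boolean or an integer label image (anything
    nonzero is foreground).
    """
    mask = np.asarray(skeleton) != 0
    if mask.ndim != 2:
        raise ValueError("skeleton must be a 2-D raster")
    g = nx.MultiGraph()
    rows, cols = np.nonzero(mask)
    fg = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(fg)
    for r, c in fg:
        # half of the 8 directions, so each pair is visited once
        e = (r, c + 1)
        if e in fg:
            g.add_edge((r, c), e)
        s = (r + 1, c)
        if s in fg:
            g.add_edge((r, c), s)
        se = (r + 1, c + 1)
        if se in fg and (r, c + 1) not in fg and (r + 1, c) not in fg:
            g.add_edge((r, c), se)
        sw = (r + 1, c - 1)
        if sw in fg and (r, c - 1) not in fg and (r + 1, c) not in fg:
            g.add_edge((r, c), sw)
    return g


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def mean_degree(graph: nx.MultiGraph, include_isolated: bool = True) -> float:
    """Average number of edge endpoints per node (self-loops count twice).

    ``include_isolated=False`` drops degree-0 nodes from the average; the
    default keeps them, matching cluster counts that merely *exclude*
    isolated nodes (they still exist in the node set).
    """
    degrees = [d for _, d in graph.degree()]
    if not include_isolated:
        degrees = [d for d in degrees if d > 0]
    if not degrees:
        raise ValueError("mean degree of an empty graph is undefined")
    return float(sum(degrees)) / len(degrees)


def _component_edge_counts(graph: nx.MultiGraph) -> list:
    """Edge count of every connected component (including 0-edge ones)."""
    deg = dict(graph.degree())
    return [sum(deg[n] for n in comp) // 2 for comp in nx.connected_components(graph)]


def cluster_sizes(graph: nx.MultiGraph) -> list:
    """Edge counts of components with >= 1 edge, descending."""
    return sorted((s for s in _component_edge_counts(graph) if s > 0), reverse=True)


def giant_cluster(graph: nx.MultiGraph) -> tuple:
    """``(N_g, N_g/N)``: edge count of the largest cluster and its share."""
    n = graph.number_of_edges()
    if n == 0:
        raise ValueError("giant cluster of an edgeless graph is undefined")
    ng = max(_component_edge_counts(graph))
    return ng, ng / n


def cycle_rank(graph: nx.MultiGraph) -> int:
    """Number of independent cycles, E - V + C."""
    return (graph.number_of_edges() - graph.number_of_nodes()
            + nx.number_connected_components(graph))


# ---------------------------------------------------------------------------
# chain collapse
# ---------------------------------------------------------------------------

def _canon(u, v, k):
    return (u, v, k) if repr(u) <= repr(v) else (v, u, k)


def collapse_chains(graph: nx.MultiGraph) -> nx.MultiGraph:
    """Collapse every maximal chain of degree-2 nodes into one super-edge.

    Returns a multigraph on the junction nodes (degree != 2) whose edges
    carry a ``weight`` attribute equal to the number of unit edges
    absorbed.  A component that is a pure cycle (every node degree 2,
    including single-node self-loops) is represented by a self-loop
    super-edge on one representative node, so cycle rank is preserved
    exactly: rank(collapsed) == rank(original).
    """
    deg = dict(graph.degree())
    out = nx.MultiGraph()
    out.add_nodes_from(n for n, d in deg.items() if d != 2)
    visited = set()

    for u in list(out.nodes):
        for _, v, k in list(graph.edges(u, keys=True)):
            if _canon(u, v, k) in visited:
                continue
            visited.add(_canon(u, v, k))
            weight = 1
            prev, cur = u, v
            while deg[cur] == 2:
                nxt = None
                for _, w, k2 in graph.edges(cur, keys=True):
                    if _canon(cur, w, k2) not in visited:
                        nxt = (w, k2)
                        break
                if nxt is None:  # closed walk back onto a visited edge
                    break
                visited.add(_canon(cur, nxt[0], nxt[1]))
                weight += 1
                prev, cur = cur, nxt[0]
            out.add_edge(u, cur, weight=weight)

    # leftover edges form pure-cycle components (every node degree 2)
    leftover = [e for e in graph.edges(keys=True) if _canon(*e) not in visited]
    if leftover:
        sub = nx.MultiGraph()
        sub.add_edges_from(leftover)
        for comp in nx.connected_components(sub):
            rep = next(iter(comp))
            out.add_edge(rep, rep, weight=sub.subgraph(comp).number_of_edges())
    return out


# ---------------------------------------------------------------------------
# loops and branches
# ---------------------------------------------------------------------------

def _single_cycle_weight(sub: nx.MultiGraph) -> int:
    """Total weight of the unique cycle of a rank-1 component."""
    g = nx.MultiGraph(sub)
    leaves = [n for n, d in g.degree() if d == 1]
    while leaves:
        n = leaves.pop()
        nbrs = list(g.neighbors(n))
        g.remove_node(n)
        for m in nbrs:
            if m in g and g.degree(m) == 1:
                leaves.append(m)
    return int(round(sum(w for _, _, w in g.edges(data="weight"))))


def _min_cycle_basis_weights(sub: nx.MultiGraph) -> list:
    """Minimum-weight cycle basis of a weighted multigraph component.

    networkx's ``minimum_cycle_basis`` handles neither parallel edges nor
    self-loops, so each super-edge (u, v, weight w) is subdivided into
    u - m1 - m2 - v with weights (w/2, 0, w/2); the result is a simple
    graph with an identical, identically weighted cycle space.  Each basis
    cycle returned as a node set induces exactly its own edges there
    (every edge of the subdivided graph joins an original node to a
    midpoint), so its weight is the induced subgraph's total weight.
    """
    h = nx.Graph()
    for i, (u, v, _, w) in enumerate(sub.edges(keys=True, data="weight")):
        m1, m2 = ("_mid", i, 0), ("_mid", i, 1)
        h.add_edge(u, m1, weight=w / 2)
        h.add_edge(m1, m2, weight=0.0)
        h.add_edge(m2, v, weight=w / 2)
    weights = []
    for cyc in nx.minimum_cycle_basis(h, weight="weight"):
        ind = h.subgraph(cyc)
        weights.append(int(round(sum(w for _, _, w in ind.edges(data="weight")))))
    return weights


def loop_sizes(graph: nx.MultiGraph) -> list:
    """Sizes (unit edges) of the loops of the network, smallest first.

    Loops are the minimum-weight cycle basis of each chain-collapsed
    component, so the number of loops equals the cycle rank and a
    component that is a pure cycle reports its full edge count as one
    loop.  Nested or fused cycles (rank >= 2) report the smallest
    independent set of cycles.
    """
    collapsed = collapse_chains(graph)
    sizes = []
    for comp in nx.connected_components(collapsed):
        sub = collapsed.subgraph(comp)
        rank = sub.number_of_edges() - sub.number_of_nodes() + 1
        if rank <= 0:
            continue
        if rank == 1:
            sizes.append(_single_cycle_weight(sub))
        else:
            sizes.extend(_min_cycle_basis_weights(sub))
    return sorted(sizes)


def branch_lengths(graph: nx.MultiGraph) -> list:
    """Lengths (unit edges) of branches: chains with >= 1 open end.

    A branch is a maximal chain whose interior nodes have degree 2,
    terminated at both ends by nodes of degree != 2, at least one of
    which has degree 1.  An isolated path counts once (not once per
    end); pure cycles contribute nothing.
    """
    collapsed = collapse_chains(graph)
    deg = dict(graph.degree())
    out = []
    for u, v, w in collapsed.edges(data="weight"):
        if u == v:
            continue
        if deg[u] == 1 or deg[v] == 1:
            out.append(int(w))
    return sorted(out)


def cluster_size_distribution(graph: nx.MultiGraph) -> tuple:
    """Per-cluster sizes and their cumulative probability curve.

    Returns ``(sizes, (unique_sizes, cum_prob))`` where ``cum_prob[i]`` is
    the fraction of clusters of size <= ``unique_sizes[i]`` (clusters
    weighted equally, not by edge count).
    """
    sizes = cluster_sizes(graph)
    if not sizes:
        raise ValueError("no clusters in an edgeless graph")
    uniq, counts = np.unique(np.asarray(sizes), return_counts=True)
    cum = np.cumsum(counts) / len(sizes)
    return sizes, (uniq, cum)


def network_stats(graph: nx.MultiGraph, include_isolated: bool = True) -> NetworkStats:
    """All morphology metrics of one network in a single bundle."""
    n = graph.number_of_edges()
    if n == 0:
        raise ValueError("network statistics of an edgeless graph are undefined")
    sizes = cluster_sizes(graph)
    ng = sizes[0]
    return NetworkStats(
        n_edges=n,
        n_nodes=graph.number_of_nodes(),
        mean_degree=mean_degree(graph, include_isolated=include_isolated),
        n_clusters=len(sizes),
        avg_cluster_size=n / len(sizes),
        giant_size=ng,
        giant_frac=ng / n,
        loop_sizes=loop_sizes(graph),
        branch_lengths=branch_lengths(graph),
        cluster_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.MultiGraph, path) -> None:
    """Write a network as GraphML (node ids stringified, degrees attached)."""
    g = nx.MultiGraph()
    for n, d in graph.degree():
        g.add_node(str(n), degree=int(d))
    for u, v in graph.edges():
        g.add_edge(str(u), str(v), weight=1)
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.MultiGraph:
    return nx.MultiGraph(nx.read_graphml(path))


def stats_to_json(stats: NetworkStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2, default=float)


def stats_frame(stats: NetworkStats) -> pd.DataFrame:
    """One row per scalar metric, ready for CSV export."""
    scalars = {k: v for k, v in stats.to_dict().items() if np.isscalar(v)}
    return pd.DataFrame({"metric": list(scalars), "value": list(scalars.values())})
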