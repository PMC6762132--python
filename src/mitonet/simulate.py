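"""Agent-based Gillespie model of mitochondrial fission and fusion.

The network consists of ``N`` indivisible tubes (unit edges), each with
two tips.  Tips merge into shared nodes through two reversible reactions:

* tip-to-tip (longitudinal):  ``X1 + X1 <-> X2``  with rates ``a1 / b1``,
* tip-to-side (lateral):      ``X1 + X2 <-> X3``  with rates ``a2 / b2``,

where ``X1``, ``X2``, ``X3`` count nodes of degree 1, 2 and 3.  At most
three tips may share a node; degree >= 4 is excluded by construction.
Tip endpoints are conserved, so ``X1 + 2*X2 + 3*X3 == 2*N`` always.

The kinetics are controlled by the dimensionless fusion-to-fission
ratios ``C1 = a1/b1`` and ``C2 = a2/b2`` with the fission rates fixed at
``b1 = 0.01`` and ``b2 = 1.5*b1``.  Starting from fully fragmented
networks (all tips free), ``5*N`` reaction events suffice to reach the
stationary state, whose realized graph is then summarized with
:mod:`mitonet.graphs`.

Because the propensity combinatorics of the original formulation are
ambiguous, several conventions are offered (see :data:`CONVENTIONS`);
``scripts/calibrate_conventions.py`` ranks them against the reference
condition table and the best-ranked one, ``"squared"``, is the default.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import NetworkStats, network_stats

__all__ = [
    "CONVENTIONS",
    "DEFAULT_CONVENTION",
    "AbsorbingStateError",
    "RateParams",
    "SimState",
    "SimResult",
    "EnsembleResult",
    "init_state",
    "propensities",
    "step",
    "run",
    "simulate_ensemble",
    "realized_graph",
]

#: Propensity conventions for the four reaction channels, as functions of
#: the species counts.  All share the fission channel ``b1*X2`` and the
#: tip-to-side fusion ``a2*X1*X2``; they differ in the tip-to-tip fusion
#: pair count and in the multiplicity of tip-to-side fission:
#:
#: * ``"pairwise"``: fusion1 = a1*X1*(X1-1)/2 (unordered pairs),
#:   fission2 = b2*X3.
#: * ``"squared"``:  fusion1 = a1*X1**2 (deterministic mass action),
#:   fission2 = b2*X3.
#: * ``"triple-fission"``: as ``"pairwise"`` but fission2 = 3*b2*X3
#:   (each of the three tips of an X3 node detaches independently).
CONVENTIONS = ("pairwise", "squared", "triple-fission")

#: Shipped default, selected by the committed calibration script as the
#: convention closest to the reference condition table.
DEFAULT_CONVENTION = "squared"


class AbsorbingStateError(RuntimeError):
    """Raised when every propensity is zero (no reaction can fire)."""


@dataclass
class RateParams:
    """Kinetic parameters of the two-reaction model.

    ``b1``/``b2`` are the tip-to-tip / tip-to-side fission rates per node
    per unit time; ``C1``/``C2`` the dimensionless fusion-to-fission
    ratios, so the fusion rates are ``a1 = C1*b1`` and ``a2 = C2*b2``.
    """

    C1: float
    C2: float
    b1: float = 0.01
    b2: float = None  # type: ignore[assignment]
    convention: str = DEFAULT_CONVENTION

    def __post_init__(self):
        if self.b2 is None:
            self.b2 = 1.5 * self.b1
        if min(self.C1, self.C2, self.b1, self.b2) < 0:
            raise ValueError("rates must be non-negative")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def a1(self) -> float:
        return self.C1 * self.b1

    @property
    def a2(self) -> float:
        return self.C2 * self.b2


class SimState:
    """Mutable agent-based state: tips, nodes and species registries.

    Tips are numbered ``0 .. 2N-1``; tips ``2i`` and ``2i+1`` are the two
    ends of edge ``i``.  ``tip_node[t]`` is the node a tip currently
    belongs to and ``node_tips[n]`` the (1-3) tips of node ``n``; freed
    node slots are recycled, so at most ``2N`` slots ever exist.
    """

    __slots__ = ("N", "seed", "rng", "tip_node", "node_tips", "free_nodes",
                 "species", "node_pos", "time", "n_events")

    def __init__(self, N: int, seed=None):
        if N < 1:
            raise ValueError("need at least one edge")
        self.N = N
        self.seed = seed
        self.rng = random.Random(seed)
        self.tip_node = list(range(2 * N))
        self.node_tips = [[t] for t in range(2 * N)]
        self.free_nodes: list = []
        # species[d-1] lists the node ids of degree d; node_pos tracks each
        # live node's index in its species list for O(1) swap-pop removal.
        self.species = (list(range(2 * N)), [], [])
        self.node_pos = list(range(2 * N))
        self.time = 0.0
        self.n_events = 0

    # -- species bookkeeping -------------------------------------------
    @property
    def counts(self) -> tuple:
        """(X1, X2, X3) node counts."""
        s1, s2, s3 = self.species
        return len(s1), len(s2), len(s3)

    @property
    def n_nodes(self) -> int:
        return sum(self.counts)

    def fractions(self) -> tuple:
        x1, x2, x3 = self.counts
        m = x1 + x2 + x3
        return x1 / m, x2 / m, x3 / m

    def _remove(self, node: int, deg: int) -> None:
        lst = self.species[deg - 1]
        pos = self.node_pos[node]
        last = lst[-1]
        lst[pos] = last
        self.node_pos[last] = pos
        lst.pop()

    def _add(self, node: int, deg: int) -> None:
        lst = self.species[deg - 1]
        self.node_pos[node] = len(lst)
        lst.append(node)

    def _new_node(self, tip: int) -> int:
        node = self.free_nodes.pop()
        self.node_tips[node] = [tip]
        self.tip_node[tip] = node
        return node

    # -- reaction channels ---------------------------------------------
    def fuse_tip_tip(self) -> None:
        """Two distinct degree-1 nodes merge into one degree-2 node."""
        s1 = self.species[0]
        i = self.rng.randrange(len(s1))
        j = self.rng.randrange(len(s1) - 1)
        if j >= i:
            j += 1
        a, b = s1[i], s1[j]
        self._remove(a, 1)
        self._remove(b, 1)
        tb = self.node_tips[b][0]
        self.tip_node[tb] = a
        self.node_tips[a].append(tb)
        self.node_tips[b] = []
        self.free_nodes.append(b)
        self._add(a, 2)

    def fiss_tip_tip(self) -> None:
        """A degree-2 node splits into two free tips."""
        s2 = self.species[1]
        a = s2[self.rng.randrange(len(s2))]
        self._remove(a, 2)
        t1 = self.node_tips[a].pop()
        b = self._new_node(t1)
        self._add(a, 1)
        self._add(b, 1)

    def fuse_tip_side(self) -> None:
        """A degree-1 node joins a degree-2 node, forming a degree-3 node."""
        s1, s2 = self.species[0], self.species[1]
        a = s1[self.rng.randrange(len(s1))]
        c = s2[self.rng.randrange(len(s2))]
        self._remove(a, 1)
        self._remove(c, 2)
        ta = self.node_tips[a][0]
        self.tip_node[ta] = c
        self.node_tips[c].append(ta)
        self.node_tips[a] = []
        self.free_nodes.append(a)
        self._add(c, 3)

    def fiss_tip_side(self) -> None:
        """One of the three tips of a degree-3 node detaches, uniformly."""
        s3 = self.species[2]
        c = s3[self.rng.randrange(len(s3))]
        self._remove(c, 3)
        k = self.rng.randrange(3)
        t = self.node_tips[c].pop(k)
        b = self._new_node(t)
        self._add(c, 2)
        self._add(b, 1)

    def check_invariants(self) -> None:
        x1, x2, x3 = self.counts
        assert x1 + 2 * x2 + 3 * x3 == 2 * self.N, "tip conservation violated"
        assert all(1 <= len(self.node_tips[n]) <= 3
                   for s in self.species for n in s), "node degree out of range"


def init_state(N: int, seed=None) -> SimState:
    """Fully fragmented initial state: 2N free tips, all nodes degree 1."""
    return SimState(N, seed)


def propensities(state: SimState, rates: RateParams) -> tuple:
    """Propensities of (tip-tip fusion, tip-tip fission, tip-side fusion,
    tip-side fission) under the chosen convention.

    The ``"squared"`` tip-to-tip fusion term is zeroed when fewer than two
    degree-1 nodes exist, since no physical pair is available.
    """
    x1, x2, x3 = state.counts
    conv = rates.convention
    if conv == "squared":
        f1 = rates.a1 * x1 * x1 if x1 >= 2 else 0.0
    else:
        f1 = rates.a1 * x1 * (x1 - 1) / 2.0
    f2 = rates.a2 * x1 * x2
    d1 = rates.b1 * x2
    d2 = rates.b2 * x3 * (3.0 if conv == "triple-fission" else 1.0)
    return f1, d1, f2, d2


def step(state: SimState, rates: RateParams) -> SimState:
    """Execute one Gillespie event in place: exponential waiting time at
    the total propensity, channel chosen proportionally, reactants chosen
    uniformly among eligible agents."""
    f1, d1, f2, d2 = propensities(state, rates)
    total = f1 + d1 + f2 + d2
    if total <= 0.0:
        raise AbsorbingStateError(
            "all propensities zero (no fusion possible and nothing to split)")
    state.time += state.rng.expovariate(total)
    u = state.rng.random() * total
    if u < f1:
        state.fuse_tip_tip()
    elif u < f1 + d1:
        state.fiss_tip_tip()
    elif u < f1 + d1 + f2:
        state.fuse_tip_side()
    else:
        state.fiss_tip_side()
    state.n_events += 1
    return state


def realized_graph(state: SimState) -> nx.MultiGraph:
    """The current network: one unit edge per tube between its tips' nodes."""
    g = nx.MultiGraph()
    g.add_nodes_from(n for s in state.species for n in s)
    tn = state.tip_node
    g.add_edges_from((tn[2 * i], tn[2 * i + 1]) for i in range(state.N))
    return g


def _giant_and_clusters(state: SimState) -> tuple:
    """(N_g, cluster edge counts) via union-find over the N edges."""
    parent = list(range(len(state.node_tips)))

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    tn = state.tip_node
    for i in range(state.N):
        a, b = find(tn[2 * i]), find(tn[2 * i + 1])
        if a != b:
            parent[a] = b
    counts: dict = {}
    for i in range(state.N):
        r = find(tn[2 * i])
        counts[r] = counts.get(r, 0) + 1
    sizes = sorted(counts.values(), reverse=True)
    return sizes[0], sizes


@dataclass
class SimResult:
    """Outcome of a single run: realized network summaries plus the
    species-fraction trajectory sampled on an event-count grid."""

    N: int
    seed: object
    n_events: int
    counts: tuple
    mean_degree: float
    giant_size: int
    giant_frac: float
    cluster_sizes: list
    trajectory: np.ndarray  # columns: event, x1, x2, x3 fractions
    state: SimState = None
    stats: NetworkStats = None  # full morphology bundle, if requested

    def fractions(self) -> tuple:
        x1, x2, x3 = self.counts
        m = x1 + x2 + x3
        return x1 / m, x2 / m, x3 / m


def run(N: int, rates: RateParams, n_events: int = None, seed=None,
        full_stats: bool = False, record_trajectory: bool = True,
        n_trajectory_points: int = 200,
        check_invariants: bool = False) -> SimResult:
    """Run ``n_events`` Gillespie events (default ``5*N``) from the fully
    fragmented state and summarize the final network.

    ``full_stats=True`` additionally converts the realized network to a
    multigraph and computes the complete :class:`NetworkStats` bundle
    (loops, branches, cluster distribution).  ``check_invariants``
    asserts tip conservation and the degree <= 3 bound after every event.
    """
    if n_events is None:
        n_events = 5 * N
    state = init_state(N, seed)
    traj = []
    record_at = set()
    if record_trajectory:
        pts = np.unique(np.linspace(0, n_events, min(n_trajectory_points, n_events) + 1,
                                    dtype=int))
        record_at = set(pts.tolist())
        traj.append((0, *state.fractions()))
    for _ in range(n_events):
        try:
            step(state, rates)
        except AbsorbingStateError:
            break
        if check_invariants:
            state.check_invariants()
        if state.n_events in record_at:
            traj.append((state.n_events, *state.fractions()))
    ng, sizes = _giant_and_clusters(state)
    x1, x2, x3 = state.counts
    result = SimResult(
        N=N, seed=seed, n_events=state.n_events, counts=(x1, x2, x3),
        mean_degree=2 * N / (x1 + x2 + x3),
        giant_size=ng, giant_frac=ng / N, cluster_sizes=sizes,
        trajectory=np.asarray(traj, dtype=float), state=state,
    )
    if full_stats:
        result.stats = network_stats(realized_graph(state))
    return result


def _se(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class EnsembleResult:
    """Mean and standard error of the network summaries over an ensemble
    of independently seeded runs, plus pooled size distributions."""

    N: int
    reps: int
    rates: RateParams
    master_seed: object
    seeds: list
    mean_degree: float
    se_degree: float
    giant_frac: float
    se_giant_frac: float
    fractions: tuple        # mean (x1, x2, x3) node fractions
    se_fractions: tuple
    per_run_degree: np.ndarray
    per_run_giant: np.ndarray
    per_run_fractions: np.ndarray
    loop_sizes: list = field(default_factory=list)      # pooled over runs
    branch_lengths: list = field(default_factory=list)
    cluster_sizes: list = field(default_factory=list)
    mean_trajectory: np.ndarray = None
    results: list = None


def ensemble_seeds(master_seed, reps: int) -> list:
    """Deterministic per-run seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(reps) % (2 ** 31)]


def simulate_ensemble(N: int, rates: RateParams, reps: int = 100,
                      master_seed=0, n_events: int = None,
                      collect_distributions: bool = False,
                      collect_trajectories: bool = False,
                      keep_results: bool = False) -> EnsembleResult:
    """Repeat :func:`run` ``reps`` times with derived seeds and average.

    Distribution pooling (loops, branches, clusters) requires the full
    graph conversion per run and is off by default; the scalar summaries
    (mean degree, normalized giant cluster, species fractions) are always
    collected.
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    seeds = ensemble_seeds(master_seed, reps)
    runs = [run(N, rates, n_events=n_events, seed=s,
                full_stats=collect_distributions,
                record_trajectory=collect_trajectories)
            for s in seeds]
    deg = np.array([r.mean_degree for r in runs])
    gf = np.array([r.giant_frac for r in runs])
    fr = np.array([r.fractions() for r in runs])
    loops, branches, clusters = [], [], []
    if collect_distributions:
        for r in runs:
            loops.extend(r.stats.loop_sizes)
            branches.extend(r.stats.branch_lengths)
            clusters.extend(r.stats.cluster_sizes)
    mean_traj = None
    if collect_trajectories:
        grids = [r.trajectory for r in runs]
        n = min(t.shape[0] for t in grids)
        mean_traj = np.mean([t[:n] for t in grids], axis=0)
    return EnsembleResult(
        N=N, reps=reps, rates=rates, master_seed=master_seed, seeds=seeds,
        mean_degree=float(deg.mean()), se_degree=_se(deg),
        giant_frac=float(gf.mean()), se_giant_frac=_se(gf),
        fractions=tuple(fr.mean(axis=0)),
        se_fractions=tuple(_se(fr[:, i]) for i in range(3)),
        per_run_degree=deg, per_run_giant=gf, per_run_fractions=fr,
        loop_sizes=loops, branch_lengths=branches, cluster_sizes=clusters,
        mean_trajectory=mean_traj,
        results=runs if keep_results else None,
    )
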