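"""Tests of the agent-based Gillespie fission-fusion simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitonet.graphs import loop_sizes, network_stats
from mitonet.meanfield import mean_degree_meanfield, steady_state
from mitonet.simulate import (
    AbsorbingStateError,
    RateParams,
    init_state,
    propensities,
    realized_graph,
    run,
    simulate_ensemble,
    step,
)


class TestRateParams:
    def test_b2_defaults_to_three_halves_b1(self):
        r = RateParams(C1=1e-4, C2=1e-5)
        assert r.b2 == pytest.approx(1.5 * r.b1)
        assert r.a1 == pytest.approx(1e-4 * 0.01)
        assert r.a2 == pytest.approx(1e-5 * 0.015)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateParams(C1=-1.0, C2=0.0)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            RateParams(C1=0.0, C2=0.0, convention="nope")


class TestInitState:
    def test_all_tips_free(self):
        s = init_state(10, seed=0)
        assert s.counts == (20, 0, 0)
        x1, x2, x3 = s.counts
        assert x1 + 2 * x2 + 3 * x3 == 20
        g = realized_graph(s)
        assert g.number_of_edges() == 10
        assert all(d == 1 for _, d in g.degree())

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            init_state(0)


class TestPropensities:
    R = RateParams(C1=2.0, C2=3.0, b1=0.01, convention="pairwise")

    def _state_with(self, x1, x2, x3, N):
        s = init_state(N, seed=1)
        for _ in range(x2 + x3):
            s.fuse_tip_tip()
        for _ in range(x3):
            s.fuse_tip_side()
        assert s.counts == (x1, x2, x3)
        return s

    def test_initial_state_only_tip_tip_fusion(self):
        s = init_state(10, seed=0)
        f1, d1, f2, d2 = propensities(s, self.R)
        assert f1 == pytest.approx(self.R.a1 * 190)
        assert (d1, f2, d2) == (0.0, 0.0, 0.0)

    def test_no_free_tips_only_fission(self):
        s = self._state_with(0, 5, 2, 8)  # 0*1 + 2*5 + 3*2 = 16 tips
        f1, d1, f2, d2 = propensities(s, self.R)
        assert f1 == 0.0 and f2 == 0.0
        assert d1 == pytest.approx(self.R.b1 * 5)
        assert d2 == pytest.approx(self.R.b2 * 2)

    def test_single_free_tip_cannot_self_pair(self):
        s = self._state_with(1, 1, 1, 3)
        f1, d1, f2, d2 = propensities(s, self.R)
        assert f1 == 0.0  # a pair needs two degree-1 nodes
        assert f2 == pytest.approx(self.R.a2 * 1 * 1)

    def test_squared_convention_zeroed_below_two(self):
        s = self._state_with(1, 1, 1, 3)
        r = RateParams(C1=2.0, C2=3.0, convention="squared")
        assert propensities(s, r)[0] == 0.0


class TestChannels:
    def test_tip_tip_fission_bookkeeping(self):
        s = init_state(5, seed=3)
        s.fuse_tip_tip()
        assert s.counts == (8, 1, 0)
        s.fiss_tip_tip()
        assert s.counts == (10, 0, 0)
        s.check_invariants()

    def test_tip_side_fission_bookkeeping(self):
        s = init_state(5, seed=3)
        s.fuse_tip_tip()
        s.fuse_tip_side()
        assert s.counts == (7, 0, 1)
        s.fiss_tip_side()
        assert s.counts == (8, 1, 0)
        s.check_invariants()

    def test_self_fusion_makes_unit_loop(self):
        # with a single edge the only possible fusion joins its own tips
        s = init_state(1, seed=0)
        s.fuse_tip_tip()
        g = realized_graph(s)
        assert g.number_of_nodes() == 1
        assert g.number_of_edges() == 1
        assert dict(g.degree())[next(iter(g.nodes))] == 2
        assert loop_sizes(g) == [1]

    def test_absorbing_state_signalled(self):
        s = init_state(3, seed=0)
        with pytest.raises(AbsorbingStateError):
            step(s, RateParams(C1=0.0, C2=0.0))


class TestRun:
    def test_no_fusion_limit(self):
        r = run(20, RateParams(C1=0.0, C2=0.0), seed=4)
        assert r.mean_degree == 1.0
        assert r.giant_frac == pytest.approx(1 / 20)
        assert r.n_events == 0  # absorbing immediately

    def test_strong_fusion_forms_giant_cluster(self):
        r = run(200, RateParams(C1=0.5, C2=0.5), seed=4)
        assert r.giant_frac > 0.9

    def test_edge_count_conserved_and_consistent_with_graph(self):
        r = run(60, RateParams(C1=5e-3, C2=1e-3), seed=7, full_stats=True)
        assert r.stats.n_edges == 60
        assert r.stats.mean_degree == pytest.approx(r.mean_degree)
        assert r.stats.giant_frac == pytest.approx(r.giant_frac)
        assert sum(r.stats.cluster_sizes) == 60

    def test_determinism(self):
        a = run(50, RateParams(C1=1e-3, C2=1e-3), seed=11)
        b = run(50, RateParams(C1=1e-3, C2=1e-3), seed=11)
        assert a.counts == b.counts
        assert a.mean_degree == b.mean_degree
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_trajectory_fractions_sum_to_one(self):
        r = run(100, RateParams(C1=1e-3, C2=1e-3), seed=2)
        assert np.allclose(r.trajectory[:, 1:].sum(axis=1), 1.0)


@given(st.integers(0, 1000), st.floats(0, 0.01), st.floats(0, 0.01))
@settings(max_examples=15)
def test_conservation_and_degree_cap_hold_throughout(seed, c1, c2):
    """X1 + 2*X2 + 3*X3 == 2N and degree <= 3 after every event."""
    run(30, RateParams(C1=c1, C2=c2), seed=seed, check_invariants=True)


class TestEnsemble:
    def test_single_rep_reduces_to_run(self):
        rates = RateParams(C1=1e-3, C2=1e-4)
        ens = simulate_ensemble(40, rates, reps=1, master_seed=9)
        r = run(40, rates, seed=ens.seeds[0])
        assert ens.mean_degree == pytest.approx(r.mean_degree)
        assert ens.giant_frac == pytest.approx(r.giant_frac)

    def test_determinism_and_seed_derivation(self):
        rates = RateParams(C1=1e-3, C2=1e-4)
        a = simulate_ensemble(30, rates, reps=5, master_seed=3)
        b = simulate_ensemble(30, rates, reps=5, master_seed=3)
        assert a.seeds == b.seeds
        assert a.mean_degree == b.mean_degree
        assert all(s < 2 ** 31 for s in a.seeds)

    def test_matches_meanfield_fixed_point(self):
        """Stochastic means agree with the deterministic oracle (3 SE)."""
        c1, c2, n = 5e-4, 1e-4, 1000
        ens = simulate_ensemble(n, RateParams(C1=c1, C2=c2), reps=40,
                                master_seed=17)
        sol = steady_state(c1, c2, n)
        for mc, se, mf in zip(ens.fractions, ens.se_fractions, sol.fractions()):
            assert abs(mc - mf) < 3 * se + 1e-3

    def test_stationarity_after_5n_events(self):
        """Summaries after 5N and 10N events agree within sampling error."""
        rates = RateParams(C1=5e-4, C2=1e-4)
        a = simulate_ensemble(400, rates, reps=25, master_seed=5)
        b = simulate_ensemble(400, rates, reps=25, master_seed=6,
                              n_events=4000)
        z = abs(a.mean_degree - b.mean_degree) / np.hypot(a.se_degree, b.se_degree)
        assert z < 3.5

    def test_pooled_distributions_collected(self):
        ens = simulate_ensemble(50, RateParams(C1=5e-3, C2=1e-3), reps=3,
                                master_seed=2, collect_distributions=True)
        assert sum(ens.cluster_sizes) == 3 * 50
        assert all(b >= 1 for b in ens.branch_lengths)

    def test_mean_trajectory_shape(self):
        ens = simulate_ensemble(50, RateParams(C1=1e-3, C2=1e-4), reps=3,
                                master_seed=2, collect_trajectories=True)
        assert ens.mean_trajectory.shape[1] == 4
        assert np.allclose(ens.mean_trajectory[:, 1:].sum(axis=1), 1.0)
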