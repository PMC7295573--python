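"""Unit tests of the 1D LEF engine: binding, stepping, stalling, switching,
diffusive moves, terminal unloading and the two schedulers."""

import numpy as np
import pytest
from scipy import stats

from lefsim import (
    Barrier,
    LatticeConfig,
    LEFParams,
    bind_lef,
    diffusive_rates,
    diffusive_step,
    fixed_step_run,
    gillespie_run,
    init_simulation,
    switch_roles,
    translocate_active,
    unbind_lef,
)
from lefsim.config import ConfigurationError
from lefsim.engine import recommended_duration

from conftest import place_lef


class TestInit:
    def test_initial_state_all_unbound(self, small_state):
        st = small_state
        assert st.n_bound == 0
        assert st.time == 0.0
        assert np.all(st.left == -1)
        assert np.all(st.occ == 0)

    def test_determinism_identical_seeds(self):
        config = LatticeConfig(n_sites=200)
        params = LEFParams(n_lefs=10, k_bind=1.0, k_unbind=0.05)
        trajs = []
        for _ in range(2):
            st = init_simulation(config, params, seed=42)
            trajs.append(gillespie_run(st, 200.0, n_samples=50))
        np.testing.assert_array_equal(trajs[0].left, trajs[1].left)
        np.testing.assert_array_equal(trajs[0].right, trajs[1].right)
        np.testing.assert_array_equal(trajs[0].active_left, trajs[1].active_left)

    def test_pigeonhole_too_many_lefs(self):
        config = LatticeConfig(n_sites=10)
        params = LEFParams(n_lefs=6, k_bind=1.0, k_unbind=0.1)
        with pytest.raises(ConfigurationError):
            init_simulation(config, params, seed=0)

    def test_recommended_duration_formula(self):
        config = LatticeConfig(n_sites=1000)
        params = LEFParams(n_lefs=10, k_bind=0.5, k_unbind=0.01, v=1.0)
        # 400 * max(1/k_unbind + 1/k_bind, L/v + 1/k_bind)
        assert recommended_duration(config, params) == pytest.approx(
            400.0 * (1000.0 + 2.0)
        )


class TestBinding:
    def test_bind_occupies_adjacent_pair(self, small_state):
        st = bind_lef(small_state, 0)
        assert st.bound[0] == 1
        assert st.right[0] == st.left[0] + 1
        assert st.occ[st.left[0]] == 1
        assert st.check_occupancy()

    def test_uniform_loading_position_distribution(self):
        config = LatticeConfig(n_sites=50)
        params = LEFParams(n_lefs=1, k_bind=1.0, k_unbind=0.1)
        counts = np.zeros(50)
        st = init_simulation(config, params, seed=3)
        for _ in range(6000):
            bind_lef(st, 0)
            counts[st.left[0]] += 1
            unbind_lef(st, 0)
        # loading sites are 0..L-2, uniformly
        assert counts[49] == 0
        p = stats.chisquare(counts[:49]).pvalue
        assert p > 1e-4

    def test_one_sided_orientation_is_symmetric(self):
        config = LatticeConfig(n_sites=50)
        params = LEFParams(n_lefs=1, k_bind=1.0, k_unbind=0.1)
        st = init_simulation(config, params, seed=4)
        n_left = 0
        n = 4000
        for _ in range(n):
            bind_lef(st, 0)
            n_left += int(st.act_l[0])
            unbind_lef(st, 0)
        assert abs(n_left / n - 0.5) < 0.03

    def test_bind_rejected_when_sites_occupied(self):
        config = LatticeConfig(n_sites=4)
        params = LEFParams(n_lefs=2, k_bind=1.0, k_unbind=0.1)
        st = init_simulation(config, params, seed=5)
        place_lef(st, 0, 1, 2)
        # only pairs (0,1),(1,2),(2,3) exist and all clash with (1,2)
        for _ in range(50):
            bind_lef(st, 1)
        assert st.bound[1] == 0

    def test_directional_loading_sets_active_side(self):
        orient = np.zeros(50, dtype=np.int8)
        orient[10] = +1
        weights = np.zeros(50)
        weights[10] = 1.0
        config = LatticeConfig(n_sites=50, loading_weights=weights,
                               loading_orientation=orient)
        params = LEFParams(n_lefs=1, k_bind=1.0, k_unbind=0.1)
        st = init_simulation(config, params, seed=6)
        for _ in range(20):
            bind_lef(st, 0)
            assert (st.left[0], st.right[0]) == (10, 11)
            assert st.act_r[0] == 1 and st.act_l[0] == 0
            unbind_lef(st, 0)


class TestUnbinding:
    def test_unbind_frees_sites_and_clears_flags(self, small_state):
        st = place_lef(small_state, 0, 10, 20)
        st.stall_r[0] = 1
        unbind_lef(st, 0)
        assert st.occ[10] == 0 and st.occ[20] == 0
        assert st.bound[0] == 0 and st.stall_r[0] == 0

    def test_terminal_unload_site_triggers_unbind(self):
        config = LatticeConfig(n_sites=30, terminal_unload_sites=[29])
        params = LEFParams(n_lefs=1, k_bind=1.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=7)
        place_lef(st, 0, 27, 28, active="right")
        translocate_active(st, 0, "right")  # steps onto site 29 -> ter
        assert st.bound[0] == 0
        assert np.all(st.occ == 0)

    def test_bound_fraction_matches_two_state_kinetics(self):
        # long run: mean bound fraction -> k_bind / (k_bind + k_unbind)
        config = LatticeConfig(n_sites=500)
        params = LEFParams(n_lefs=20, k_bind=0.3, k_unbind=0.1, v=0.5)
        st = init_simulation(config, params, seed=8)
        traj = gillespie_run(st, 4000.0, n_samples=400)
        frac = traj.bound_fraction()[100:].mean()
        expected = 0.3 / 0.4
        assert abs(frac - expected) < 0.03


class TestTranslocation:
    def test_two_sided_loop_grows_at_2v(self):
        config = LatticeConfig(n_sites=4001)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, v=1.0,
                           sidedness=1.0)
        st = init_simulation(config, params, seed=9)
        place_lef(st, 0, 2000, 2001, two_sided=True)
        t = 500.0
        traj = gillespie_run(st, t, n_samples=1)
        size = st.right[0] - st.left[0]
        assert size == pytest.approx(2 * params.v * t, rel=0.15)

    def test_blocking_by_other_subunit(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=2, k_bind=0.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=10)
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 15, active="right")
        translocate_active(st, 0, "right")  # site 11 occupied
        assert st.right[0] == 10

    def test_stepping_passive_subunit_is_logic_error(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=11)
        place_lef(st, 0, 5, 10, active="right")
        with pytest.raises(ValueError):
            translocate_active(st, 0, "left")

    @pytest.mark.parametrize("p_stall,crosses", [(0.0, True), (1.0, False)])
    def test_barrier_stall_probability_limits(self, p_stall, crosses):
        config = LatticeConfig(
            n_sites=30, barriers=[Barrier(11, "right-blocking", p_stall)]
        )
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=12)
        place_lef(st, 0, 5, 10, active="right")
        for _ in range(5):
            translocate_active(st, 0, "right")
        if crosses:
            assert st.right[0] == 15
            assert st.stall_r[0] == 0
        else:
            assert st.right[0] == 10
            assert st.stall_r[0] == 1

    def test_barrier_only_blocks_its_direction(self):
        config = LatticeConfig(
            n_sites=30, barriers=[Barrier(11, "left-blocking", 1.0)]
        )
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=13)
        place_lef(st, 0, 5, 10, active="right")
        translocate_active(st, 0, "right")  # crossing rightward is free
        assert st.right[0] == 11

    def test_stall_scope_partner_continues(self):
        config = LatticeConfig(
            n_sites=40, barriers=[Barrier(21, "right-blocking", 1.0)]
        )
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, sidedness=1.0)
        st = init_simulation(config, params, seed=14)
        place_lef(st, 0, 19, 20, two_sided=True)
        translocate_active(st, 0, "right")
        assert st.stall_r[0] == 1
        for _ in range(5):
            translocate_active(st, 0, "left")
        assert st.left[0] == 14  # left subunit unaffected

    def test_traversal_ignores_occupancy(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=2, k_bind=0.0, k_unbind=0.0, traversal=True)
        st = init_simulation(config, params, seed=15)
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 15, active="right")
        translocate_active(st, 0, "right")
        assert st.right[0] == 11  # co-occupies site 11


class TestPushing:
    def _setup(self, mode):
        config = LatticeConfig(n_sites=40)
        params = LEFParams(n_lefs=3, k_bind=0.0, k_unbind=0.0, pushing=mode)
        st = init_simulation(config, params, seed=16)
        return st

    def test_weak_pushing_displaces_single_passive(self):
        st = self._setup("weak")
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 20, active="right")  # passive-left at 11
        translocate_active(st, 0, "right")
        assert st.right[0] == 11
        assert st.left[1] == 12
        assert st.check_occupancy()

    def test_weak_pushing_cannot_move_train_of_two(self):
        st = self._setup("weak")
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 20, active="right")
        place_lef(st, 2, 12, 25, active="right")  # wait: 12 inside (11,20)?
        # rearrange: passive subunits at 11 and 12 belong to two LEFs
        st = self._setup("weak")
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 30, active="right")
        place_lef(st, 2, 12, 29, active="right")
        translocate_active(st, 0, "right")
        assert st.right[0] == 10  # blocked: two passive subunits ahead

    def test_strong_pushing_displaces_train(self):
        st = self._setup("strong")
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 30, active="right")
        place_lef(st, 2, 12, 29, active="right")
        translocate_active(st, 0, "right")
        assert st.right[0] == 11
        assert st.left[1] == 12
        assert st.left[2] == 13
        assert st.check_occupancy()

    def test_pushing_blocked_by_active_subunit(self):
        st = self._setup("strong")
        place_lef(st, 0, 5, 10, active="right")
        place_lef(st, 1, 11, 30, active="left")  # active at 11
        translocate_active(st, 0, "right")
        assert st.right[0] == 10


class TestDiffusive:
    def test_rates_printed_formula(self):
        params = LEFParams(n_lefs=1, k_bind=1, k_unbind=1, v_diff=1.0)
        grow, shrink = diffusive_rates(1, params)
        assert grow == pytest.approx(np.exp(-1.5), rel=1e-12)
        assert shrink == pytest.approx(np.exp(1.5), rel=1e-12)
        grow10, _ = diffusive_rates(10, params)
        assert grow10 == pytest.approx(np.exp(-0.15), rel=1e-12)

    def test_rates_monotone_to_vdiff(self):
        params = LEFParams(n_lefs=1, k_bind=1, k_unbind=1, v_diff=2.0)
        g1, s1 = diffusive_rates(5, params)
        g2, s2 = diffusive_rates(1e9, params)
        assert g1 <= params.v_diff <= s1
        assert g2 == pytest.approx(params.v_diff, rel=1e-6)
        assert s2 == pytest.approx(params.v_diff, rel=1e-6)

    def test_detailed_balance_ratio(self):
        # shrink/grow ratio equals exp(3/ell): loop-entropy free-energy step
        params = LEFParams(n_lefs=1, k_bind=1, k_unbind=1, v_diff=1.3)
        for ell in (1, 2, 7, 50):
            g, s = diffusive_rates(ell, params)
            assert s / g == pytest.approx(np.exp(3.0 / ell), rel=1e-9)

    def test_minimum_loop_shrink_rejected(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, v_diff=1.0)
        st = init_simulation(config, params, seed=17)
        place_lef(st, 0, 10, 11, active="right")  # passive-left, loop = 1
        for _ in range(50):
            diffusive_step(st, 0, grow=False)
        assert (st.left[0], st.right[0]) == (10, 11)

    def test_vdiff_zero_reduces_to_pure_one_sided(self):
        # the anchored subunit never moves while the active one extrudes
        config = LatticeConfig(n_sites=500)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, v_diff=0.0)
        st = init_simulation(config, params, seed=18)
        place_lef(st, 0, 250, 251, active="right")
        traj = fixed_step_run(st, 0.1, 200.0, n_samples=50, method="sweep")
        assert np.all(traj.left[:, 0] == 250)
        assert traj.right[-1, 0] > 251

    def test_large_loop_walk_is_unbiased(self):
        config = LatticeConfig(n_sites=5001)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, v=0.0,
                           v_diff=1.0)
        st = init_simulation(config, params, seed=19)
        place_lef(st, 0, 100, 4900, active="right")  # huge loop, passive-left
        disp = []
        for rep in range(200):
            start = st.left[0]
            for _ in range(20):
                diffusive_step(st, 0, grow=bool(np.random.default_rng(rep).integers(2)))
            disp.append(st.left[0] - start)
            st.left[0] = 100 if st.occ[100] == 0 else st.left[0]
        # mean displacement per attempt ~ 0 for ell >> 1
        assert abs(np.mean(disp)) < 1.5


class TestSwitching:
    def test_switch_swaps_roles(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, k_switch=1.0)
        st = init_simulation(config, params, seed=20)
        place_lef(st, 0, 5, 10, active="left")
        switch_roles(st, 0)
        assert st.act_l[0] == 0 and st.act_r[0] == 1

    def test_switch_on_two_sided_is_error(self):
        config = LatticeConfig(n_sites=30)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0, sidedness=1.0)
        st = init_simulation(config, params, seed=21)
        place_lef(st, 0, 5, 10, two_sided=True)
        with pytest.raises(ValueError):
            switch_roles(st, 0)

    def test_fast_switching_splits_active_time_evenly(self):
        # k_switch/k_unbind = 30: each side active ~half the bound lifetime
        config = LatticeConfig(n_sites=2000)
        params = LEFParams(n_lefs=5, k_bind=1.0, k_unbind=0.01, k_switch=0.3)
        st = init_simulation(config, params, seed=22)
        traj = gillespie_run(st, 30000.0, n_samples=2000)
        m = traj.bound == 1
        frac_left = traj.active_left[m].mean()
        assert abs(frac_left - 0.5) < 0.05

    def test_kswitch_zero_matches_pure_one_sided(self):
        config = LatticeConfig(n_sites=300)
        base = dict(n_lefs=6, k_bind=0.5, k_unbind=0.05)
        t1 = gillespie_run(
            init_simulation(config, LEFParams(k_switch=0.0, **base), seed=33),
            2000.0, n_samples=100)
        t2 = gillespie_run(
            init_simulation(config, LEFParams(**base), seed=33),
            2000.0, n_samples=100)
        np.testing.assert_array_equal(t1.left, t2.left)
        np.testing.assert_array_equal(t1.right, t2.right)


class TestSchedulers:
    def test_gillespie_refuses_semi_diffusive(self):
        config = LatticeConfig(n_sites=100)
        params = LEFParams(n_lefs=2, k_bind=1.0, k_unbind=0.1, v_diff=0.5)
        st = init_simulation(config, params, seed=23)
        with pytest.raises(ConfigurationError):
            gillespie_run(st, 10.0)

    def test_fixed_step_rejects_coarse_dt(self):
        config = LatticeConfig(n_sites=100)
        params = LEFParams(n_lefs=2, k_bind=1.0, k_unbind=0.1)
        st = init_simulation(config, params, seed=24)
        with pytest.raises(ConfigurationError):
            fixed_step_run(st, 0.5, 10.0)  # k_bind*dt = 0.5 > 0.1

    def test_unbinding_waiting_times_exponential(self):
        # exponential residence times: sampled at interval dt the bound-state
        # sojourns of the chain are geometric with p = 1 - exp(-k_unbind*dt)
        config = LatticeConfig(n_sites=50)
        k_u, k_b, dt = 0.2, 0.02, 0.5
        params = LEFParams(n_lefs=1, k_bind=k_b, k_unbind=k_u, v=0.0)
        st = init_simulation(config, params, seed=25)
        traj = gillespie_run(st, 60000.0, sample_interval=dt)
        b = traj.bound[:, 0]
        # lengths of maximal bound runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], b, [0]))))
        runs = edges[1::2] - edges[::2]
        p_geom = 1.0 - np.exp(-k_u * dt)
        # chi-square against the geometric law over the first bins
        kmax = 30
        obs = np.array([(runs == k).sum() for k in range(1, kmax)])
        obs = np.append(obs, (runs >= kmax).sum())
        exp_p = np.array([p_geom * (1 - p_geom) ** (k - 1)
                          for k in range(1, kmax)])
        exp_p = np.append(exp_p, (1 - p_geom) ** (kmax - 1))
        n = len(runs)
        assert n > 300
        pval = stats.chisquare(obs, exp_p * n).pvalue
        assert pval > 1e-3

    def test_scheduler_cross_validation_one_sided(self):
        # same lambda/d: steady-state mean FC agrees between schedulers
        from lefsim.metrics import steady_state_summary

        config = LatticeConfig(n_sites=2000)
        params = LEFParams(n_lefs=40, k_bind=0.2, k_unbind=0.002)
        tau = 1 / params.k_unbind
        fcs = {}
        for method in ("gillespie", "events", "sweep"):
            trajs = []
            for rep in range(3):
                st = init_simulation(config, params, seed=100 + rep)
                if method == "gillespie":
                    gillespie_run(st, 10 * tau, n_samples=1)
                    trajs.append(gillespie_run(st, 20 * tau,
                                               sample_interval=tau / 10))
                else:
                    fixed_step_run(st, 0.1, 10 * tau, n_samples=1,
                                   method=method)
                    trajs.append(fixed_step_run(st, 0.1, 20 * tau,
                                                sample_interval=tau / 10,
                                                method=method))
            fcs[method] = steady_state_summary(trajs, burn_in=0.0).fc
        assert fcs["events"] == pytest.approx(fcs["gillespie"], rel=0.05)
        assert fcs["sweep"] == pytest.approx(fcs["gillespie"], rel=0.05)

    def test_deterministic_extruder_position(self):
        # deterministic mode: active subunit advances one site per step
        config = LatticeConfig(n_sites=200)
        params = LEFParams(n_lefs=1, k_bind=0.0, k_unbind=0.0)
        st = init_simulation(config, params, seed=26)
        place_lef(st, 0, 100, 101, active="right")
        fixed_step_run(st, 1.0, 50.0, n_samples=1, method="sweep",
                       deterministic=True)
        assert st.right[0] == 151

    def test_occupancy_conserved_through_runs(self):
        config = LatticeConfig(n_sites=300)
        params = LEFParams(n_lefs=20, k_bind=0.5, k_unbind=0.05,
                           sidedness=0.5)
        st = init_simulation(config, params, seed=27)
        for _ in range(5):
            gillespie_run(st, st.time + 200.0, n_samples=1)
            assert st.check_occupancy()
            if st.n_bound:
                loops = st.loops()
                assert all(l < r for l, r in loops)
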