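"""Scenario presets: mitotic sweeps, interphase TAD layouts, bacterial
parS/ter chromosomes and their analyses."""

import numpy as np
import pytest

from lefsim import derived_scales, gillespie_run, init_simulation
from lefsim.config import ConfigurationError
from lefsim.contacts import ContactMap, accumulate_map
from lefsim import scenarios as sc

from conftest import place_lef


class TestMitoticConfigs:
    def test_emitted_configs_are_runnable(self):
        for variant in sc.VARIANTS:
            kw = {}
            if variant == "mix":
                kw["fraction_two_sided"] = 0.5
            elif variant == "switching":
                kw["k_switch_over_k_unbind"] = 10.0
            elif variant == "semi-diffusive":
                kw["v_diff_over_v"] = 1.0
            config, params = sc.mitotic_config(variant, 50, 1000, 20, **kw)
            st = init_simulation(config, params, seed=1)
            assert st.n_bound == 0

    def test_derived_lam_over_d_matches_request(self):
        config, params = sc.mitotic_config("one-sided", 100, 10_000, 200)
        ds = derived_scales(config, params)
        assert ds.lam_over_d == pytest.approx(100.0, rel=0.02)
        config, params = sc.mitotic_config("two-sided", 50, 10_000, 200)
        ds = derived_scales(config, params)
        assert ds.lam_over_d == pytest.approx(50.0, rel=0.02)

    def test_bound_fraction_realizes_derived_d(self):
        # steady state: simulated bound count matches N_b = N kb/(kb+ku)
        config, params = sc.mitotic_config("one-sided", 20, 2000, 40)
        st = init_simulation(config, params, seed=2)
        tau = 1 / params.k_unbind
        traj = gillespie_run(st, 20 * tau, sample_interval=tau / 5)
        nb = traj.bound.sum(axis=1)[20:].mean()
        ds = derived_scales(config, params)
        assert nb == pytest.approx(ds.n_bound_mean, rel=0.02)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.mitotic_config("one-sided", 100, 1000, 600)

    def test_mixture_endpoints_reduce_to_pure_models(self):
        c0, p0 = sc.mitotic_config("mix", 30, 2000, 40, fraction_two_sided=0.0)
        c1, p1 = sc.mitotic_config("one-sided", 30, 2000, 40)
        assert p0 == p1
        c0, p0 = sc.mitotic_config("mix", 30, 2000, 40, fraction_two_sided=1.0)
        c1, p1 = sc.mitotic_config("two-sided", 30, 2000, 40)
        assert p0 == p1

    def test_fc_crossing_bracketing(self):
        x = [20, 35, 50, 65, 100]
        y = [100, 400, 2000, 5000, 9000]
        crossing, bracket = sc.find_fc_crossing(x, y, 1000.0)
        assert bracket == (35.0, 50.0)
        assert 35 < crossing < 50
        crossing, bracket = sc.find_fc_crossing(x, [2e3] * 5, 1000.0)
        assert bracket is None and crossing == 20.0


class TestInterphase:
    def test_layout_boundaries(self):
        lay = sc.InterphaseLayout(n_repeats=2)
        assert lay.n_sites == 1400
        assert lay.boundaries[:5] == [0, 100, 300, 700, 800]
        assert len(lay.tads) == 6

    def test_config_has_convergent_barriers(self):
        lay = sc.InterphaseLayout(n_repeats=2)
        config, params = sc.interphase_config(lay)
        sites = {b.site for b in config.barriers}
        assert set(lay.boundaries) <= sites
        orientations = {
            (b.site, b.orientation) for b in config.barriers
        }
        assert (100, "left-blocking") in orientations
        assert (100, "right-blocking") in orientations

    def test_directional_loading_sites(self):
        lay = sc.InterphaseLayout(n_repeats=2, loading_bias=100.0)
        config, _ = sc.interphase_config(lay)
        w = np.asarray(config.loading_weights)
        assert w[101] == 100.0 and w[98] == 100.0
        assert config.loading_orientation[101] == 1
        assert config.loading_orientation[98] == -1

    def test_dot_strength_flat_map_is_one(self):
        lay = sc.InterphaseLayout(n_repeats=2)
        n = lay.n_sites // 10
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        d[d < 1] = 1
        cmap = ContactMap(d**-1.5, 10, 2.0)
        rep = sc.dot_strength(cmap, lay)
        assert rep.primary_mean == pytest.approx(1.0, abs=1e-9)
        assert rep.extended_mean == pytest.approx(1.0, abs=1e-9)

    def test_dot_strength_recovers_planted_corner(self, fixtures):
        i, j, enrich = fixtures.planted_dot
        cmap = ContactMap(fixtures.planted_dot_map, 10, 2.0)
        lay = sc.InterphaseLayout(tad_sizes=(100, 200, 100),
                                  n_repeats=1)
        # plant aligns with the (100, 300) TAD: bins 10 and 30.  The O/E
        # normalization dilutes the planted 5x pixel by its own contribution
        # to the diagonal mean: 20 pixels on that diagonal, one enriched.
        n_diag = fixtures.planted_dot_map.shape[0] - (j - i)
        expected = enrich / (1 + (enrich - 1) / n_diag)
        rep = sc.dot_strength(cmap, lay, window=1)
        assert rep.primary[200] == pytest.approx(expected, rel=0.01)

    def test_ungapped_tad_trivial_cases(self):
        from lefsim.engine import Trajectory

        lay = sc.InterphaseLayout(tad_sizes=(100,), n_repeats=2)
        n = lay.n_sites
        # no LEFs -> 0 %
        z = np.zeros((1, 1), np.uint8)
        empty = Trajectory(np.zeros(1), np.full((1, 1), -1, np.int64),
                           np.full((1, 1), -1, np.int64), z.copy(), z.copy(),
                           z.copy(), z.copy(), np.zeros((1, 1), np.uint8), n)
        assert sc.ungapped_tad_fraction(empty, lay) == 0.0
        # one permanent loop spanning a TAD boundary-to-boundary -> 50 %
        left = np.array([[0]], np.int64)
        right = np.array([[100]], np.int64)
        full = Trajectory(np.zeros(1), left, right, z.copy(), z.copy(),
                          z.copy(), z.copy(), np.ones((1, 1), np.uint8), n)
        assert sc.ungapped_tad_fraction(full, lay) == 50.0
        assert sc.ungapped_tad_fraction(full, lay, predicate="anchors") == 50.0


class TestBacterial:
    def test_parS_loading_analytics(self):
        lay = sc.BacterialLayout()
        assert lay.parS == 2000
        assert lay.k_unbind == pytest.approx(2.0 / 4000)
        # overall preference parS : any single other site = 40,000
        frac = lay.parS_load_fraction()
        assert frac == pytest.approx(10 / 11, rel=0.01)

    def test_parS_loading_histogram(self):
        config, params = sc.bacterial_config()
        st = init_simulation(config, params, seed=3)
        from lefsim import bind_lef, unbind_lef

        n, hits = 2000, 0
        for _ in range(n):
            bind_lef(st, 0)
            if st.bound[0]:
                hits += st.left[0] == 2000
                unbind_lef(st, 0)
        p = sc.BacterialLayout().parS_load_fraction()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 4 * sd

    def test_ter_sites_diametric(self):
        lay = sc.BacterialLayout()
        assert lay.ter_sites == [0, 1, 2, 3, 3996, 3997, 3998, 3999]

    def test_density_decays_from_parS(self):
        traj, _ = sc.build_bacterial("one-sided", n_snapshots=400, seed=4,
                                     sample_every=20)
        prof = sc.occupancy_profile(traj, n_windows=10)
        center = prof[4:6].mean()
        edges = (prof[0] + prof[-1]) / 2
        assert center > 2 * edges

    def test_secondary_diagonal_synthetic_ridge(self):
        # a map that is pure distance-law plus a delta ridge on the
        # anti-diagonal has a strong, 1-bin-wide ridge
        n = 80
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        d[d < 1] = 1
        m = d**-1.5
        for x in range(2, 38):
            m[40 - x, 40 + x] += 50 * m[40 - x, 40 + x]
            m[40 + x, 40 - x] = m[40 - x, 40 + x]
        cmap = ContactMap(m, 50, 1.0)
        prof = sc.secondary_diagonal_profile(cmap)
        assert prof["ridge_present"]
        assert prof["median_width_bins"] <= 2.0
        flat = sc.secondary_diagonal_profile(ContactMap(d**-1.5, 50, 1.0))
        assert not flat["ridge_present"]
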