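import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import spearmanr

from giantcell.errors import ConfigError
from giantcell.sim import (
    SimParams,
    crop_maximal_rectangle,
    cycle_events,
    divide_cell,
    grow_and_dilute,
    init_simulation,
    langevin_step,
    largest_interior_rectangle,
    run_simulation,
    shortest_centroid_wall,
    sim_giant_set,
    table_for_tissue,
    _polygon_area,
)
from giantcell.tissue import CellTable


def quiet_params(**kw):
    """No noise, no growth, no events unless overridden."""
    defaults = dict(c0=0.0, k_radial=0.0, k_axial=0.0,
                    theta_CS=1e8, theta_CD=2e8, theta_T=1e9, seed=0)
    defaults.update(kw)
    return SimParams(**defaults)


class TestInit:
    def test_initial_ranges(self):
        state = init_simulation(SimParams(seed=3))
        assert ((state.A >= 0) & (state.A < 1)).all()
        assert ((state.T >= 0) & (state.T < 0.1)).all()
        assert (state.ploidy == 2).all()
        assert not state.committed.any()

    def test_determinism(self):
        a = init_simulation(SimParams(seed=5))
        b = init_simulation(SimParams(seed=5))
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_patch_size(self):
        state = init_simulation(SimParams(n_init_rings=2))
        assert 16 <= state.n_cells <= 24

    def test_timer_correlates_with_area(self):
        rhos = []
        for seed in range(50):
            state = init_simulation(SimParams(seed=seed))
            rhos.append(spearmanr(state.areas, state.C).statistic)
        assert np.mean(rhos) > 0.8

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            SimParams(theta_CS=2.0, theta_CD=1.0).validate()
        with pytest.raises(ConfigError):
            SimParams(dt=0.0).validate()
        with pytest.raises(ConfigError):
            SimParams(n_A=0.5).validate()


class TestLangevin:
    def test_linear_fixed_point(self):
        p = quiet_params(V_A=0.0, P_A=0.4, G_A=0.8, dt=0.05)
        state = init_simulation(p)
        for _ in range(2000):
            langevin_step(state, p)
        np.testing.assert_allclose(state.A, 0.4 / 0.8, rtol=1e-6)

    def test_target_fixed_point_frozen_a(self):
        p = quiet_params(P_A=0.0, V_A=0.0, G_A=0.0, V_T=1.2, K_T=0.7,
                         n_T=4.0, G_T=0.25, dt=0.05)
        state = init_simulation(p)
        state.A[:] = 0.9  # frozen: no production/degradation of A
        for _ in range(3000):
            langevin_step(state, p)
        a = 0.9
        expected = 1.2 * a**4 / (0.7**4 + a**4) / 0.25
        np.testing.assert_allclose(state.T, expected, rtol=1e-6)

    def test_bistable_roots_match_bracketing_oracle(self):
        from scipy.optimize import brentq

        p = quiet_params(P_A=0.05, V_A=2.0, K_A=1.0, n_A=4.0, G_A=1.0, dt=0.05)
        f = lambda A: p.P_A + p.V_A * A**p.n_A / (p.K_A**p.n_A + A**p.n_A) - p.G_A * A
        # brute-force root bracketing oracle
        xs = np.linspace(0, 3, 2000)
        roots = sorted(
            brentq(f, xs[i], xs[i + 1])
            for i in range(len(xs) - 1)
            if f(xs[i]) * f(xs[i + 1]) < 0
        )
        assert len(roots) == 3
        state = init_simulation(p)
        half = state.n_cells // 2
        state.A[:half] = 0.01
        state.A[half:] = 2.5
        for _ in range(3000):
            langevin_step(state, p)
        np.testing.assert_allclose(state.A[:half], roots[0], rtol=1e-5)
        np.testing.assert_allclose(state.A[half:], roots[2], rtol=1e-5)

    def test_noise_off_matches_reference_ode(self):
        # independent high-order integrator over the full time span
        p = quiet_params(P_A=0.2, V_A=1.5, K_A=0.95, n_A=4.0, G_A=1.0,
                         V_T=1.0, K_T=0.7, n_T=4.0, G_T=0.3)
        state = init_simulation(p)
        A0, T0 = state.A.copy(), state.T.copy()
        n_steps = int(round(135.0 / p.dt))
        for _ in range(n_steps):
            langevin_step(state, p)

        def rhs(_, y):
            n = len(y) // 2
            A, T = y[:n], y[n:]
            hill_A = p.V_A * A**p.n_A / (p.K_A**p.n_A + A**p.n_A)
            hill_T = p.V_T * A**p.n_T / (p.K_T**p.n_T + A**p.n_T)
            return np.concatenate([p.P_A + hill_A - p.G_A * A, hill_T - p.G_T * T])

        sol = solve_ivp(rhs, (0, 135.0), np.concatenate([A0, T0]),
                        rtol=1e-10, atol=1e-12, dense_output=False)
        n = len(A0)
        np.testing.assert_allclose(state.A, sol.y[:n, -1], rtol=1e-3)
        np.testing.assert_allclose(state.T, sol.y[n:, -1], rtol=1e-3)


class TestGrowth:
    def test_zero_rates_identity(self):
        p = quiet_params()
        state = init_simulation(p)
        areas = state.areas.copy()
        A = state.A.copy()
        grow_and_dilute(state, p)
        np.testing.assert_array_equal(state.areas, areas)
        np.testing.assert_array_equal(state.A, A)

    def test_area_growth_factor_exact(self):
        p = quiet_params(k_radial=0.01, k_axial=0.02)
        state = init_simulation(p)
        total0 = state.total_area()
        for _ in range(100):
            grow_and_dilute(state, p)
        expected = total0 * math.exp((0.01 + 0.02) * 100 * p.dt)
        assert state.total_area() == pytest.approx(expected, rel=1e-6)
        # recomputed polygon areas agree with the bookkeeping
        poly = sum(_polygon_area(state.cell_polygon(i)) for i in range(state.n_cells))
        assert poly == pytest.approx(state.total_area(), rel=1e-9)

    def test_pure_growth_conserves_amount(self):
        p = quiet_params(P_A=0.0, V_A=0.0, G_A=0.0, V_T=0.0, G_T=0.0, P_C=0.0,
                         k_radial=0.015, k_axial=0.005)
        state = init_simulation(p)
        amount0 = state.A * state.areas
        for _ in range(50):
            langevin_step(state, p)
            grow_and_dilute(state, p)
        np.testing.assert_allclose(state.A * state.areas, amount0, rtol=1e-9)

    def test_anisotropic_growth_increases_aspect(self):
        p = quiet_params(k_radial=0.005, k_axial=0.03)
        state = init_simulation(p)

        def aspect(s):
            span = s.vertices.max(axis=0) - s.vertices.min(axis=0)
            return span[1] / span[0]

        a0 = aspect(state)
        prev = a0
        for _ in range(100):
            grow_and_dilute(state, p)
            cur = aspect(state)
            assert cur > prev
            prev = cur


class TestCycleEvents:
    def test_s_phase_doubles_ploidy_once(self):
        p = quiet_params(theta_CS=0.5, theta_CD=1.0)
        state = init_simulation(p)
        state.C[:] = 0.6
        cycle_events(state, p)
        assert (state.ploidy == 4).all()
        cycle_events(state, p)  # post_S already set: no second doubling
        assert (state.ploidy == 4).all()

    def test_committed_endocycle_ploidy_sequence(self):
        p = quiet_params(theta_CS=0.5, theta_CD=1.0, theta_T=0.0)
        state = init_simulation(p)
        i = 0
        state.T[i] = 1.0
        ploidies = []
        for _ in range(3):
            state.C[i] = 0.6
            cycle_events(state, p)  # S-phase (doubling) + commitment
            state.C[i] = 1.1
            cycle_events(state, p)  # endocycle reset
            ploidies.append(int(state.ploidy[i]))
        assert ploidies == [4, 8, 16]
        assert state.committed[i]
        assert state.C[i] < 0.5

    def test_uncommitted_division_daughters(self):
        p = quiet_params(theta_CS=0.5, theta_CD=1.0, theta_T=1e9)
        state = init_simulation(p)
        n0 = state.n_cells
        i = 2
        state.C[i] = 1.2
        state.A[i] = 0.77
        state.T[i] = 0.33
        state.ploidy[i] = 4
        cycle_events(state, p)
        assert state.n_cells == n0 + 1
        j = state.n_cells - 1
        for d in (i, j):
            assert state.A[d] == pytest.approx(0.77)   # sisters share A
            assert state.T[d] == pytest.approx(0.33)   # and T at birth
            assert state.ploidy[d] == 2
            assert 0 <= state.C[d] < 0.5
            assert not state.post_S[d]

    def test_commitment_is_absorbing(self):
        p = quiet_params(theta_CS=0.5, theta_CD=1.0, theta_T=0.0)
        state = init_simulation(p)
        state.C[:] = 0.6
        cycle_events(state, p)
        assert state.committed.all()
        state.T[:] = 0.0
        cycle_events(state, p)
        assert state.committed.all()


class TestDivideGeometry:
    def _state_with_polygon(self, points):
        p = quiet_params()
        state = init_simulation(p)
        state.vertices = np.array(points, dtype=float)
        state.loops = [list(range(len(points)))]
        state.areas = np.array([_polygon_area(state.vertices)])
        for name in ("A", "T", "C"):
            setattr(state, name, np.zeros(1))
        state.ploidy = np.array([2])
        state.post_S = np.array([False])
        state.committed = np.array([False])
        state.divisions = np.array([0])
        state.last_division_time = np.array([-np.inf])
        state.ids = [1]
        state.lineage = [1]
        state.next_id = 2
        return state

    def test_rectangle_short_wall(self):
        state = self._state_with_polygon([[0, 0], [2, 0], [2, 1], [0, 1]])
        i, j = divide_cell(state, 0)
        a1 = _polygon_area(state.vertices[state.loops[i]])
        a2 = _polygon_area(state.vertices[state.loops[j]])
        assert a1 == pytest.approx(1.0, rel=1e-9)
        assert a2 == pytest.approx(1.0, rel=1e-9)
        # the wall is the vertical chord of length 1 at x=1
        new = state.vertices[-2:]
        np.testing.assert_allclose(sorted(new[:, 0]), [1.0, 1.0], atol=1e-6)

    def test_hexagon_matches_angular_bruteforce(self):
        pts = np.array(
            [[math.cos(a), math.sin(a)] for a in np.linspace(0, 2 * math.pi, 7)[:-1]]
        )
        cands = shortest_centroid_wall(pts, angle_step_deg=0.1)
        best = cands[0][0]
        # 3600-angle brute force oracle, independent chord computation
        from shapely.geometry import LineString, Polygon

        poly = Polygon(pts)
        c = np.array(poly.centroid.coords[0])
        lengths = []
        for ang in np.linspace(0, math.pi, 3600, endpoint=False):
            d = np.array([math.cos(ang), math.sin(ang)])
            line = LineString([c - 10 * d, c + 10 * d])
            seg = poly.intersection(line)
            lengths.append(seg.length)
        assert best == pytest.approx(min(lengths), rel=1e-3)
        assert best == pytest.approx(math.sqrt(3), rel=1e-3)

    def test_partition_law(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            angles = np.sort(rng.uniform(0, 2 * math.pi, 8))
            radii = rng.uniform(0.5, 1.5, 8)
            pts = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
            if _polygon_area(pts) <= 0:
                pts = pts[::-1]
            state = self._state_with_polygon(pts.tolist())
            mother = _polygon_area(np.array(pts))
            i, j = divide_cell(state, 0)
            a1 = _polygon_area(state.vertices[state.loops[i]])
            a2 = _polygon_area(state.vertices[state.loops[j]])
            assert a1 + a2 == pytest.approx(mother, rel=1e-9)


class TestRunSimulation:
    def test_t_end_zero_returns_initial(self):
        p = SimParams(t_end=0.0, seed=1)
        res = run_simulation(p)
        assert res.state.time == 0.0
        assert res.state.n_cells == init_simulation(p).n_cells

    def test_theta_t_infinite_pure_proliferation(self):
        p = SimParams(t_end=30.0, theta_T=np.inf, seed=2)
        res = run_simulation(p)
        assert not res.state.committed.any()
        assert res.state.n_cells > init_simulation(p).n_cells

    def test_theta_t_zero_all_commit_no_divisions(self):
        p = SimParams(t_end=40.0, theta_T=0.0, seed=3)
        res = run_simulation(p)
        st = res.state
        assert st.committed.all()
        assert st.n_cells == init_simulation(p).n_cells
        assert (st.ploidy >= 4).all()

    def test_invariants_over_run(self):
        p = SimParams(t_end=60.0, seed=4)
        res = run_simulation(p, snapshot_times=[30.0])
        st = res.state
        assert (st.ploidy >= 2).all()
        assert ((st.ploidy & (st.ploidy - 1)) == 0).all()  # powers of two
        assert st.total_area() > init_simulation(p).total_area()

    def test_determinism(self):
        a = run_simulation(SimParams(t_end=25.0, seed=6))
        b = run_simulation(SimParams(t_end=25.0, seed=6))
        np.testing.assert_array_equal(a.state.A, b.state.A)
        assert a.state.ids == b.state.ids
        t_a, _ = a.snapshots[25.0]
        t_b, _ = b.snapshots[25.0]
        np.testing.assert_array_equal(t_a.labels, t_b.labels)


class TestRasterAndCrop:
    def test_largest_rectangle_vs_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mask = rng.random((12, 14)) < 0.7
            r0, c0, h, w = largest_interior_rectangle(mask)
            assert mask[r0 : r0 + h, c0 : c0 + w].all()
            best = h * w
            # brute force over all rectangles
            H, W = mask.shape
            for rr in range(H):
                for cc in range(W):
                    for hh in range(1, H - rr + 1):
                        for ww in range(1, W - cc + 1):
                            if mask[rr : rr + hh, cc : cc + ww].all():
                                assert hh * ww <= best

    def test_crop_is_fully_tissue(self):
        res = run_simulation(SimParams(t_end=30.0, seed=7))
        tissue, _ = res.snapshots[30.0]
        crop = crop_maximal_rectangle(tissue)
        assert (crop.labels > 0).all()

    def test_snapshot_table_consistent(self):
        res = run_simulation(SimParams(t_end=30.0, seed=8))
        tissue, table = res.snapshots[30.0]
        assert set(table.ids) == tissue.cell_ids
        ctab = table_for_tissue(crop_maximal_rectangle(tissue), table)
        assert set(ctab.ids) <= set(table.ids)


class TestSimGiantSet:
    def _table(self, rows):
        return CellTable(pd.DataFrame(rows))

    def test_all_diploid_empty(self):
        table = self._table(
            [dict(id=1, area_um2=5.0, ploidy=2, is_border=False),
             dict(id=2, area_um2=9.0, ploidy=2, is_border=False)]
        )
        with pytest.warns(UserWarning):
            assert sim_giant_set(table) == set()

    def test_stated_rule_by_hand(self):
        table = self._table(
            [dict(id=1, area_um2=10.0, ploidy=32, is_border=False),
             dict(id=2, area_um2=7.0, ploidy=16, is_border=False),
             dict(id=3, area_um2=8.0, ploidy=8, is_border=False),
             dict(id=4, area_um2=3.0, ploidy=4, is_border=False)]
        )
        # threshold = 7 (min area among >=16C); 8C cell above it included
        assert sim_giant_set(table) == {1, 2, 3}

    def test_border_cells_do_not_set_threshold(self):
        table = self._table(
            [dict(id=1, area_um2=1.0, ploidy=16, is_border=True),
             dict(id=2, area_um2=9.0, ploidy=16, is_border=False),
             dict(id=3, area_um2=5.0, ploidy=2, is_border=False)]
        )
        assert sim_giant_set(table) == {1, 2}

    def test_first_arising_tracks_committed(self):
        res = run_simulation(SimParams(t_end=50.0, theta_T=0.0, seed=9),
                             snapshot_times=[20.0])
        _, tab20 = res.snapshots[20.0]
        _, tab50 = res.snapshots[50.0]
        fa20 = sim_giant_set(tab20, mode="first-arising")
        fa50 = sim_giant_set(tab50, mode="first-arising")
        # committed cells never divide: the early set maps into the late one
        assert fa20 <= fa50
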