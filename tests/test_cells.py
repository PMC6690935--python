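"""Cell agents: geometry, mechanics, metabolism, cycle, division."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

import nichesim.cells as cm
from nichesim.cells import (Cell, CellPopulation, backward_euler_step,
                            cycle_population_step, delaunay_neighbors,
                            divide_cell, mechanics_step, metabolism_step,
                            metabolism_population_step, surface_cells_alpha,
                            total_pair_overlap, divide_in_population)
from nichesim.config import CellConfig


def _pop(points, radius=5.0):
    pop = CellPopulation()
    for i, p in enumerate(np.atleast_2d(points)):
        pop.add(Cell(id=i, position=np.asarray(p, float), radius=radius))
    return pop


# --------------------------------------------------------------------------
# neighbour geometry
# --------------------------------------------------------------------------

class TestDelaunayNeighbors:
    def test_regular_tetrahedron_fully_connected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                        [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]]) * 10.0
        g = delaunay_neighbors(_pop(pts), cutoff=20.0)
        assert len(g.edges) == 6

    def test_cutoff_separates_clusters(self, rng):
        a = rng.normal(size=(20, 3)) * 5.0
        b = rng.normal(size=(20, 3)) * 5.0 + [200.0, 0, 0]
        g = delaunay_neighbors(_pop(np.vstack([a, b])), cutoff=50.0)
        cross = (g.edges[:, 0] < 20) != (g.edges[:, 1] < 20)
        assert not cross.any()

    def test_matches_bruteforce_delaunay(self, rng):
        pts = rng.random((50, 3)) * 100.0
        g = delaunay_neighbors(_pop(pts), cutoff=60.0)
        tri = Delaunay(pts)     # independent triangulation
        want = set()
        for simplex in tri.simplices:
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = sorted((simplex[i], simplex[j]))
                    if np.linalg.norm(pts[a] - pts[b]) <= 60.0:
                        want.add((a, b))
        got = {tuple(e) for e in g.edges}
        assert got == want

    def test_fewer_than_two_cells(self):
        assert len(delaunay_neighbors(_pop(np.zeros((1, 3))), 10.0).edges) == 0

    def test_symmetric_no_self_edges(self, rng):
        pts = rng.random((30, 3)) * 50.0
        g = delaunay_neighbors(_pop(pts), cutoff=100.0)
        assert (g.edges[:, 0] != g.edges[:, 1]).all()
        assert len(np.unique(np.sort(g.edges, axis=1), axis=0)) == len(g.edges)


class TestAlphaSurface:
    def test_center_cell_not_on_surface(self, rng):
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = np.vstack([v * 50.0, [[0.0, 0.0, 0.0]]])
        surf = surface_cells_alpha(_pop(pts), alpha=(60.0) ** 2)
        assert 100 not in surf

    def test_contains_convex_hull_vertices(self, rng):
        from scipy.spatial import ConvexHull
        pts = rng.random((80, 3)) * 100.0
        surf = set(surface_cells_alpha(_pop(pts), alpha=(150.0) ** 2).tolist())
        hull = set(ConvexHull(pts).vertices.tolist())
        assert hull <= surf

    def test_ball_surface_is_one_connected_shell(self, cell_ball_100):
        """Surface cells of a ball-like cluster form a single connected
        shell under the contact graph."""
        pop = cell_ball_100
        surf = surface_cells_alpha(pop, alpha=(3 * 5.0) ** 2)
        g = delaunay_neighbors(pop, cutoff=30.0)
        surf_set = set(surf.tolist())
        adj = {i: set() for i in surf_set}
        for a, b in g.edges:
            if int(a) in surf_set and int(b) in surf_set:
                adj[int(a)].add(int(b))
                adj[int(b)].add(int(a))
        seen = {surf[0]}
        stack = [int(surf[0])]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert seen == surf_set

    def test_packed_ball_surface_is_outer_shell(self, cell_ball_100):
        pop = cell_ball_100
        surf = surface_cells_alpha(pop, alpha=(3 * 5.0) ** 2)
        centroid = pop.position.mean(axis=0)
        r = np.linalg.norm(pop.position - centroid, axis=1)
        r_max = r.max()
        assert (r[surf] > r_max - 4 * 2 * 5.0).any()
        # every surface cell lies within two mean diameters of the rim
        assert (r[surf] >= r_max - 2 * 2 * 5.0 - 15).all()


# --------------------------------------------------------------------------
# mechanics
# --------------------------------------------------------------------------

class TestMechanics:
    def test_action_reaction_two_cells(self):
        pop = _pop([[0, 0, 0], [8.0, 0, 0]], radius=5.0)
        g = delaunay_neighbors(pop, cutoff=30.0)
        before = pop.position.copy()
        mechanics_step(pop, g, dt=1.0)
        d = pop.position - before
        assert np.allclose(d[0], -d[1], atol=1e-12)
        assert d[0][0] < 0.0 < d[1][0]          # pushed apart along x
        assert np.allclose(d[:, 1:], 0.0)

    def test_equilibrium_distance_no_motion(self):
        pop = _pop([[0, 0, 0], [10.0, 0, 0]], radius=5.0)
        g = delaunay_neighbors(pop, cutoff=30.0)
        before = pop.position.copy()
        mechanics_step(pop, g, dt=1.0)
        assert np.allclose(pop.position, before)

    def test_pair_centroid_conserved(self, rng):
        pop = _pop(rng.normal(size=(2, 3)) * 3.0, radius=5.0)
        g = delaunay_neighbors(pop, cutoff=50.0)
        c0 = pop.position.mean(axis=0)
        for _ in range(50):
            mechanics_step(pop, g, dt=1.0)
        assert np.allclose(pop.position.mean(axis=0), c0, atol=1e-9)

    def test_overlap_relaxes_monotonically(self, rng):
        pop = _pop(rng.normal(size=(30, 3)) * 12.0, radius=5.0)
        cfg = CellConfig()
        prev = None
        for _ in range(600):
            g = delaunay_neighbors(pop, cutoff=30.0)
            overlap = total_pair_overlap(pop, g)
            if prev is not None and overlap > 1.0:
                assert overlap <= prev + 1e-9
            prev = overlap
            mechanics_step(pop, g, dt=2.0, cfg=cfg)
        assert prev < 0.1

    def test_rejects_nonpositive_dt(self):
        pop = _pop([[0, 0, 0], [8, 0, 0]])
        g = delaunay_neighbors(pop, cutoff=30.0)
        with pytest.raises(ValueError):
            mechanics_step(pop, g, dt=0.0)


# --------------------------------------------------------------------------
# metabolism
# --------------------------------------------------------------------------

class TestMetabolism:
    def test_backward_euler_linear_decay_closed_form(self):
        y = backward_euler_step(lambda y: -0.1 * y, np.array([[1.0]]), 10.0)
        assert y[0, 0] == pytest.approx(1.0 / (1.0 + 0.1 * 10.0), abs=1e-12)

    def test_fixed_point_when_env_equals_internal(self):
        cfg = CellConfig(q_o2_max=0.0, u_anaerobic_max=0.0, p_lactate=0.0)
        c = Cell(id=0, position=np.zeros(3), radius=10.0, o2_in=50.0,
                 glucose_in=3.0, lactate_in=1.0)
        c2, _ = metabolism_step(c, (50.0, 3.0, 7.4, 1.0), 10.0, cfg)
        assert c2.o2_in == pytest.approx(50.0, abs=1e-9)
        assert c2.glucose_in == pytest.approx(3.0, abs=1e-9)
        assert c2.lactate_in == pytest.approx(1.0, abs=1e-9)

    def test_anaerobic_stoichiometry(self):
        # no lactate export, no oxygen: lactate gain = 2 x glucose to glycolysis
        cfg = CellConfig(p_lactate=0.0, membrane_p_o2=0.0)
        c = Cell(id=0, position=np.zeros(3), radius=10.0, o2_in=0.0,
                 glucose_in=5.0, lactate_in=0.0)
        c2, rates = metabolism_step(c, (0.0, 5.0, 7.4, 0.0), 10.0, cfg)
        vol = 4.0 / 3.0 * np.pi * 10.0 ** 3
        lactate_gain = c2.lactate_in * vol
        anaerobic = rates["anaerobic_glucose"] * 10.0
        assert lactate_gain == pytest.approx(2.0 * anaerobic, rel=1e-10)

    def test_equilibrium_below_env_by_consumption(self):
        cfg = CellConfig()
        c = Cell(id=0, position=np.zeros(3), radius=10.0, o2_in=80.0,
                 glucose_in=5.0)
        for _ in range(10):
            c, _ = metabolism_step(c, (80.0, 5.0, 7.4, 0.0), 10.0, cfg)
        area = 4 * np.pi * 100.0
        drop_expected = cfg.q_o2_max / (cfg.membrane_p_o2 * area)
        assert c.o2_in == pytest.approx(80.0 - drop_expected, rel=0.05)

    def test_dt_range_enforced(self):
        pop = CellPopulation.from_cells(
            [Cell(id=0, position=np.zeros(3), radius=10.0)])
        with pytest.raises(ValueError):
            metabolism_population_step(pop, 0.1, CellConfig())


# --------------------------------------------------------------------------
# cycle and division
# --------------------------------------------------------------------------

class TestCycle:
    def test_saturating_nutrients_total_cycle_duration(self):
        cfg = CellConfig()
        pop = CellPopulation.from_cells([
            Cell(id=0, position=np.zeros(3), radius=7.94, o2_in=90.0,
                 glucose_in=5.0, env_o2=90.0, env_glucose=5.0, env_ph=7.4)])
        dt = 30.0
        t, divided = 0.0, None
        while t < 1.3 * cfg.cycle_time * 3600 and divided is None:
            pop.o2_in[:] = 300.0      # clamp: saturating nutrients throughout
            pop.glucose_in[:] = 50.0
            ready, _ = cycle_population_step(pop, dt, cfg)
            if len(ready):
                divided = t
            t += dt
        assert divided is not None
        assert divided / 3600.0 == pytest.approx(cfg.cycle_time, rel=0.01)

    def test_starvation_death_at_threshold(self):
        cfg = CellConfig()
        pop = CellPopulation.from_cells([
            Cell(id=0, position=np.zeros(3), radius=10.0, o2_in=0.0,
                 glucose_in=5.0, env_ph=7.4)])
        dt = 30.0
        steps_to_die = int(cfg.t_starve * 3600 / dt)
        for k in range(steps_to_die):
            assert pop.alive[0], f"died early after {k} steps"
            pop.o2_in[:] = 0.0
            cycle_population_step(pop, dt, cfg)
        # the anoxia clock crosses t_starve exactly on the last step
        assert not pop.alive[0]

    def test_dead_is_absorbing(self):
        cfg = CellConfig()
        pop = CellPopulation.from_cells([
            Cell(id=0, position=np.zeros(3), radius=10.0, phase=cm.DEAD)])
        for _ in range(100):
            ready, dead = cycle_population_step(pop, 10.0, cfg)
            assert len(ready) == 0
        assert pop.phase[0] == cm.DEAD
        assert pop.radius[0] < 10.0         # necrotic shrinkage

    def test_acidosis_death(self):
        cfg = CellConfig()
        pop = CellPopulation.from_cells([
            Cell(id=0, position=np.zeros(3), radius=10.0, o2_in=50.0,
                 glucose_in=5.0, env_ph=6.0)])
        cycle_population_step(pop, 10.0, cfg)
        assert not pop.alive[0]

    def test_single_cell_wrapper_rejects_dead(self):
        with pytest.raises(ValueError):
            cm.cycle_step(Cell(id=0, position=np.zeros(3), radius=10.0,
                               phase=cm.DEAD), 10.0)


class TestDivision:
    def test_volume_conserving_radii(self, rng):
        parent = Cell(id=0, position=np.zeros(3), radius=10.0,
                      phase=cm.M_PHASE, phase_clock=10.0)
        a, b = divide_cell(parent, rng)
        assert a.radius == pytest.approx(10.0 * 2 ** (-1 / 3), abs=1e-9)
        assert a.radius == pytest.approx(7.937, abs=1e-3)
        assert b.radius == a.radius

    def test_mitochondria_sum_conserved(self, rng):
        for _ in range(200):
            parent = Cell(id=0, position=np.zeros(3), radius=10.0,
                          phase=cm.M_PHASE, n_mito=100)
            a, b = divide_cell(parent, rng)
            assert a.n_mito + b.n_mito == 100

    def test_binomial_moments(self, rng):
        counts = []
        for _ in range(10_000):
            parent = Cell(id=0, position=np.zeros(3), radius=10.0,
                          phase=cm.M_PHASE, n_mito=100)
            a, _ = divide_cell(parent, rng)
            counts.append(a.n_mito)
        counts = np.asarray(counts)
        assert abs(counts.mean() - 50.0) < 1.0
        assert 15.0 < counts.var() < 38.0    # ~ n p q = 25

    def test_requires_m_phase(self, rng):
        with pytest.raises(ValueError):
            divide_cell(Cell(id=0, position=np.zeros(3), radius=10.0,
                             phase=cm.S_PHASE), rng)

    def test_population_division_bookkeeping(self, rng):
        pop = CellPopulation.from_cells([
            Cell(id=0, position=np.zeros(3), radius=10.0, phase=cm.M_PHASE)])
        j = divide_in_population(pop, 0, rng, CellConfig())
        assert len(pop) == 2
        assert pop.id[0] != pop.id[j]
        assert pop.phase[0] == pop.phase[j] == cm.G1M


class TestPopulationKinetics:
    def test_well_fed_culture_doubles_at_cycle_time(self, rng):
        """Dispersed well-fed culture: log2 count slope = 1/cycle_time to 5%."""
        cfg = CellConfig()
        pop = CellPopulation()
        T = cfg.cycle_time
        durs = [cfg.t_g1m, cfg.t_g1p, cfg.t_s, cfg.t_g2, cfg.t_m]
        for i in range(200):
            clock = rng.random() * T
            ph, rem = 0, clock
            for k, d in enumerate(durs):
                if rem < d:
                    ph = k
                    break
                rem -= d
            r = 7.94 + (10.0 - 7.94) * min(clock / (T - cfg.t_m), 1.0)
            pop.add(Cell(id=i, position=rng.normal(size=3) * 100.0, radius=r,
                         phase=ph, phase_clock=rem, o2_in=80.0, glucose_in=5.0,
                         env_o2=90.0, env_glucose=5.0, env_ph=7.4))
        dt = 10.0
        times, counts = [], []
        for step in range(int(4.2 * T * 3600 / dt)):
            metabolism_population_step(pop, dt, cfg)
            ready, _ = cycle_population_step(pop, dt, cfg)
            for idx in ready:
                divide_in_population(pop, idx, rng, cfg)
            if step % 500 == 0:
                times.append(step * dt / 3600.0)
                counts.append(len(pop))
        slope = np.polyfit(times, np.log2(counts), 1)[0]
        assert np.log2(counts[-1] / counts[0]) >= 4.0   # >= 4 doublings
        assert 1.0 / slope == pytest.approx(cfg.cycle_time, rel=0.05)
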