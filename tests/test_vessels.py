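"""Vessel network construction, rheology and hemodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nichesim as ns
from nichesim import fixtures as fx
from nichesim import vessels as ves
from nichesim.config import VesselConfig


# --------------------------------------------------------------------------
# independent oracle transcriptions (kept separate from the implementation)
# --------------------------------------------------------------------------

def oracle_relative_viscosity(d, h):
    """Empirical in-vitro apparent-viscosity law, transcribed independently."""
    import math
    mu45 = 220 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d ** 0.645)
    c = (0.8 + math.exp(-0.075 * d)) * (1 / (1 + 1e-11 * d ** 12) - 1) \
        + 1 / (1 + 1e-11 * d ** 12)
    return 1 + (mu45 - 1) * ((1 - h) ** c - 1) / ((1 - 0.45) ** c - 1)


def oracle_phase_split(psi, d_p, d_a, d_b, h):
    """Empirical red-cell split at a bifurcation, transcribed independently."""
    import math
    x0 = 0.964 * (1 - h) / d_p
    if psi <= x0:
        return 0.0
    if psi >= 1 - x0:
        return 1.0
    a = -13.29 * (((d_a / d_b) ** 2 - 1) / ((d_a / d_b) ** 2 + 1)) * (1 - h) / d_p
    b = 1 + 6.98 * (1 - h) / d_p
    x = (psi - x0) / (1 - 2 * x0)
    return 1 / (1 + math.exp(-(a + b * math.log(x / (1 - x)))))


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

class TestBuildMesh:
    def test_cube_graph_counts(self):
        cfg = VesselConfig(nx=2, ny=2, nz=2, spacing=80.0, n_inlets=1, n_outlets=1)
        net = ns.build_capillary_mesh(cfg, seed=0)
        assert net.n_nodes == 8
        assert net.n_segments == 12
        assert np.allclose(net.length, 80.0)

    def test_deterministic_for_seed(self):
        cfg = VesselConfig(nx=4, ny=3, nz=3, n_inlets=2, n_outlets=2)
        a = ns.build_capillary_mesh(cfg, seed=42)
        b = ns.build_capillary_mesh(cfg, seed=42)
        assert np.array_equal(a.seg_nodes, b.seg_nodes)
        assert np.array_equal(a.radius, b.radius)
        assert np.array_equal(a.inlets, b.inlets)

    def test_all_nodes_reachable_from_inlets(self):
        cfg = VesselConfig(nx=10, ny=10, nz=3)
        net = ns.build_capillary_mesh(cfg, seed=3)
        # independent breadth-first search oracle
        adj = {}
        for a, b in net.seg_nodes:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        seen = set(int(i) for i in net.inlets)
        frontier = list(seen)
        while frontier:
            u = frontier.pop()
            for v in adj.get(u, []):
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        assert len(seen) == net.n_nodes

    def test_rejects_bad_pressures(self):
        with pytest.raises(ValueError):
            ns.build_capillary_mesh(VesselConfig(inlet_pressure=1.0,
                                                 outlet_pressure=2.0))

    def test_positions_on_lattice(self):
        cfg = VesselConfig(nx=3, ny=3, nz=3, spacing=50.0)
        net = ns.build_capillary_mesh(cfg, seed=0)
        rel = net.positions / 50.0
        assert np.abs(rel - np.round(rel)).max() < 1e-9 / 50.0


# --------------------------------------------------------------------------
# rheology
# --------------------------------------------------------------------------

class TestViscosity:
    def test_pure_plasma_limit(self):
        for d in (4.0, 10.0, 50.0, 300.0):
            assert ns.relative_viscosity(d, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_transcription(self):
        got = ns.relative_viscosity(10.0, 0.45)
        assert got == pytest.approx(oracle_relative_viscosity(10.0, 0.45),
                                    rel=1e-12)
        for d, h in [(5.0, 0.2), (25.0, 0.6), (100.0, 0.45)]:
            assert ns.relative_viscosity(d, h) == pytest.approx(
                oracle_relative_viscosity(d, h), rel=1e-12)

    def test_fahraeus_lindqvist_minimum_near_7um(self):
        d = np.linspace(4.0, 100.0, 2000)
        rv = ns.relative_viscosity(d, 0.45)
        d_min = d[np.argmin(rv)]
        assert 6.0 < d_min < 8.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ns.relative_viscosity(2.0, 0.45)
        with pytest.raises(ValueError):
            ns.relative_viscosity(10.0, 1.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(d=st.floats(3.1, 500.0), h=st.floats(0.0, 0.99))
    def test_positive_and_continuous(self, d, h):
        v = ns.relative_viscosity(d, h)
        assert np.isfinite(v) and v > 0
        assert ns.relative_viscosity(d + 1e-7, h) == pytest.approx(v, rel=1e-3)


# --------------------------------------------------------------------------
# flow
# --------------------------------------------------------------------------

class TestComputeFlow:
    def test_poiseuille_single_tube(self):
        net = fx.single_tube(length=100.0, radius=5.0, p_in=2.0, p_out=1.0)
        ns.compute_flow(net, viscosity=4e-3)
        q_expected = np.pi * 5.0 ** 4 * 1000.0 / (8 * 4e-3 * 100.0)
        assert net.flow[0] == pytest.approx(q_expected, rel=1e-12)

    def test_wall_shear_two_routes(self):
        net = fx.single_tube(length=100.0, radius=5.0, p_in=2.0, p_out=1.0)
        ns.compute_flow(net, viscosity=4e-3)
        # independent identity tau = r dp / (2 L)
        assert net.wall_shear[0] == pytest.approx(5.0 * 1000.0 / 200.0, rel=1e-12)

    def test_symmetric_bifurcation_equal_daughters(self):
        net = fx.y_bifurcation()
        ns.compute_flow(net, viscosity=3e-3)
        assert net.flow[1] == pytest.approx(net.flow[2], rel=1e-12)

    def test_mass_conservation(self, random_mesh):
        res = random_mesh.interior_flow_residuals()
        assert res.max() < 1e-8 * random_mesh.total_inflow()

    def test_matches_dense_solve(self):
        cfg = VesselConfig(nx=4, ny=3, nz=3)   # 36 nodes <= 100
        net = ns.build_capillary_mesh(cfg, seed=9)
        ns.compute_flow(net)
        g, _ = ves.segment_conductance(net)
        n = net.n_nodes
        lap = np.zeros((n, n))
        for s, (a, b) in enumerate(net.seg_nodes):
            lap[a, a] += g[s]
            lap[b, b] += g[s]
            lap[a, b] -= g[s]
            lap[b, a] -= g[s]
        p = np.zeros(n)
        fixed = net.is_boundary
        p[fixed] = net.boundary_pressure[fixed] * 1e3
        free = ~fixed
        p[free] = np.linalg.solve(lap[np.ix_(free, free)],
                                  -lap[np.ix_(free, fixed)] @ p[fixed])
        assert np.allclose(p / 1e3, net.node_pressure, rtol=1e-10, atol=1e-12)

    def test_raising_inlet_pressure_monotone_inflow(self):
        cfg = VesselConfig(nx=5, ny=4, nz=4)
        net1 = ns.build_capillary_mesh(cfg, seed=2)
        ns.compute_flow(net1)
        q1 = net1.total_inflow()
        cfg2 = VesselConfig(nx=5, ny=4, nz=4, inlet_pressure=12.0)
        net2 = ns.build_capillary_mesh(cfg2, seed=2)
        ns.compute_flow(net2)
        assert net2.total_inflow() >= q1

    def test_isolated_subnetwork_raises(self):
        net = fx.single_tube()
        net.add_node([0.0, 500.0, 0.0])
        net.add_node([100.0, 500.0, 0.0])
        net.add_segment(2, 3, 4.0)
        with pytest.raises(ves.PerfusionError, match="orphan"):
            ns.compute_flow(net, viscosity=4e-3)


# --------------------------------------------------------------------------
# hematocrit
# --------------------------------------------------------------------------

class TestHematocrit:
    def test_symmetric_bifurcation_equal_split(self):
        net = fx.y_bifurcation(radius_a=4.0, radius_b=4.0)
        ns.compute_flow(net, viscosity=3e-3)
        ns.propagate_hematocrit(net, 0.45)
        assert net.hematocrit[1] == pytest.approx(net.hematocrit[2], abs=1e-12)
        assert net.hematocrit[1] == pytest.approx(0.45, abs=1e-12)

    def test_junction_rbc_flux_conserved(self):
        net = fx.y_bifurcation(radius_a=5.0, radius_b=3.0, p_out_b=1.4)
        ns.compute_flow(net)
        ns.propagate_hematocrit(net, 0.45)
        flux_parent = abs(net.flow[0]) * net.hematocrit[0]
        flux_children = (abs(net.flow[1]) * net.hematocrit[1]
                         + abs(net.flow[2]) * net.hematocrit[2])
        assert flux_children == pytest.approx(flux_parent, rel=1e-12)

    def test_asymmetric_split_matches_oracle(self):
        net = fx.y_bifurcation(radius_a=5.0, radius_b=3.0, p_out_b=1.4)
        ns.compute_flow(net)
        ns.propagate_hematocrit(net, 0.45)
        q0, qa, qb = abs(net.flow[0]), abs(net.flow[1]), abs(net.flow[2])
        frac = oracle_phase_split(qa / (qa + qb), 2 * net.radius[0],
                                  2 * net.radius[1], 2 * net.radius[2], 0.45)
        assert net.hematocrit[1] == pytest.approx(0.45 * q0 * frac / qa, rel=1e-10)
        assert net.hematocrit[2] == pytest.approx(
            0.45 * q0 * (1 - frac) / qb, rel=1e-10)

    def test_network_rbc_conservation(self, random_mesh):
        fin, fout = ves.rbc_flux_balance(random_mesh)
        assert abs(fin - fout) < 1e-8 * fin

    def test_hematocrit_within_bounds(self, random_mesh):
        assert (random_mesh.hematocrit >= 0).all()
        assert (random_mesh.hematocrit <= 0.99).all()
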