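"""Oxygen transport: saturation, reaction-diffusion, intravascular march."""

import numpy as np
import pytest

import nichesim as ns
from nichesim import fixtures as fx
from nichesim import oxygen as ox
from nichesim.grid import make_grid


class TestHillSaturation:
    def test_half_saturation_point(self):
        assert ox.hill_saturation(27.0, 27.0, 2.7) == pytest.approx(0.5)

    def test_zero_pressure(self):
        assert ox.hill_saturation(0.0, 27.0, 2.7) == 0.0

    def test_two_p50_cubic(self):
        assert ox.hill_saturation(54.0, 27.0, 3.0) == pytest.approx(8.0 / 9.0,
                                                                    rel=1e-12)

    def test_monotone(self):
        p = np.linspace(0, 200, 500)
        s = ox.hill_saturation(p, 27.0, 2.7)
        assert (np.diff(s) > 0).all()
        assert (s >= 0).all() and (s < 1).all()

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            ox.hill_saturation(-1.0, 27.0, 2.7)


class TestReactionDiffusion:
    def test_uniform_dirichlet_no_sources(self):
        g = make_grid([0, 0, 0], 10.0, (9, 9, 9))
        f = ox.solve_reaction_diffusion(g, "po2", 1000.0, boundary="dirichlet",
                                        boundary_value=42.0)
        assert np.allclose(f, 42.0, atol=1e-9)

    def test_1d_slab_decay_cosh_profile(self):
        # D c'' = lambda c with fixed edges -> cosh profile
        D, lam, L, c0 = 1000.0, 0.01, 400.0, 5.0
        h = 2.0
        n = int(L / h) + 1
        g = make_grid([0, 0, 0], h, (n, 5, 5))
        x = g.node_coordinates(0)
        mask = np.zeros(g.shape, dtype=bool)
        mask[0], mask[-1] = True, True
        ox.solve_reaction_diffusion(g, "glucose", D, decay=lam,
                                    fixed_mask=mask.ravel(), fixed_values=c0)
        k = np.sqrt(lam / D)
        analytic = c0 * np.cosh(k * (x - L / 2)) / np.cosh(k * L / 2)
        profile = g.fields["glucose"][:, 2, 2]
        assert np.abs(profile - analytic).max() / c0 < 1e-3

    def test_discrete_maximum_principle(self):
        g = make_grid([0, 0, 0], 10.0, (11, 11, 11))
        mask = np.zeros(g.shape, dtype=bool)
        mask[5, 5, 5] = True
        f = ox.solve_reaction_diffusion(g, "po2", 500.0, boundary="dirichlet",
                                        boundary_value=10.0,
                                        fixed_mask=mask.ravel(), fixed_values=60.0)
        interior = f[1:-1, 1:-1, 1:-1]
        assert f.max() <= 60.0 + 1e-9
        assert interior.min() >= 10.0 - 1e-9

    def test_krogh_cylinder_profile(self):
        # single axial vessel, zero-order consumption in an annulus
        err = krogh_max_relative_error(spacing=5.0)
        assert err < 0.02

    def test_grid_refinement_consistency(self):
        coarse = krogh_max_relative_error(spacing=5.0)
        fine = krogh_max_relative_error(spacing=2.5)
        assert abs(coarse - fine) < 0.01

    def test_too_small_grid_rejected(self):
        g = make_grid([0, 0, 0], 10.0, (2, 5, 5))
        with pytest.raises(ValueError):
            ox.solve_reaction_diffusion(g, "po2", 100.0)


def krogh_max_relative_error(spacing, rc=15.0, R=100.0, M0=11.36,
                             p_wall=80.0, D=2000.0):
    """Max relative deviation from the Krogh closed form, anchored two
    voxels outside the discretized lumen (where the staircase boundary is
    resolved)."""
    net, grid, mask = fx.krogh(vessel_radius=rc, spacing=spacing)
    x = grid.node_coordinates(0)
    y = grid.node_coordinates(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.sqrt(xx ** 2 + yy ** 2)
    sink = M0 * np.where((~mask) & (rr <= R)[:, :, None], 1.0, 0.0)
    grid.fields["po2"][:] = p_wall
    ox.solve_reaction_diffusion(grid, "po2", D, source=-sink.ravel(),
                                fixed_mask=mask.ravel(), fixed_values=p_wall)
    iy = int(np.argmin(np.abs(y)))
    ix0 = int(np.argmin(np.abs(x - (rc + 2 * spacing))))
    r0, p0 = x[ix0], grid.fields["po2"][ix0, iy, 1]

    def closed_form(r):
        return p0 + (M0 / D) * ((r ** 2 - r0 ** 2) / 4
                                - (R ** 2 / 2) * np.log(r / r0))

    errs = []
    for r in np.arange(r0 + spacing, 0.92 * R, spacing):
        ix = int(np.argmin(np.abs(x - r)))
        num = grid.fields["po2"][ix, iy, 1]
        errs.append(abs(num - closed_form(x[ix])) / abs(closed_form(x[ix])))
    return max(errs)


class TestIntravascular:
    def test_no_exchange_preserves_inlet(self):
        net = fx.single_tube(hematocrit=0.45)
        ns.compute_flow(net, viscosity=4e-3)
        g = make_grid([-50, -50, -50], 50.0, (5, 3, 3))
        ox.intravascular_po2(net, g, transfer_coeff=0.0, inlet_po2=80.0)
        assert net.node_po2[1] == pytest.approx(80.0, rel=1e-10)

    def test_monotone_decrease_downstream(self):
        net = fx.y_bifurcation()
        ns.compute_flow(net, viscosity=3e-3)
        ns.propagate_hematocrit(net, 0.45)
        g = make_grid([-50, -150, -50], 50.0, (7, 7, 3))
        g.fields["po2"][:] = 0.0    # tissue below blood everywhere
        ox.intravascular_po2(net, g, transfer_coeff=5.0, inlet_po2=80.0)
        p = net.node_po2
        assert p[0] >= p[1] >= p[2] - 1e-9
        assert p[1] >= p[3] - 1e-9

    def test_dissolved_only_exponential_relaxation(self):
        net = fx.single_tube(length=1000.0, radius=5.0, hematocrit=0.0)
        ns.compute_flow(net, viscosity=4e-3)
        q = abs(net.flow[0])
        g = make_grid([-50, -50, -50], 50.0, (41, 3, 3))
        g.fields["po2"][:] = 0.0
        k_total = 2.0   # dimensionless decay k*L
        gamma = q * k_total / (2 * np.pi * 5.0 * 1000.0)
        ox.intravascular_po2(net, g, transfer_coeff=gamma, inlet_po2=80.0,
                             ds=2.0)
        assert net.node_po2[1] == pytest.approx(80.0 * np.exp(-k_total),
                                                rel=5e-3)


class TestCoupled:
    def test_no_sink_equilibrates_to_blood(self):
        net = fx.single_tube(hematocrit=0.45)
        ns.compute_flow(net, viscosity=4e-3)
        g = make_grid([-40, -60, -60], 20.0, (9, 7, 7))
        seg_p, po2 = ox.coupled_oxygen_solve(net, g, transfer_coeff=20.0,
                                             inlet_po2=80.0, tol=0.05)
        assert po2.min() > 75.0
        assert po2.max() <= 80.0 + 1e-6

    def test_budget_closes_at_convergence(self):
        net, grid = fx.two_vessel_slab(spacing=20.0)
        ns.compute_flow(net, viscosity=4e-3)
        net.hematocrit[:] = 0.45
        sink = np.full(grid.n_nodes, 2.0)
        seg_p, _ = ox.coupled_oxygen_solve(net, grid, transfer_coeff=20.0,
                                           mm_sink_rate=sink, mm_half=4.0,
                                           tol=0.02)
        released, consumed = ox.oxygen_budget(net, grid, transfer_coeff=20.0,
                                              seg_p=seg_p, mm_sink_rate=sink,
                                              mm_half=4.0)
        assert released == pytest.approx(consumed, rel=0.01)

    def test_two_vessel_interior_minimum_midway(self):
        prof, x = _slab_profile(fx.two_vessel_slab)
        interior = slice(2, -2)
        imin = np.argmin(prof[interior]) + 2
        assert abs(x[imin]) <= 15.0          # midway between the vessels

    def test_third_vessel_turns_dip_into_local_max(self):
        prof, x = _slab_profile(fx.three_vessel_slab)
        imid = int(np.argmin(np.abs(x)))
        assert prof[imid] > prof[imid - 3]
        assert prof[imid] > prof[imid + 3]


def _slab_profile(builder):
    net, grid = builder(spacing=20.0)
    ns.compute_flow(net, viscosity=4e-3)
    net.hematocrit[:] = 0.45
    sink = np.full(grid.n_nodes, 2.0)
    ox.coupled_oxygen_solve(net, grid, transfer_coeff=20.0, mm_sink_rate=sink,
                            mm_half=4.0, tol=0.05)
    x = grid.node_coordinates(0)
    iy = grid.shape[1] // 2
    iz = grid.shape[2] // 2
    return grid.fields["po2"][:, iy, iz], x
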