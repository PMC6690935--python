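"""Deterministic small test scenarios.

Every fixture builds in well under a second and is reproducible for a
fixed seed, so the whole simulator is testable without any external data:
analytic hemodynamics (single tube, Y bifurcation), the Krogh cylinder,
the two/three-parallel-vessel slabs used for inter-vessel line sampling,
packed cell balls, and a miniature coupled tumour scenario.
"""

from __future__ import annotations

import numpy as np

from .cells import Cell, CellPopulation
from .config import (CellConfig, FieldConfig, OutputConfig, RemodelingConfig,
                     ScheduleConfig, SimulationConfig, VesselConfig)
from .grid import make_grid
from .vessels import ARTERY, CAPILLARY, VEIN, VesselNetwork

FIXTURE_NAMES = ("single_tube", "y_bifurcation", "krogh", "two_vessel_slab",
                 "three_vessel_slab", "cell_ball", "mini_coupled")


def make_fixture(name: str, seed: int = 0, **kwargs):
    """Dispatch by name; raises ``ValueError`` listing valid names."""
    try:
        fn = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; valid names: "
                         f"{', '.join(FIXTURE_NAMES)}") from None
    return fn(seed=seed, **kwargs)


def single_tube(seed: int = 0, length: float = 100.0, radius: float = 5.0,
                p_in: float = 2.0, p_out: float = 1.0,
                hematocrit: float = 0.45) -> VesselNetwork:
    """One straight segment with Dirichlet pressures (kPa) at both ends."""
    net = VesselNetwork(np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]),
                        lattice_spacing=length)
    net.is_boundary[:] = True
    net.boundary_pressure[:] = [p_in, p_out]
    net.add_segment(0, 1, radius, CAPILLARY, hematocrit=hematocrit)
    net.inlets = np.array([0])
    net.outlets = np.array([1])
    return net


def y_bifurcation(seed: int = 0, radius_parent: float = 6.0,
                  radius_a: float = 4.0, radius_b: float = 4.0,
                  length: float = 100.0, p_in: float = 3.0,
                  p_out_a: float = 1.0, p_out_b: float = 1.0) -> VesselNetwork:
    """Parent segment splitting into two daughters (symmetric by default)."""
    pts = np.array([
        [0.0, 0.0, 0.0], [length, 0.0, 0.0],
        [2 * length, +length * 0.6, 0.0], [2 * length, -length * 0.6, 0.0]])
    net = VesselNetwork(pts, lattice_spacing=length)
    net.is_boundary[[0, 2, 3]] = True
    net.boundary_pressure[[0, 2, 3]] = [p_in, p_out_a, p_out_b]
    net.add_segment(0, 1, radius_parent, ARTERY)
    net.add_segment(1, 2, radius_a, CAPILLARY)
    net.add_segment(1, 3, radius_b, CAPILLARY)
    net.inlets = np.array([0])
    net.outlets = np.array([2, 3])
    return net


def krogh(seed: int = 0, tissue_radius: float = 100.0, vessel_radius: float = 15.0,
          spacing: float = 5.0, pad: float = 10.0):
    """A single axial vessel in a slab grid: the classic Krogh geometry.

    Returns ``(network, grid, vessel_node_mask)`` where the mask marks
    grid nodes lying inside the vessel lumen (radial distance below the
    vessel radius), used to pin the wall pO2.
    """
    L = tissue_radius + pad
    n = int(round(2 * L / spacing)) + 1
    grid = make_grid([-L, -L, 0.0], spacing, (n, n, 3))
    net = VesselNetwork(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2 * spacing]]),
                        lattice_spacing=2 * spacing)
    net.is_boundary[:] = True
    net.boundary_pressure[:] = [2.0, 1.0]
    net.add_segment(0, 1, vessel_radius, CAPILLARY)
    net.inlets = np.array([0])
    net.outlets = np.array([1])
    x = grid.node_coordinates(0)
    y = grid.node_coordinates(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.sqrt(xx ** 2 + yy ** 2)
    mask = np.repeat((rr <= vessel_radius)[:, :, None], grid.shape[2], axis=2)
    return net, grid, mask


def _parallel_vessel_slab(xs, seed=0, half_width: float = 160.0,
                          depth: float = 300.0, spacing: float = 10.0,
                          radius: float = 4.0):
    """Vessels along y at given x offsets, inside a 3-D slab grid."""
    nx = int(round(2 * half_width / spacing)) + 1
    ny = int(round(depth / spacing)) + 1
    grid = make_grid([-half_width, 0.0, -3 * spacing], spacing, (nx, ny, 7))
    pts = []
    segs = []
    for i, x in enumerate(xs):
        pts.append([x, 0.0, 0.0])
        pts.append([x, depth, 0.0])
        segs.append((2 * i, 2 * i + 1))
    net = VesselNetwork(np.asarray(pts, float), lattice_spacing=spacing)
    net.is_boundary[:] = True
    for i in range(len(xs)):
        net.boundary_pressure[2 * i] = 2.0
        net.boundary_pressure[2 * i + 1] = 1.0
        net.add_segment(2 * i, 2 * i + 1, radius, CAPILLARY)
    net.inlets = np.arange(0, 2 * len(xs), 2)
    net.outlets = np.arange(1, 2 * len(xs), 2)
    return net, grid


def two_vessel_slab(seed: int = 0, separation: float = 240.0, **kwargs):
    """Two parallel vessels separated well beyond the O2 penetration depth."""
    return _parallel_vessel_slab([-separation / 2, separation / 2], seed,
                                 half_width=separation / 2 + 40.0, **kwargs)


def three_vessel_slab(seed: int = 0, separation: float = 240.0, **kwargs):
    """Same slab with a third vessel midway between the original pair."""
    return _parallel_vessel_slab([-separation / 2, 0.0, separation / 2], seed,
                                 half_width=separation / 2 + 40.0, **kwargs)


def cell_ball(seed: int = 0, n: int = 100, radius_cell: float = 5.0,
              packing: float = 0.55) -> CellPopulation:
    """N cells packed in a ball (rejection-free radial placement + relax).

    Positions are drawn uniformly in a ball sized for the requested
    packing fraction, then lightly relaxed to reduce deep overlaps.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ball_r = radius_cell * (n / packing) ** (1.0 / 3.0)
    u = rng.random(n) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pos = ball_r * u[:, None] * v
    pop = CellPopulation()
    for i in range(n):
        pop.add(Cell(id=i, position=pos[i], radius=radius_cell))
    from .cells import delaunay_neighbors, mechanics_step
    from .config import CellConfig
    cfg = CellConfig(k_repulsion=0.5)
    for _ in range(20):
        graph = delaunay_neighbors(pop, cutoff=6 * radius_cell)
        mechanics_step(pop, graph, 1.0, cfg)
    return pop


def mini_coupled(seed: int = 0) -> SimulationConfig:
    """Tiny coupled tumour run: 4³ mesh, coarse grid, short horizon."""
    return SimulationConfig(
        vessels=VesselConfig(nx=4, ny=4, nz=4, spacing=80.0),
        cells=_compressed_cells(),
        fields=FieldConfig(spacing=40.0, margin=40.0),
        remodeling=RemodelingConfig(),
        schedule=ScheduleConfig(dt_cell=10.0, dt_fields=600.0, dt_vessel=0.5,
                                t_end=1.0, snapshot_every=0.5, seed=seed),
        output=OutputConfig(),
    )


def _compressed_cells() -> CellConfig:
    """Cell parameters of the desk-scale scenario (see tumour_growth_scenario)."""
    c = 20.0   # time compression of the biology
    return CellConfig(
        t_g1m=6.0 / c, t_g1p=5.0 / c, t_s=8.0 / c, t_g2=3.0 / c, t_m=1.0 / c,
        t_starve=8.0 / c, necrotic_shrink_rate=0.1 * c / 4,
    )


def tumour_growth_scenario(seed: int = 0, t_end: float = 26.0,
                           seed_mode: str = "network_center") -> SimulationConfig:
    """The scaled-down vascularized tumour growth study conditions.

    A 9×9×9 capillary mesh at 80 μm spacing perfused from the −x (arterial)
    to the +x (venous) face hosts a single tumour cell seeded at the
    network centre.  One agent stands for a small cluster of real cells
    (division radius 10 μm) and the biological clocks are compressed
    twenty-fold, so ~14 h of simulated time corresponds to the early
    avascular stage and ~26 h to the late, remodeled stage of a
    multi-week tumour.  All remodeling thresholds were fixed on this
    scenario once and are not tuned per run.
    """
    c = 20.0
    return SimulationConfig(
        vessels=VesselConfig(nx=9, ny=9, nz=9, spacing=80.0),
        cells=_compressed_cells(),
        fields=FieldConfig(spacing=25.0, margin=60.0),
        remodeling=RemodelingConfig(
            sprout_probability=0.1, collapse_probability=0.25, tau_crit=1.0,
            regression_grace=4.0 / c, maturation_age=20.0 / c,
        ),
        schedule=ScheduleConfig(dt_cell=10.0, dt_fields=1200.0, dt_vessel=0.5,
                                t_end=t_end, snapshot_every=t_end,
                                seed=seed, seed_mode=seed_mode),
        output=OutputConfig(),
    )


def run_distance_study(seed: int = 0, clearance_spacings: float = 2.0,
                       t_max: float = 26.0, checkpoint_h: float = 1.0,
                       progress=None) -> dict:
    """Run the scaled-down scenario through the angiogenic switch.

    Advances the coupled simulation in hourly checkpoints and records the
    maximum nearest-vessel distance over all tumour cells at two stages:

    * **early** — the last checkpoint before any vessel collapse or
      regression has been logged (intact capillary mesh);
    * **late** — the first checkpoint at which remodeling has cleared
      every vessel within ``clearance_spacings`` lattice spacings of the
      tumour centroid (the vessel-free interior of the necrotic-core
      regime), or ``t_max`` if that never happens.

    Returns a dict with the two stage records and the final state.
    """
    from .coupling import advance, initialize, nearest_vessel_distances

    cfg = tumour_growth_scenario(seed=seed, t_end=t_max)
    state = initialize(cfg)
    clearance_target = clearance_spacings * cfg.vessels.spacing
    early = late = None
    t = 0.0
    while t < t_max - 1e-9:
        t = min(t + checkpoint_h, t_max)
        advance(state, t)
        d, _ = nearest_vessel_distances(state.cells, state.network)
        record = {"time": t, "max_distance": float(d.max()),
                  "n_cells": len(state.cells),
                  "n_segments": int((~state.network.collapsed).sum())}
        kinds = {e["kind"] for e in state.events}
        remodeled = bool(kinds & {"collapse", "regression"})
        if not remodeled:
            early = record
        else:
            centroid = state.cells.position.mean(axis=0)
            clear, _ = nearest_vessel_distances(centroid[None, :], state.network)
            record["centroid_clearance"] = float(clear[0])
            if progress is not None:
                progress(record)
            if clear[0] >= clearance_target:
                late = record
                break
        if progress is not None and not remodeled:
            progress(record)
    if late is None:
        late = record
    return {"early": early, "late": late, "state": state}


_BUILDERS = {
    "single_tube": single_tube,
    "y_bifurcation": y_bifurcation,
    "krogh": krogh,
    "two_vessel_slab": two_vessel_slab,
    "three_vessel_slab": three_vessel_slab,
    "cell_ball": cell_ball,
    "mini_coupled": mini_coupled,
}
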