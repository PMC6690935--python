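"""Coupling of the cell and vessel worlds and the two-timescale main loop.

Cells deposit consumption and growth-factor emission onto the tissue grid
with the cloud-in-cell kernel and sample their local environment back by
the adjoint interpolation.  Vessel proximity queries use exact
point-to-segment distances pruned by a k-d tree over segment midpoints,
giving brute-force-identical results at near-linear cost.  The main loop
advances cell biochemistry every few seconds, refreshes the continuum
fields on an intermediate cadence, and re-solves hemodynamics, oxygen and
vascular remodeling on the hour scale; remodeling stays off until the
growth-factor field first exceeds its threshold.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import cells as cellmod
from . import grid as gridmod
from . import oxygen as oxymod
from . import remodeling as remod
from . import vessels as vesmod
from .config import SimulationConfig
from .grid import TissueGrid
from .vessels import VesselNetwork


@dataclass
class SimulationState:
    time: float                      # h
    cells: cellmod.CellPopulation
    network: VesselNetwork
    grid: TissueGrid
    rng: np.random.Generator
    config: SimulationConfig
    step: int = 0
    events: list = field(default_factory=list)
    remodeling_active: bool = False
    graph: cellmod.NeighborGraph | None = None
    _moved: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_segments(self) -> int:
        return self.network.n_segments

    def copy(self) -> "SimulationState":
        out = SimulationState(
            time=self.time, cells=self.cells.copy(), network=self.network.copy(),
            grid=self.grid.copy(),
            rng=_copy.deepcopy(self.rng), config=self.config, step=self.step,
            events=[dict(e) for e in self.events],
            remodeling_active=self.remodeling_active)
        return out

    def log_event(self, kind: str, **info) -> None:
        self.events.append({"t": round(self.time, 9), "kind": kind, **info})


# ---------------------------------------------------------------------------
# particle-mesh transfer
# ---------------------------------------------------------------------------

def deposit_to_grid(cells, rates, grid: TissueGrid, field_name: str = "o2_sink"):
    """Cloud-in-cell deposit of per-cell rates; conserves the total.

    ``cells`` is a CellPopulation or (N,3) positions.  Cells outside the
    grid are clamped onto the nearest face (a warning-style count is
    returned).  The field holds rates per node, not densities.
    """
    pts = cells.position if isinstance(cells, cellmod.CellPopulation) else cells
    clamped = gridmod.deposit(grid, field_name, pts, rates)
    return int(clamped.sum())


def sample_environment(cells, grid: TissueGrid,
                       names=("po2", "glucose", "ph")) -> dict[str, np.ndarray]:
    """Trilinear interpolation of the named fields at the cell positions."""
    pts = cells.position if isinstance(cells, cellmod.CellPopulation) else np.atleast_2d(cells)
    return {name: gridmod.sample(grid, name, pts) for name in names}


# ---------------------------------------------------------------------------
# nearest-vessel distances
# ---------------------------------------------------------------------------

def point_segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Exact distances from points to one 3-D segment (clamped projection)."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip(((points - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def nearest_vessel_distances(cells, network: VesselNetwork,
                             exclude=None) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each cell to the closest non-collapsed segment.

    Exact point-to-segment distances; candidate segments are pruned with a
    k-d tree over segment midpoints using the bound
    dist(point, segment) ≥ dist(point, midpoint) − length/2, so results
    match the all-pairs brute force exactly while the expected cost stays
    linear in the number of cells for bounded vessel density.

    Returns ``(distances, segment_ids)``.
    """
    pts = cells.position if isinstance(cells, cellmod.CellPopulation) else np.atleast_2d(cells)
    active = np.flatnonzero(~network.collapsed)
    if exclude is not None:
        active = np.setdiff1d(active, np.asarray(exclude, dtype=np.int64))
    if len(active) == 0:
        raise ValueError("network has no active segments")
    a = network.positions[network.seg_nodes[active, 0]]
    b = network.positions[network.seg_nodes[active, 1]]
    mid = 0.5 * (a + b)
    half = 0.5 * network.length[active]
    hmax = float(half.max())
    tree = cKDTree(mid)

    n = len(pts)
    best = np.full(n, np.inf)
    best_seg = np.zeros(n, dtype=np.int64)
    # initial candidate: nearest midpoint
    d_mid, j = tree.query(pts, k=1)
    for i in range(n):
        s = j[i]
        best[i] = point_segment_distance(pts[i:i + 1], a[s], b[s])[0]
        best_seg[i] = s
    # verify against all segments whose midpoint could beat the current best
    r = best + hmax + 1e-9
    neighborhoods = tree.query_ball_point(pts, r)
    for i, cand in enumerate(neighborhoods):
        for s in cand:
            if s == best_seg[i]:
                continue
            if d_mid_lower_bound(pts[i], mid[s], half[s]) >= best[i]:
                continue
            d = point_segment_distance(pts[i:i + 1], a[s], b[s])[0]
            if d < best[i]:
                best[i] = d
                best_seg[i] = s
    return best, active[best_seg]


def d_mid_lower_bound(p, mid, half) -> float:
    return max(float(np.linalg.norm(p - mid)) - half, 0.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _seed_positions(net: VesselNetwork, mode: str, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    h = net.lattice_spacing
    if mode == "network_center":
        center = 0.5 * (net.positions.min(axis=0) + net.positions.max(axis=0))
        base = center + 0.5 * h * np.array([0.5, 0.5, 0.5])
    elif mode in ("near_arterial_bifurcation", "near_venous_bifurcation"):
        wanted = vesmod.ARTERY if mode == "near_arterial_bifurcation" else vesmod.VEIN
        deg = net.node_degree()
        cls_nodes = np.unique(net.seg_nodes[net.vessel_class == wanted].ravel())
        junctions = cls_nodes[deg[cls_nodes] >= 3]
        if len(junctions) == 0:
            junctions = cls_nodes
        node = int(junctions[len(junctions) // 2])
        offset = rng.normal(size=3)
        offset *= (0.6 * h) / np.linalg.norm(offset)
        base = net.positions[node] + offset
    else:
        raise ValueError(f"unknown seed mode {mode!r}")
    out = [base]
    for _ in range(n - 1):
        out.append(base + 4.0 * rng.normal(size=3))
    return np.asarray(out)


def initialize(config: SimulationConfig) -> SimulationState:
    """Build network, grid and seed cells; solve the initial physiology."""
    sched = config.schedule
    rng = np.random.default_rng(sched.seed)
    net = vesmod.build_capillary_mesh(config.vessels, seed=sched.seed)
    vesmod.compute_flow(net, plasma_viscosity=config.vessels.plasma_viscosity)
    vesmod.propagate_hematocrit(net, config.vessels.inlet_hematocrit)

    grid = gridmod.grid_covering(net.positions.min(axis=0), net.positions.max(axis=0),
                                 config.fields.spacing, config.fields.margin)
    grid.fields["po2"][:] = config.vessels.arterial_po2 * 0.5
    grid.fields["glucose"][:] = config.vessels.vessel_glucose

    state = SimulationState(time=0.0, cells=cellmod.CellPopulation(), network=net,
                            grid=grid, rng=rng, config=config)
    for pos in _seed_positions(net, sched.seed_mode, sched.n_seed_cells, rng):
        cell = cellmod.make_cell(state.cells, pos, config.cells.r_div * 2 ** (-1 / 3))
        state.cells.add(cell)

    _refresh_fields(state, full_oxygen=True)
    _sample_cell_environment(state)
    state.cells.o2_in[:] = state.cells.env_o2
    state.cells.glucose_in[:] = state.cells.env_glucose
    state.log_event("init", n_cells=len(state.cells), n_segments=net.n_segments)
    return state


# ---------------------------------------------------------------------------
# field refresh and vessel tick
# ---------------------------------------------------------------------------

def _deposit_rates(state: SimulationState, rates) -> None:
    """Deposit the rates recorded at metabolism time (with the positions
    and hypoxia flags captured alongside them, so divisions between the
    metabolism step and this deposit cannot desynchronize the arrays)."""
    pos = rates["positions"]
    gridmod.deposit(state.grid, "o2_sink", pos, rates["o2_consumption"])
    gridmod.deposit(state.grid, "glucose_sink", pos, rates["glucose_uptake"])
    gridmod.deposit(state.grid, "lactate_source", pos, rates["lactate_export"])
    gridmod.deposit(state.grid, "vegf_source", pos, rates["vegf_emission"])


def _refresh_fields(state: SimulationState, full_oxygen: bool = False) -> None:
    """Re-solve the quasi-static tissue fields from the deposited sinks."""
    cfg = state.config
    g = state.grid
    vvol = g.voxel_volume
    vcfg = cfg.vessels
    fcfg = cfg.fields

    o2_sink_density = g.fields["o2_sink"].ravel() / vvol

    if full_oxygen:
        oxymod.coupled_oxygen_solve(
            state.network, g, transfer_coeff=vcfg.gamma_o2,
            inlet_po2=vcfg.arterial_po2, kappa=vcfg.o2_carrying_capacity,
            p50=vcfg.p50, hill_n=vcfg.hill_n, d_o2=fcfg.d_o2,
            mm_sink_rate=o2_sink_density, mm_half=fcfg.o2_mm_half,
            ds=vcfg.intravascular_ds, tol=fcfg.coupled_tol,
            max_iters=fcfg.coupled_max_iters)
    else:
        # tissue-only refresh against the last intravascular solution
        flat_idx, a_coef, seg_of = oxymod.vessel_exchange_stencil(
            state.network, g, vcfg.gamma_o2, vcfg.intravascular_ds)
        seg_p = 0.5 * (state.network.node_po2[state.network.seg_nodes[:, 0]]
                       + state.network.node_po2[state.network.seg_nodes[:, 1]])
        a_lin = np.zeros(g.n_nodes)
        b_val = np.zeros(g.n_nodes)
        if len(flat_idx):
            np.add.at(a_lin, flat_idx, a_coef / vvol)
            np.add.at(b_val, flat_idx, (a_coef / vvol) * seg_p[seg_of])
        b_val = np.where(a_lin > 0, b_val / np.maximum(a_lin, 1e-300), 0.0)
        oxymod.solve_reaction_diffusion(
            g, "po2", fcfg.d_o2, linear_sink_coeff=a_lin, linear_sink_value=b_val,
            mm_sink_rate=o2_sink_density, mm_half=fcfg.o2_mm_half,
            tol=fcfg.rd_tol, max_iters=fcfg.rd_max_iters)

    # glucose: vessel supply via the same exchange stencil, cell sinks
    flat_idx, a_coef, _ = oxymod.vessel_exchange_stencil(
        state.network, g, vcfg.gamma_glucose, vcfg.intravascular_ds)
    a_lin = np.zeros(g.n_nodes)
    if len(flat_idx):
        np.add.at(a_lin, flat_idx, a_coef / vvol)
    oxymod.solve_reaction_diffusion(
        g, "glucose", fcfg.d_glucose, linear_sink_coeff=a_lin,
        linear_sink_value=np.full(g.n_nodes, vcfg.vessel_glucose),
        mm_sink_rate=g.fields["glucose_sink"].ravel() / vvol,
        mm_half=fcfg.glucose_mm_half, tol=fcfg.rd_tol, max_iters=fcfg.rd_max_iters)

    # lactate: cell export source, diffusion with clearance; pH algebraic
    oxymod.solve_reaction_diffusion(
        g, "lactate", fcfg.d_lactate, decay=fcfg.lactate_decay,
        source=g.fields["lactate_source"].ravel() / vvol)
    g.fields["ph"] = np.clip(fcfg.ph0 - fcfg.beta_ph * g.fields["lactate"], 6.0, 7.6)

    # VEGF: hypoxic-cell point sources, diffusion with linear decay
    oxymod.solve_reaction_diffusion(
        g, "vegf", fcfg.d_vegf, decay=fcfg.vegf_decay,
        source=g.fields["vegf_source"].ravel() / vvol)


def _sample_cell_environment(state: SimulationState) -> None:
    pop = state.cells
    if len(pop) == 0:
        return
    env = sample_environment(pop, state.grid, ("po2", "glucose", "ph", "lactate"))
    pop.env_o2[:] = env["po2"]
    pop.env_glucose[:] = env["glucose"]
    pop.env_ph[:] = env["ph"]
    pop.env_lactate[:] = env["lactate"]


def _vessel_tick(state: SimulationState) -> None:
    """Hemodynamics + oxygen re-solve and, once gated on, remodeling."""
    cfg = state.config
    net = state.network
    net.age[:] += cfg.schedule.dt_vessel

    if cfg.remodeling.enabled and not state.remodeling_active:
        if state.grid.fields["vegf"].max() > cfg.schedule.vegf_threshold:
            state.remodeling_active = True
            state.log_event("remodeling_enabled")

    if state.remodeling_active:
        remod.remodel_tick(state)
    else:
        vesmod.compute_flow(net, plasma_viscosity=cfg.vessels.plasma_viscosity)
        vesmod.propagate_hematocrit(net, cfg.vessels.inlet_hematocrit)

    _refresh_fields(state, full_oxygen=True)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _cell_tick(state: SimulationState) -> dict:
    cfg = state.config
    pop = state.cells
    dt = cfg.schedule.dt_cell
    _sample_cell_environment(state)
    rates = cellmod.metabolism_population_step(pop, dt, cfg.cells)
    rates["positions"] = pop.position.copy()
    hypoxic = (pop.o2_in < cfg.cells.p_hypoxia) & pop.alive
    rates["vegf_emission"] = np.where(hypoxic, cfg.cells.vegf_rate, 0.0)
    ready, newly_dead = cellmod.cycle_population_step(pop, dt, cfg.cells)
    for idx in newly_dead:
        state.log_event("death", cell=int(pop.id[idx]))
    patch_edges = []
    for idx in ready:
        j = cellmod.divide_in_population(pop, idx, state.rng, cfg.cells)
        state.log_event("division", parent=int(pop.id[idx]), daughter=int(pop.id[j]))
        patch_edges.append((idx, j))
    if state.graph is None or state._moved > 0.5 \
            or state.step % cfg.schedule.rebuild_every == 0:
        state.graph = cellmod.delaunay_neighbors(pop, cfg.cells.contact_cutoff)
        state._moved = 0.0
    elif patch_edges:
        # between full rebuilds, splice daughters in: daughter B inherits
        # the slot-A neighbourhood plus the sibling contact
        g = state.graph
        extra = []
        for idx, j in patch_edges:
            extra.append((min(idx, j), max(idx, j)))
            if len(g.edges):
                mask = (g.edges == idx).any(axis=1)
                for a, b in g.edges[mask]:
                    nb = int(b if a == idx else a)
                    extra.append((min(nb, j), max(nb, j)))
        edges = np.vstack([g.edges.reshape(-1, 2),
                           np.asarray(extra, dtype=np.int64)])
        edges = np.unique(edges, axis=0)
        state.graph = cellmod.NeighborGraph(edges, np.zeros(len(edges)), len(pop))
    if len(pop) > 1:
        disp = cellmod.mechanics_step(pop, state.graph, dt, cfg.cells)
        state._moved += float(np.abs(disp).max())
    return rates


def advance(state: SimulationState, until_h: float,
            snapshot_times: list[float] | None = None,
            on_snapshot=None) -> SimulationState:
    """Run the two-timescale loop in place until ``until_h`` (hours)."""
    sched = state.config.schedule
    dt_h = sched.dt_cell / 3600.0
    fields_every = max(1, round(sched.dt_fields / sched.dt_cell))
    vessel_every = max(1, round(sched.dt_vessel * 3600.0 / sched.dt_cell))
    n_steps = max(0, round((until_h - state.time) / dt_h))
    snap_iter = iter(sorted(snapshot_times or []))
    next_snap = next(snap_iter, None)

    for _ in range(n_steps):
        rates = _cell_tick(state)
        state.step += 1
        state.time += dt_h
        if state.step % fields_every == 0:
            _deposit_rates(state, rates)
            _refresh_fields(state)
        if state.step % vessel_every == 0:
            _deposit_rates(state, rates)
            _vessel_tick(state)
            _sample_cell_environment(state)
        while next_snap is not None and state.time >= next_snap - 1e-9:
            if on_snapshot is not None:
                on_snapshot(state)
            next_snap = next(snap_iter, None)
    return state


@dataclass
class RunResult:
    state: SimulationState
    snapshots: list
    events: list


def run_simulation(config: SimulationConfig) -> RunResult:
    """Initialize and run to ``t_end``, collecting snapshots on cadence.

    Snapshots are in-memory state copies unless ``output.out_dir`` is set,
    in which case they are written as HDF5 files (and the returned list
    holds the paths).  Bit-reproducible for a fixed seed.
    """
    from . import io as iomod

    state = initialize(config)
    sched = config.schedule
    out_dir = config.output.out_dir
    snapshots: list = []

    def take(state: SimulationState):
        if out_dir is None:
            snapshots.append(state.copy())
        else:
            from pathlib import Path
            p = Path(out_dir)
            p.mkdir(parents=True, exist_ok=True)
            path = p / f"snapshot_t{state.time:08.2f}h.h5"
            iomod.write_snapshot(state, path)
            snapshots.append(path)

    take(state)
    if sched.t_end > 0:
        times = [t for t in np.arange(sched.snapshot_every, sched.t_end + 1e-9,
                                      sched.snapshot_every)]
        if not times or abs(times[-1] - sched.t_end) > 1e-9:
            times.append(sched.t_end)
        advance(state, sched.t_end, snapshot_times=times, on_snapshot=take)
    if out_dir is not None and config.output.write_events:
        iomod.write_events(state.events, f"{out_dir}/events.jsonl")
    return RunResult(state=state, snapshots=snapshots, events=state.events)
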