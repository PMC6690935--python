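"""Off-lattice tumour cell agents.

Each agent is a two-compartment structure: an intracellular pool (oxygen
partial pressure, glucose, lactate) exchanging with the extracellular
environment sampled from the tissue grid.  Oxygen crosses the membrane by
simple diffusion, glucose by a saturable carrier; oxygen consumption is
modulated by intracellular pO2 (Hill), extracellular pH (bell curve) and
the mitochondrial endowment, and glucose not oxidized feeds anaerobic
glycolysis producing two lactate per glucose.  Cells progress through
G1m → G1p → S → G2 → M with nutrient-dependent stretching of the clock,
divide with binomial partitioning of mitochondria, and die under
sustained anoxia or acidosis.

Neighbour relations come from the Delaunay triangulation of cell centres
(edges capped at a contact cutoff), the spheroid surface from the alpha
complex, and mechanics from overdamped pairwise spring forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

from .config import CellConfig

# phase codes (exported mapping, used by snapshots and analysis)
G1M, G1P, S_PHASE, G2, M_PHASE, DEAD = 0, 1, 2, 3, 4, 5
PHASE_NAMES = {G1M: "G1m", G1P: "G1p", S_PHASE: "S", G2: "G2", M_PHASE: "M",
               DEAD: "dead"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}
_CYCLE_ORDER = (G1M, G1P, S_PHASE, G2, M_PHASE)


@dataclass
class Cell:
    """Single-cell record; the population stores the same fields as arrays."""

    id: int
    position: np.ndarray
    radius: float
    phase: int = G1M
    phase_clock: float = 0.0        # h
    o2_in: float = 50.0             # mmHg
    glucose_in: float = 5.0         # mM
    lactate_in: float = 0.0         # mM
    env_o2: float = 50.0
    env_glucose: float = 5.0
    env_ph: float = 7.4
    env_lactate: float = 0.0
    n_mito: int = 100
    mito_buffer: float = 0.0        # fractional mitochondrial biogenesis
    consumption_scale: float = 1.0
    cycle_scale: float = 1.0
    age: float = 0.0                # h
    starve_clock: float = 0.0       # h below the anoxia threshold


_FIELDS = [
    ("id", np.int64), ("radius", float), ("phase", np.int8),
    ("phase_clock", float), ("o2_in", float), ("glucose_in", float),
    ("lactate_in", float), ("env_o2", float), ("env_glucose", float),
    ("env_ph", float), ("env_lactate", float), ("n_mito", np.int64),
    ("mito_buffer", float),
    ("consumption_scale", float), ("cycle_scale", float), ("age", float),
    ("starve_clock", float),
]


class CellPopulation:
    """Structure-of-arrays container for the whole cell population."""

    def __init__(self):
        self.position = np.empty((0, 3))
        for name, dtype in _FIELDS:
            setattr(self, name, np.empty(0, dtype=dtype))
        self.next_id = 0

    def __len__(self) -> int:
        return len(self.position)

    @property
    def alive(self) -> np.ndarray:
        return self.phase != DEAD

    def add(self, cell: Cell) -> int:
        self.position = np.vstack([self.position, np.asarray(cell.position, float)])
        for name, dtype in _FIELDS:
            arr = getattr(self, name)
            setattr(self, name, np.append(arr, dtype(getattr(cell, name))))
        self.next_id = max(self.next_id, cell.id + 1)
        return len(self) - 1

    def add_many(self, cells: list[Cell]) -> None:
        for c in cells:
            self.add(c)

    def view(self, i: int) -> Cell:
        kwargs = {name: getattr(self, name)[i].item() for name, _ in _FIELDS}
        return Cell(position=self.position[i].copy(), **kwargs)

    def write(self, i: int, cell: Cell) -> None:
        self.position[i] = cell.position
        for name, dtype in _FIELDS:
            getattr(self, name)[i] = getattr(cell, name)

    def copy(self) -> "CellPopulation":
        out = CellPopulation()
        out.position = self.position.copy()
        for name, _ in _FIELDS:
            setattr(out, name, getattr(self, name).copy())
        out.next_id = self.next_id
        return out

    @classmethod
    def from_cells(cls, cells: list[Cell]) -> "CellPopulation":
        pop = cls()
        pop.add_many(cells)
        return pop


def make_cell(pop_or_id, position, radius, rng=None, **kwargs) -> Cell:
    """Convenience constructor assigning the next free id."""
    cid = pop_or_id.next_id if isinstance(pop_or_id, CellPopulation) else int(pop_or_id)
    return Cell(id=cid, position=np.asarray(position, float), radius=float(radius),
                **kwargs)


# ---------------------------------------------------------------------------
# neighbour geometry
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    edges: np.ndarray                  # (E,2) population indices, i<j
    contact_areas: np.ndarray          # μm², lens intersection estimate
    n_cells: int = 0

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {}
        for i, j in self.edges:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        return adj


def _jittered(points: np.ndarray, scale: float = 1e-6) -> np.ndarray:
    """Deterministic per-index jitter used to break degenerate geometry."""
    n = len(points)
    rng = np.random.default_rng(12345)
    return points + scale * (rng.random((n, 3)) - 0.5)


def _delaunay(points: np.ndarray) -> Delaunay:
    try:
        return Delaunay(points)
    except Exception:
        return Delaunay(_jittered(points))


def delaunay_neighbors(cells, cutoff: float) -> NeighborGraph:
    """Delaunay edges of the cell centres, filtered by a length cutoff.

    ``cells`` may be a CellPopulation or an (N,3) position array.  Returns
    an empty graph for fewer than two cells; degenerate configurations are
    retried with a deterministic jitter.
    """
    pts = cells.position if isinstance(cells, CellPopulation) else np.atleast_2d(cells)
    n = len(pts)
    if n < 2:
        return NeighborGraph(np.empty((0, 2), np.int64), np.empty(0), n)
    if n == 2:
        edges = np.array([[0, 1]], dtype=np.int64)
    elif n == 3:
        edges = np.array([[0, 1], [0, 2], [1, 2]], dtype=np.int64)
    else:
        tri = _delaunay(pts)
        e = np.vstack([tri.simplices[:, [a, b]]
                       for a in range(4) for b in range(a + 1, 4)])
        e = np.unique(np.sort(e, axis=1), axis=0)
        edges = e.astype(np.int64)
    d = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = d <= cutoff
    edges, d = edges[keep], d[keep]
    if isinstance(cells, CellPopulation):
        areas = contact_area(cells.radius[edges[:, 0]], cells.radius[edges[:, 1]], d)
    else:
        areas = np.zeros(len(edges))
    return NeighborGraph(edges, areas, n)


def contact_area(r1, r2, d):
    """Area of the sphere-sphere intersection disc (0 when not touching)."""
    r1, r2, d = np.asarray(r1, float), np.asarray(r2, float), np.asarray(d, float)
    touching = d < (r1 + r2)
    with np.errstate(invalid="ignore"):
        x = (d ** 2 - r2 ** 2 + r1 ** 2) / (2 * np.maximum(d, 1e-12))
        a2 = r1 ** 2 - x ** 2
    return np.where(touching & (a2 > 0), np.pi * np.maximum(a2, 0.0), 0.0)


def _tet_circumradius2(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Squared circumradius of each tetrahedron (vectorized)."""
    p0 = pts[tets[:, 0]]
    rows = pts[tets[:, 1:]] - p0[:, None, :]        # (T,3,3)
    rhs = 0.5 * (rows ** 2).sum(axis=2)             # (T,3)
    det = np.linalg.det(rows)
    good = np.abs(det) > 1e-12
    centers = np.full((len(tets), 3), np.nan)
    if good.any():
        centers[good] = np.linalg.solve(rows[good], rhs[good][:, :, None])[:, :, 0]
    r2 = (centers ** 2).sum(axis=1)
    r2[~good] = np.inf
    return r2


def surface_cells_alpha(cells, alpha: float) -> np.ndarray:
    """Indices of cells on the alpha-shape boundary of the cluster.

    The alpha complex keeps Delaunay tetrahedra with squared circumradius
    at most ``alpha`` (μm²); cells incident to facets bounding the kept
    complex — plus cells in no kept tetrahedron at all — form the surface.
    """
    pts = cells.position if isinstance(cells, CellPopulation) else np.atleast_2d(cells)
    n = len(pts)
    if n < 4:
        return np.arange(n, dtype=np.int64)
    tri = _delaunay(pts)
    r2 = _tet_circumradius2(tri.points, tri.simplices)
    kept = r2 <= alpha
    if not kept.any():
        return np.arange(n, dtype=np.int64)
    faces: dict[tuple, int] = {}
    for tet in tri.simplices[kept]:
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted(tet[list(f)]))
            faces[key] = faces.get(key, 0) + 1
    boundary = {v for key, cnt in faces.items() if cnt == 1 for v in key}
    in_kept = np.zeros(n, dtype=bool)
    in_kept[np.unique(tri.simplices[kept])] = True
    boundary |= set(np.flatnonzero(~in_kept).tolist())
    return np.array(sorted(boundary), dtype=np.int64)


def alpha_complex_mask(cells, alpha: float):
    """(Delaunay, kept-tet mask) for point-in-tumour tests."""
    pts = cells.position if isinstance(cells, CellPopulation) else np.atleast_2d(cells)
    if len(pts) < 4:
        return None, None
    tri = _delaunay(pts)
    kept = _tet_circumradius2(tri.points, tri.simplices) <= alpha
    return tri, kept


def points_in_alpha_shape(points, tri, kept) -> np.ndarray:
    """Boolean mask of query points inside the kept alpha complex."""
    if tri is None:
        return np.zeros(len(np.atleast_2d(points)), dtype=bool)
    simplex = tri.find_simplex(np.atleast_2d(points))
    inside = simplex >= 0
    inside[inside] = kept[simplex[inside]]
    return inside


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------

def pair_forces(pop: CellPopulation, graph: NeighborGraph, cfg: CellConfig):
    """Per-cell velocity (μm/s) from pairwise springs along centre lines.

    Repulsive inside the equilibrium distance (sum of radii), adhesive in
    a shell of thickness ``delta_adhesion`` outside it, zero beyond.
    Newton's third law holds pairwise by construction.
    """
    v = np.zeros_like(pop.position)
    if len(graph.edges) == 0:
        return v
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    dx = pop.position[j] - pop.position[i]
    d = np.linalg.norm(dx, axis=1)
    d = np.maximum(d, 1e-9)
    u = dx / d[:, None]
    d_eq = pop.radius[i] + pop.radius[j]
    overlap = d_eq - d
    mag = np.where(
        overlap > 0,
        cfg.k_repulsion * overlap,                       # push apart (i moves -u)
        np.where(d < d_eq + cfg.delta_adhesion,
                 cfg.k_adhesion * overlap,               # negative: pull together
                 0.0),
    )
    np.add.at(v, i, -mag[:, None] * u)
    np.add.at(v, j, mag[:, None] * u)
    return v


def mechanics_step(pop: CellPopulation, graph: NeighborGraph, dt: float,
                   cfg: CellConfig | None = None) -> np.ndarray:
    """Overdamped position update x ← x + v·dt, capped at 0.1·radius.

    Returns the applied displacements.  dt is in seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = cfg or CellConfig()
    v = pair_forces(pop, graph, cfg)
    disp = v * dt
    norm = np.linalg.norm(disp, axis=1)
    cap = cfg.max_step_fraction * pop.radius
    scale = np.where(norm > cap, cap / np.maximum(norm, 1e-300), 1.0)
    disp *= scale[:, None]
    pop.position += disp
    return disp


def total_pair_overlap(pop: CellPopulation, graph: NeighborGraph) -> float:
    if len(graph.edges) == 0:
        return 0.0
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    d = np.linalg.norm(pop.position[i] - pop.position[j], axis=1)
    return float(np.maximum(pop.radius[i] + pop.radius[j] - d, 0.0).sum())


# ---------------------------------------------------------------------------
# metabolism
# ---------------------------------------------------------------------------

def backward_euler_step(rhs, y0: np.ndarray, dt: float, tol: float = 1e-10,
                        max_newton: int = 50) -> np.ndarray:
    """One backward-Euler step y1 = y0 + dt·f(y1) solved by damped Newton.

    ``y0`` has shape (N, k); ``rhs`` maps (N, k) → (N, k).  The Jacobian is
    formed by forward differences and the k×k systems are solved in batch.
    This is the integrator behind the per-cell metabolic equations (the
    system is stiff: membrane exchange is fast against consumption).
    """
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    n, k = y0.shape
    y = y0.copy()
    eye = np.eye(k)
    for _ in range(max_newton):
        f = np.atleast_2d(rhs(y))
        g = y - y0 - dt * f                      # residual
        if np.abs(g).max() < tol:
            break
        jac = np.empty((n, k, k))
        h = 1e-7 * np.maximum(np.abs(y), 1.0)
        for c in range(k):
            yp = y.copy()
            yp[:, c] += h[:, c]
            jac[:, :, c] = (np.atleast_2d(rhs(yp)) - f) / h[:, c][:, None]
        a = eye[None, :, :] - dt * jac
        try:
            step = np.linalg.solve(a, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = g
        y = y - step
    return y


def metabolism_rhs(y, env, params, cfg: CellConfig):
    """Time derivatives of (o2_in, glucose_in, lactate_in) for a batch.

    ``env`` is (pe, ce, phe, le); ``params`` carries per-cell area, volume,
    mitochondrial factor and consumption scale.  Also used to report the
    instantaneous exchange/consumption rates for grid deposition.
    """
    p = np.maximum(y[:, 0], 0.0)
    c = np.maximum(y[:, 1], 0.0)
    lac = np.maximum(y[:, 2], 0.0)
    pe, ce, phe, le = env
    area, vol, mito, cscale = params
    pn = p ** cfg.hill_n_consumption
    f = pn / (pn + cfg.p50_consumption ** cfg.hill_n_consumption)
    g_ph = np.exp(-(((phe - cfg.ph_opt) / cfg.ph_sigma) ** 2))
    vref = (4.0 / 3.0) * np.pi * cfg.r_div ** 3
    q_o2 = cfg.q_o2_max * f * g_ph * mito * cscale * (vol / vref)
    j_o2 = cfg.membrane_p_o2 * area * (pe - y[:, 0])
    uptake = cfg.vmax_glucose * area * (ce / (ce + cfg.km_glucose)
                                        - c / (c + cfg.km_glucose))
    u_ox = cfg.glucose_per_o2 * q_o2
    u_an = (cfg.u_anaerobic_max * (vol / vref) * (1.0 - f) * g_ph
            * c / (c + cfg.km_glucose))
    j_lac = cfg.p_lactate * area * (y[:, 2] - le)
    dp = (j_o2 - q_o2) / vol
    dc = (uptake - u_ox - u_an) / vol
    dl = (2.0 * u_an - j_lac) / vol
    rates = {"o2_consumption": q_o2, "glucose_uptake": uptake,
             "lactate_export": j_lac, "anaerobic_glucose": u_an}
    del lac
    return np.stack([dp, dc, dl], axis=1), rates


def metabolism_population_step(pop: CellPopulation, dt: float, cfg: CellConfig,
                               max_halvings: int = 4):
    """Backward-Euler metabolic update of every living cell.

    Returns per-cell rate arrays (aligned with the population, zeros for
    dead cells) used by the scheduler for grid deposition: O2 consumption
    (mmHg·μm³/s), glucose uptake (mM·μm³/s), lactate export (mM·μm³/s)
    and anaerobic glucose use.  A step producing a negative pool is
    retried with a halved dt, up to ``max_halvings`` times.
    """
    if not (0.5 <= dt <= 30.0):
        raise ValueError("metabolism dt must lie in [0.5, 30] s")
    n = len(pop)
    zero = np.zeros(n)
    out = {"o2_consumption": zero.copy(), "glucose_uptake": zero.copy(),
           "lactate_export": zero.copy(), "anaerobic_glucose": zero.copy()}
    live = np.flatnonzero(pop.alive)
    if len(live) == 0:
        return out
    area = 4.0 * np.pi * pop.radius[live] ** 2
    vol = (4.0 / 3.0) * np.pi * pop.radius[live] ** 3
    mito = pop.n_mito[live] / cfg.n_mito_ref
    cscale = pop.consumption_scale[live]
    env = (pop.env_o2[live], pop.env_glucose[live], pop.env_ph[live],
           pop.env_lactate[live])
    params = (area, vol, mito, cscale)
    y0 = np.stack([pop.o2_in[live], pop.glucose_in[live], pop.lactate_in[live]],
                  axis=1)

    def advance(y, step_dt, depth=0):
        y1 = backward_euler_step(
            lambda yy: metabolism_rhs(yy, env, params, cfg)[0], y, step_dt)
        if (y1 < -1e-9).any():
            if depth >= max_halvings:
                raise RuntimeError("metabolism step rejected after max halvings")
            half = advance(y, step_dt / 2, depth + 1)
            return advance(half, step_dt / 2, depth + 1)
        return np.maximum(y1, 0.0)

    y1 = advance(y0, dt)
    _, rates = metabolism_rhs(y1, env, params, cfg)
    pop.o2_in[live] = y1[:, 0]
    pop.glucose_in[live] = y1[:, 1]
    pop.lactate_in[live] = y1[:, 2]
    for key in out:
        out[key][live] = rates[key]
    return out


def metabolism_step(cell: Cell, env, dt: float, cfg: CellConfig | None = None):
    """Single-cell metabolic step (thin wrapper over the batch kernel).

    ``env`` is (o2, glucose, ph) or (o2, glucose, ph, lactate) at the cell.
    Returns the updated cell and its rate dict.
    """
    cfg = cfg or CellConfig()
    env = tuple(env) + (0.0,) * (4 - len(tuple(env)))
    pop = CellPopulation.from_cells([cell])
    pop.env_o2[0], pop.env_glucose[0], pop.env_ph[0], pop.env_lactate[0] = env
    rates = metabolism_population_step(pop, dt, cfg)
    return pop.view(0), {k: float(v[0]) for k, v in rates.items()}


# ---------------------------------------------------------------------------
# cycle, growth, death, division
# ---------------------------------------------------------------------------

def nutrient_factor(pop_or_p, glucose=None, cfg: CellConfig | None = None):
    """Cycle stretch factor in [0,1]: product of O2 and glucose Hill terms."""
    cfg = cfg or CellConfig()
    if isinstance(pop_or_p, CellPopulation):
        p, c = pop_or_p.o2_in, pop_or_p.glucose_in
    else:
        p, c = np.asarray(pop_or_p, float), np.asarray(glucose, float)
    fo = p ** 2 / (p ** 2 + cfg.p_cycle ** 2)
    fg = c / (c + cfg.k_cycle)
    return fo * fg


def _phase_durations(cfg: CellConfig) -> np.ndarray:
    return np.array([cfg.t_g1m, cfg.t_g1p, cfg.t_s, cfg.t_g2, cfg.t_m])


def cycle_population_step(pop: CellPopulation, dt: float, cfg: CellConfig):
    """Advance clocks, phases, growth and death for the whole population.

    dt in seconds.  Returns (indices ready to divide, indices newly dead).
    """
    dt_h = dt / 3600.0
    durations = _phase_durations(cfg)
    live = pop.alive
    nu = nutrient_factor(pop, cfg=cfg)
    pop.age[live] += dt_h

    # growth: volume gain proportional to the nutrient factor, sized so a
    # daughter doubles its volume over the nominal growth phases
    vref = (4.0 / 3.0) * np.pi * cfg.r_div ** 3
    t_growth = (cfg.t_g1m + cfg.t_g1p + cfg.t_s + cfg.t_g2)
    growing = live & (pop.phase != M_PHASE)
    vol = (4.0 / 3.0) * np.pi * pop.radius ** 3
    vol[growing] += nu[growing] * (0.5 * vref / t_growth) * dt_h
    pop.radius[live] = np.minimum((3.0 * vol[live] / (4.0 * np.pi)) ** (1.0 / 3.0),
                                  cfg.r_max)

    # mitochondrial biogenesis: the endowment doubles over one nominal
    # cycle at full nutrition, so the binomial halving at mitosis is
    # balanced in steady state
    pop.mito_buffer[live] += nu[live] * (cfg.n_mito_ref / cfg.cycle_time) * dt_h
    whole = np.floor(pop.mito_buffer[live]).astype(np.int64)
    pop.n_mito[live] += whole
    pop.mito_buffer[live] -= whole

    # clock and phase transitions (at most one per step since dt ≪ durations)
    pop.phase_clock[live] += nu[live] * dt_h
    live_idx = np.flatnonzero(live)
    dur = durations[pop.phase[live_idx]] * pop.cycle_scale[live_idx]
    over = pop.phase_clock[live_idx] >= dur
    ph = pop.phase[live_idx]
    held = over & (ph == G1P) & (pop.radius[live_idx] < cfg.r_checkpoint)
    pop.phase_clock[live_idx[held]] = dur[held]      # hold at the checkpoint
    ready_mask = over & (ph == M_PHASE)
    advance = over & ~held & ~ready_mask
    adv_idx = live_idx[advance]
    pop.phase_clock[adv_idx] -= dur[advance]
    pop.phase[adv_idx] = pop.phase[adv_idx] + 1
    ready = live_idx[ready_mask]

    # death: sustained anoxia or acidosis
    anoxic = live & (pop.o2_in < cfg.p_death)
    pop.starve_clock[anoxic] += dt_h
    pop.starve_clock[live & ~anoxic] = 0.0
    newly_dead = np.flatnonzero(
        live & ((pop.starve_clock >= cfg.t_starve) | (pop.env_ph < cfg.ph_death)))
    pop.phase[newly_dead] = DEAD

    # dead cells shrink toward the necrotic radius
    dead = pop.phase == DEAD
    decay = np.exp(-cfg.necrotic_shrink_rate * dt_h)
    pop.radius[dead] = cfg.r_necrotic + (pop.radius[dead] - cfg.r_necrotic) * decay
    ready = np.setdiff1d(ready, newly_dead)
    return ready.astype(np.int64), newly_dead


def cycle_step(cell: Cell, dt: float, rng=None, cfg: CellConfig | None = None):
    """Single-cell cycle/death step.  Returns (cell, ready_to_divide)."""
    cfg = cfg or CellConfig()
    if cell.phase == DEAD:
        raise ValueError("cycle_step requires a living cell")
    if cell.phase not in PHASE_NAMES:
        raise ValueError(f"unknown phase {cell.phase}")
    pop = CellPopulation.from_cells([cell])
    ready, _ = cycle_population_step(pop, dt, cfg)
    return pop.view(0), len(ready) > 0


def divide_cell(cell: Cell, rng: np.random.Generator,
                cfg: CellConfig | None = None) -> tuple[Cell, Cell]:
    """Split an M-phase cell into two volume-conserving daughters.

    Daughters sit at ±ε along a uniformly random axis, each with radius
    parent·2^(−1/3); mitochondria partition Binomial(n, 1/2) with the sum
    conserved; the phenotype is copied and both daughters start G1m.
    """
    cfg = cfg or CellConfig()
    if cell.phase != M_PHASE:
        raise ValueError("divide_cell requires an M-phase cell")
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r_d = cell.radius * 2.0 ** (-1.0 / 3.0)
    eps = cfg.division_offset * r_d
    n_a = int(rng.binomial(cell.n_mito, 0.5))
    common = dict(radius=r_d, phase=G1M, phase_clock=0.0, age=0.0,
                  o2_in=cell.o2_in, glucose_in=cell.glucose_in,
                  lactate_in=cell.lactate_in, env_o2=cell.env_o2,
                  env_glucose=cell.env_glucose, env_ph=cell.env_ph,
                  env_lactate=cell.env_lactate, mito_buffer=0.0,
                  consumption_scale=cell.consumption_scale,
                  cycle_scale=cell.cycle_scale, starve_clock=0.0)
    a = Cell(id=cell.id, position=cell.position + eps * direction,
             n_mito=n_a, **common)
    b = Cell(id=-1, position=cell.position - eps * direction,
             n_mito=cell.n_mito - n_a, **common)
    return a, b


def divide_in_population(pop: CellPopulation, idx: int,
                         rng: np.random.Generator, cfg: CellConfig) -> int:
    """Divide cell ``idx`` in place; daughter A reuses the slot, daughter B
    is appended.  Returns the population index of daughter B."""
    a, b = divide_cell(pop.view(idx), rng, cfg)
    b = replace(b, id=pop.next_id)
    pop.write(idx, a)
    return pop.add(b)
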