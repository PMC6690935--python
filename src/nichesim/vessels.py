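"""Perfused vascular network: geometry, rheology, hemodynamics.

The network is a graph of lattice nodes joined by straight cylindrical
segments.  Blood is treated as a Poiseuille fluid with a diameter- and
hematocrit-dependent apparent viscosity (Fåhræus–Lindqvist effect, Pries
empirical law) and red cells partition unevenly at diverging bifurcations
(phase separation).  Pressures are in kPa, lengths in μm, flows in μm³/s
and wall shear stress in Pa.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import VesselConfig

ARTERY, VEIN, CAPILLARY, SPROUT = 0, 1, 2, 3
CLASS_NAMES = {ARTERY: "artery", VEIN: "vein", CAPILLARY: "capillary", SPROUT: "sprout"}


class PerfusionError(RuntimeError):
    """Raised when a network is not perfusable or a flow system is singular."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

class VesselNetwork:
    """Array-of-records vessel graph.

    Node arrays: ``positions`` (N,3), ``node_pressure`` (kPa), ``node_po2``
    (mmHg), ``is_boundary``, ``boundary_pressure`` (NaN where absent).
    Segment arrays: ``seg_nodes`` (M,2), ``radius``, ``length``, ``flow``
    (signed a→b), ``hematocrit``, ``wall_shear``, ``age`` (h),
    ``vessel_class``, ``inside_tumour``, ``collapsed``.
    """

    def __init__(self, positions: np.ndarray, lattice_spacing: float):
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(self.positions)
        self.lattice_spacing = float(lattice_spacing)
        self.node_pressure = np.zeros(n)
        self.node_po2 = np.zeros(n)
        self.is_boundary = np.zeros(n, dtype=bool)
        self.boundary_pressure = np.full(n, np.nan)
        self.seg_nodes = np.empty((0, 2), dtype=np.int64)
        self.radius = np.empty(0)
        self.length = np.empty(0)
        self.flow = np.empty(0)
        self.hematocrit = np.empty(0)
        self.wall_shear = np.empty(0)
        self.age = np.empty(0)
        self.vessel_class = np.empty(0, dtype=np.int8)
        self.inside_tumour = np.empty(0, dtype=bool)
        self.collapsed = np.empty(0, dtype=bool)
        self.inlets = np.empty(0, dtype=np.int64)
        self.outlets = np.empty(0, dtype=np.int64)
        # active angiogenic sprouts: list of dicts with keys
        # tip (node id), segments (list of segment ids), length (μm)
        self.sprout_tips: list[dict] = []

    # -- sizes ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    # -- construction -----------------------------------------------------
    def add_node(self, position, *, is_boundary=False, boundary_pressure=np.nan) -> int:
        self.positions = np.vstack([self.positions, np.asarray(position, float)])
        self.node_pressure = np.append(self.node_pressure, 0.0)
        self.node_po2 = np.append(self.node_po2, 0.0)
        self.is_boundary = np.append(self.is_boundary, is_boundary)
        self.boundary_pressure = np.append(self.boundary_pressure, boundary_pressure)
        return self.n_nodes - 1

    def add_segment(self, a: int, b: int, radius: float, vessel_class: int = CAPILLARY,
                    hematocrit: float = 0.45, age: float = 0.0) -> int:
        if a == b:
            raise ValueError("segment endpoints must differ")
        length = float(np.linalg.norm(self.positions[a] - self.positions[b]))
        if length < 1e-9:
            raise ValueError(f"zero-length segment between nodes {a} and {b}")
        self.seg_nodes = np.vstack([self.seg_nodes, [a, b]])
        self.radius = np.append(self.radius, radius)
        self.length = np.append(self.length, length)
        self.flow = np.append(self.flow, 0.0)
        self.hematocrit = np.append(self.hematocrit, hematocrit)
        self.wall_shear = np.append(self.wall_shear, 0.0)
        self.age = np.append(self.age, age)
        self.vessel_class = np.append(self.vessel_class, np.int8(vessel_class))
        self.inside_tumour = np.append(self.inside_tumour, False)
        self.collapsed = np.append(self.collapsed, False)
        return self.n_segments - 1

    def segment_midpoints(self) -> np.ndarray:
        return 0.5 * (self.positions[self.seg_nodes[:, 0]] + self.positions[self.seg_nodes[:, 1]])

    def copy(self) -> "VesselNetwork":
        out = VesselNetwork(self.positions.copy(), self.lattice_spacing)
        for name in ("node_pressure", "node_po2", "is_boundary", "boundary_pressure",
                     "seg_nodes", "radius", "length", "flow", "hematocrit",
                     "wall_shear", "age", "vessel_class", "inside_tumour",
                     "collapsed", "inlets", "outlets"):
            setattr(out, name, getattr(self, name).copy())
        out.sprout_tips = [dict(t, segments=list(t["segments"])) for t in self.sprout_tips]
        return out

    # -- queries ----------------------------------------------------------
    def active_segments(self) -> np.ndarray:
        """Indices of non-collapsed segments."""
        return np.flatnonzero(~self.collapsed)

    def node_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        active = self.seg_nodes[~self.collapsed]
        np.add.at(deg, active.ravel(), 1)
        return deg

    def remove_segments(self, seg_ids) -> None:
        keep = np.ones(self.n_segments, dtype=bool)
        keep[np.asarray(seg_ids, dtype=np.int64)] = False
        old_to_new = np.cumsum(keep) - 1
        for name in ("seg_nodes", "radius", "length", "flow", "hematocrit",
                     "wall_shear", "age", "vessel_class", "inside_tumour", "collapsed"):
            setattr(self, name, getattr(self, name)[keep])
        for tip in self.sprout_tips:
            tip["segments"] = [int(old_to_new[s]) for s in tip["segments"] if keep[s]]

    def drop_orphan_nodes(self) -> None:
        """Remove nodes referenced by no segment, remapping indices."""
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.seg_nodes.ravel()] = True
        if used.all():
            return
        new_idx = np.cumsum(used) - 1
        for name in ("positions", "node_pressure", "node_po2", "is_boundary",
                     "boundary_pressure"):
            setattr(self, name, getattr(self, name)[used])
        self.seg_nodes = new_idx[self.seg_nodes]
        self.inlets = new_idx[self.inlets[used[self.inlets]]]
        self.outlets = new_idx[self.outlets[used[self.outlets]]]
        for tip in self.sprout_tips:
            tip["tip"] = int(new_idx[tip["tip"]])

    def interior_flow_residuals(self) -> np.ndarray:
        """|net signed flow| at every non-boundary node."""
        net = np.zeros(self.n_nodes)
        a, b = self.seg_nodes[:, 0], self.seg_nodes[:, 1]
        np.subtract.at(net, a, self.flow)
        np.add.at(net, b, self.flow)
        return np.abs(net[~self.is_boundary])

    def total_inflow(self) -> float:
        """Total volumetric flow entering through boundary nodes."""
        net = np.zeros(self.n_nodes)
        a, b = self.seg_nodes[:, 0], self.seg_nodes[:, 1]
        np.subtract.at(net, a, self.flow)
        np.add.at(net, b, self.flow)
        boundary_net = net[self.is_boundary]
        return float(np.abs(boundary_net[boundary_net < 0]).sum())

    def validate(self) -> None:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.seg_nodes.ravel(), 1)
        if (deg == 0).any():
            raise ValueError(f"unreferenced nodes: {np.flatnonzero(deg == 0).tolist()[:10]}")
        if np.isnan(self.boundary_pressure[self.is_boundary]).any():
            raise ValueError("boundary node without boundary pressure")
        key = np.sort(self.seg_nodes, axis=1)
        if len(np.unique(key, axis=0)) != self.n_segments:
            raise ValueError("duplicate segment between a node pair")
        if len(self.inlets) == 0 or len(self.outlets) == 0:
            raise ValueError("network needs at least one inlet and one outlet")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_capillary_mesh(config: VesselConfig, seed: int = 0) -> VesselNetwork:
    """Build a regular cubic capillary mesh with arterial/venous faces.

    Nodes sit on an ``nx × ny × nz`` cubic lattice centred at the origin.
    Arterial inlets are placed on the −x face and venous outlets on the +x
    face (all face nodes by default, or a seeded random subset when
    ``n_inlets``/``n_outlets`` is given).  Segments touching an inlet are
    classed arteries and those touching an outlet veins; everything else is
    a capillary.  Deterministic for a fixed seed.
    """
    if config.spacing <= 0:
        raise ValueError("spacing must be positive")
    if config.nx < 2 or config.ny < 1 or config.nz < 1:
        raise ValueError("domain must contain at least two lattice planes")
    if config.inlet_pressure <= config.outlet_pressure:
        raise ValueError("arterial boundary pressure must exceed venous")
    rng = np.random.default_rng(seed)
    nx, ny, nz, h = config.nx, config.ny, config.nz, config.spacing
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pos = np.column_stack([
        (ix.ravel() - (nx - 1) / 2) * h,
        (iy.ravel() - (ny - 1) / 2) * h,
        (iz.ravel() - (nz - 1) / 2) * h,
    ])
    net = VesselNetwork(pos, lattice_spacing=h)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    edges = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if i + 1 < nx:
                    edges.append((nid(i, j, k), nid(i + 1, j, k)))
                if j + 1 < ny:
                    edges.append((nid(i, j, k), nid(i, j + 1, k)))
                if k + 1 < nz:
                    edges.append((nid(i, j, k), nid(i, j, k + 1)))
    edges = np.asarray(edges, dtype=np.int64)

    m = len(edges)
    radii = config.capillary_radius * (
        1.0 + config.radius_jitter * (2.0 * rng.random(m) - 1.0))

    face_in = np.flatnonzero(pos[:, 0] == pos[:, 0].min())
    face_out = np.flatnonzero(pos[:, 0] == pos[:, 0].max())
    inlets = (face_in if config.n_inlets is None
              else rng.choice(face_in, size=min(config.n_inlets, len(face_in)), replace=False))
    outlets = (face_out if config.n_outlets is None
               else rng.choice(face_out, size=min(config.n_outlets, len(face_out)), replace=False))
    inlets = np.sort(np.asarray(inlets, dtype=np.int64))
    outlets = np.sort(np.asarray(outlets, dtype=np.int64))

    net.seg_nodes = edges
    net.radius = radii
    net.length = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    net.flow = np.zeros(m)
    net.hematocrit = np.full(m, config.inlet_hematocrit)
    net.wall_shear = np.zeros(m)
    net.age = np.zeros(m)
    vclass = np.full(m, CAPILLARY, dtype=np.int8)
    vclass[np.isin(edges, inlets).any(axis=1)] = ARTERY
    vclass[np.isin(edges, outlets).any(axis=1)] = VEIN
    net.vessel_class = vclass
    net.inside_tumour = np.zeros(m, dtype=bool)
    net.collapsed = np.zeros(m, dtype=bool)
    net.is_boundary[inlets] = True
    net.is_boundary[outlets] = True
    net.boundary_pressure[inlets] = config.inlet_pressure
    net.boundary_pressure[outlets] = config.outlet_pressure
    net.inlets, net.outlets = inlets, outlets

    reach = _reachable_nodes(net, inlets)
    if not reach[outlets].any():
        raise PerfusionError("no inlet-outlet path exists")
    if not reach.all():
        raise PerfusionError(
            f"disconnected component: nodes {np.flatnonzero(~reach).tolist()[:20]}")
    net.validate()
    return net


def _reachable_nodes(net: VesselNetwork, sources) -> np.ndarray:
    """Boolean reachability over non-collapsed segments (BFS)."""
    adj: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for a, b in net.seg_nodes[~net.collapsed]:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(net.n_nodes, dtype=bool)
    stack = list(np.atleast_1d(sources))
    seen[stack] = True
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return seen


# ---------------------------------------------------------------------------
# rheology
# ---------------------------------------------------------------------------

def relative_viscosity(diameter, hematocrit):
    """Relative apparent blood viscosity of the Pries empirical law.

    Parametrized by tube diameter (μm) and discharge hematocrit; equals 1
    for pure plasma and exhibits the Fåhræus–Lindqvist minimum near 7 μm
    at physiological hematocrit.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hematocrit, dtype=float)
    if np.any(d <= 3.0):
        raise ValueError("diameter must exceed 3 μm")
    if np.any((h < 0) | (h > 0.99)):
        raise ValueError("hematocrit must lie in [0, 0.99]")
    mu45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + 1.0 / (1.0 + 1e-11 * d ** 12)) \
        + 1.0 / (1.0 + 1e-11 * d ** 12)
    num = (1.0 - h) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    return 1.0 + (mu45 - 1.0) * num / den


def blood_viscosity(diameter, hematocrit, plasma_viscosity: float = 1.2e-3):
    """Effective viscosity in Pa·s: plasma viscosity × relative viscosity."""
    return plasma_viscosity * relative_viscosity(diameter, hematocrit)


# alias under the name the quantity goes by in the microcirculation
# literature: the effective small-vessel viscosity of flowing blood
viscosity_in_vivo = blood_viscosity


def phase_separation_fraction(flow_fraction, d_parent, d_a, d_b, h_parent):
    """Fraction of parent red-cell flux entering daughter ``a``.

    Pries empirical logit law for a diverging bifurcation: below a minimal
    fractional blood flow X0 the daughter receives no red cells, above
    1−X0 it receives all of them, with a logit-linear transition in
    between whose offset depends on the daughter diameter ratio.
    """
    psi = float(flow_fraction)
    x0 = 0.964 * (1.0 - h_parent) / d_parent
    if psi <= x0:
        return 0.0
    if psi >= 1.0 - x0:
        return 1.0
    ratio2 = (d_a / d_b) ** 2
    a = -13.29 * ((ratio2 - 1.0) / (ratio2 + 1.0)) * (1.0 - h_parent) / d_parent
    b = 1.0 + 6.98 * (1.0 - h_parent) / d_parent
    x = (psi - x0) / (1.0 - 2.0 * x0)
    logit = np.log(x / (1.0 - x))
    return float(1.0 / (1.0 + np.exp(-(a + b * logit))))


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------

def segment_conductance(net: VesselNetwork, viscosity=None,
                        plasma_viscosity: float = 1.2e-3) -> np.ndarray:
    """Poiseuille conductance G = πr⁴/(8ηL) per segment, in μm³/(Pa·s)."""
    if viscosity is None:
        eta = blood_viscosity(2.0 * net.radius, np.clip(net.hematocrit, 0.0, 0.99),
                              plasma_viscosity)
    else:
        eta = np.broadcast_to(np.asarray(viscosity, dtype=float), (net.n_segments,))
    g = np.pi * net.radius ** 4 / (8.0 * eta * net.length)
    g = np.where(net.collapsed, 0.0, g)
    return g, eta


def compute_flow(net: VesselNetwork, viscosity=None,
                 plasma_viscosity: float = 1.2e-3) -> VesselNetwork:
    """Solve the Kirchhoff pressure system and set flows and wall shear.

    Modifies ``net`` in place and returns it.  Boundary nodes carry
    Dirichlet pressures (kPa); the linear system is solved for interior
    node pressures, after which the signed segment flow (a→b positive) is
    Q = G·Δp and the wall shear τ = 4η|Q|/(πr³).
    """
    g, eta = segment_conductance(net, viscosity, plasma_viscosity)
    n = net.n_nodes
    a, b = net.seg_nodes[:, 0], net.seg_nodes[:, 1]

    # singularity check: every active component must contain a boundary node
    comp = _component_labels(net)
    active_nodes = np.zeros(n, dtype=bool)
    active_nodes[net.seg_nodes[~net.collapsed].ravel()] = True
    for label in np.unique(comp[active_nodes]):
        members = np.flatnonzero((comp == label) & active_nodes)
        if not net.is_boundary[members].any():
            raise PerfusionError(
                f"isolated subnetwork without boundary pressure; orphan nodes "
                f"{members.tolist()[:20]}")

    lap = sp.coo_matrix(
        (np.concatenate([g, g, -g, -g]),
         (np.concatenate([a, b, a, b]), np.concatenate([a, b, b, a]))),
        shape=(n, n)).tocsr()
    fixed = net.is_boundary
    p = np.zeros(n)
    p[fixed] = net.boundary_pressure[fixed] * 1e3   # kPa -> Pa
    free = ~fixed
    if free.any():
        a_ff = lap[free][:, free]
        rhs = -lap[free][:, fixed] @ p[fixed]
        # isolated free nodes (all incident segments collapsed) get a unit
        # diagonal so the system stays non-singular; their pressure is 0.
        diag = a_ff.diagonal()
        if np.any(diag == 0.0):
            a_ff = a_ff + sp.diags((diag == 0.0).astype(float))
        p[free] = spla.spsolve(a_ff.tocsc(), rhs)
    net.node_pressure = p / 1e3
    dp = p[a] - p[b]
    net.flow = g * dp
    with np.errstate(divide="ignore", invalid="ignore"):
        net.wall_shear = np.where(
            net.collapsed, 0.0, 4.0 * eta * np.abs(net.flow) / (np.pi * net.radius ** 3))
    return net


def _component_labels(net: VesselNetwork) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components
    active = ~net.collapsed
    a, b = net.seg_nodes[active, 0], net.seg_nodes[active, 1]
    adj = sp.coo_matrix((np.ones(len(a)), (a, b)), shape=(net.n_nodes,) * 2)
    return connected_components(adj, directed=False)[1]


# ---------------------------------------------------------------------------
# hematocrit propagation
# ---------------------------------------------------------------------------

def flow_topological_order(net: VesselNetwork, q_tol: float = 1e-12):
    """Topological node order of the directed flow graph.

    Returns ``(order, ok)`` where ``ok`` is False when the orientation
    contains a cycle (the order is then partial).  Segments with |Q| below
    ``q_tol`` × max|Q| count as zero flow and impose no ordering.
    """
    qmax = np.abs(net.flow).max() if net.n_segments else 0.0
    thresh = q_tol * max(qmax, 1e-300)
    n = net.n_nodes
    out_edges: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for s, (a, b) in enumerate(net.seg_nodes):
        if net.collapsed[s] or abs(net.flow[s]) <= thresh:
            continue
        u, v = (a, b) if net.flow[s] > 0 else (b, a)
        out_edges[u].append(v)
        indeg[v] += 1
    order = [int(i) for i in np.flatnonzero(indeg == 0)]
    head = 0
    indeg = indeg.copy()
    while head < len(order):
        u = order[head]
        head += 1
        for v in out_edges[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                order.append(v)
    return order, len(order) == n


def propagate_hematocrit(net: VesselNetwork, inlet_hematocrit: float = 0.45,
                         max_iters: int = 200, tol: float = 1e-12,
                         q_tol: float = 1e-12) -> VesselNetwork:
    """Propagate discharge hematocrit downstream through the network.

    Red-cell flux Q·H is conserved at every junction.  At diverging
    bifurcations of out-degree 2 the flux splits by the Pries phase
    separation law; junctions of higher out-degree split proportionally to
    blood flow.  Requires flows; falls back to damped sweeps when the flow
    orientation is cyclic.
    """
    order, acyclic = flow_topological_order(net, q_tol)
    sweeps = 1 if acyclic else max_iters
    qmax = np.abs(net.flow).max() if net.n_segments else 0.0
    thresh = q_tol * max(qmax, 1e-300)

    h = np.full(net.n_segments, inlet_hematocrit)
    prev = None
    for it in range(sweeps):
        h_new = h.copy()
        _sweep_hematocrit(net, h_new, order, inlet_hematocrit, thresh)
        delta = np.abs(h_new - h).max() if net.n_segments else 0.0
        h = h_new
        if acyclic or delta < tol:
            prev = delta
            break
        prev = delta
    else:
        raise PerfusionError(
            f"hematocrit relaxation failed to converge: residual {prev:.3e}")
    net.hematocrit = np.clip(h, 0.0, 0.99)
    _assign_zero_flow_hematocrit(net, thresh)
    return net


def _sweep_hematocrit(net, h, order, inlet_h, thresh):
    """One in-order sweep applying junction rules at every node."""
    incident: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s, (a, b) in enumerate(net.seg_nodes):
        if not net.collapsed[s]:
            incident[a].append(s)
            incident[b].append(s)
    for u in order:
        seg_ids = np.asarray(incident[u], dtype=np.int64)
        if len(seg_ids) == 0:
            continue
        q_into = np.where(net.seg_nodes[seg_ids, 1] == u, net.flow[seg_ids],
                          -net.flow[seg_ids])
        incoming = seg_ids[q_into > thresh]
        outgoing = seg_ids[q_into < -thresh]
        if len(outgoing) == 0:
            continue
        q_in = np.where(net.seg_nodes[incoming, 1] == u, net.flow[incoming],
                        -net.flow[incoming])
        q_out = -np.where(net.seg_nodes[outgoing, 1] == u, net.flow[outgoing],
                          -net.flow[outgoing])
        flux_in = float((q_in * h[incoming]).sum())
        q_in_tot = float(q_in.sum())
        q_out_tot = float(q_out.sum())
        if net.is_boundary[u] and q_out_tot > q_in_tot * (1 + 1e-9):
            # net source (inlet): supply the deficit at inlet hematocrit
            flux_in += (q_out_tot - q_in_tot) * inlet_h
            q_in_tot = q_out_tot
        if q_in_tot <= 0:
            continue
        h_mix = flux_in / q_in_tot
        if len(outgoing) == 1:
            h[outgoing[0]] = min(flux_in / q_out[0], 0.99)
        elif len(outgoing) == 2:
            if len(incoming) > 0:
                d_parent = float((q_in * 2.0 * net.radius[incoming]).sum() / q_in_tot)
            else:
                d_parent = float(2.0 * net.radius[outgoing].mean())
            sa, sb = outgoing
            frac = phase_separation_fraction(
                q_out[0] / q_out_tot, d_parent,
                2.0 * net.radius[sa], 2.0 * net.radius[sb], h_mix)
            total_flux = h_mix * q_out_tot
            h[sa] = min(total_flux * frac / q_out[0], 0.99)
            h[sb] = min(total_flux * (1.0 - frac) / q_out[1], 0.99)
        else:
            # proportional split: all daughters inherit the mixed hematocrit
            for s in outgoing:
                h[s] = min(h_mix, 0.99)


def _assign_zero_flow_hematocrit(net, thresh):
    """Zero-flow segments inherit the mixed hematocrit at an endpoint.

    The endpoint fed by the lowest-id flowing segment wins the tie-break.
    """
    zero = np.flatnonzero((np.abs(net.flow) <= thresh) & ~net.collapsed)
    if len(zero) == 0:
        return
    node_h = np.full(net.n_nodes, np.nan)
    node_src = np.full(net.n_nodes, np.iinfo(np.int64).max)
    for s in range(net.n_segments):
        if net.collapsed[s] or abs(net.flow[s]) <= thresh:
            continue
        u = net.seg_nodes[s, 1] if net.flow[s] > 0 else net.seg_nodes[s, 0]
        if s < node_src[u]:
            node_src[u] = s
            node_h[u] = net.hematocrit[s]
    for s in zero:
        a, b = net.seg_nodes[s]
        cands = [(node_src[x], node_h[x]) for x in (a, b) if np.isfinite(node_h[x])]
        if cands:
            net.hematocrit[s] = min(cands)[1]


def rbc_flux_balance(net: VesselNetwork) -> tuple[float, float]:
    """(total RBC flux in, total RBC flux out) across boundary nodes."""
    fin = fout = 0.0
    for s, (a, b) in enumerate(net.seg_nodes):
        if net.collapsed[s]:
            continue
        for node, sign in ((a, -1.0), (b, 1.0)):
            if not net.is_boundary[node]:
                continue
            q = sign * net.flow[s]      # q>0: flow arrives at boundary node
            if q > 0:
                fout += q * net.hematocrit[s]
            else:
                fin += -q * net.hematocrit[s]
    return fin, fout
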