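"""Oxygen and substance transport.

Intravascular oxygen is carried both dissolved (proportional to pO2) and
bound to hemoglobin (Hill saturation curve scaled by hematocrit) and is
lost to the tissue through the vessel wall at a rate proportional to the
transmural pO2 difference.  Tissue-side fields obey quasi-static
reaction-diffusion equations discretized with 7-point finite differences:

    ∇·(D ∇c) − λ c + S − M(c) = 0,   M(c) = m0 c / (c + c_half)

with Dirichlet or zero-flux (Neumann) boundaries.  The blood/tissue pair
is solved by alternating the intravascular march and the tissue solve
until the fields stop moving.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .grid import TissueGrid, rasterize_segment, sample as _grid_sample
from .vessels import VesselNetwork, flow_topological_order


class ConvergenceError(RuntimeError):
    """A nonlinear or coupled iteration failed to converge."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals or [])


def hill_saturation(p, p50: float, n: float):
    """Hemoglobin-style saturation pⁿ/(pⁿ + p50ⁿ), monotone, in [0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("partial pressure must be non-negative")
    if p50 <= 0 or n <= 0:
        raise ValueError("p50 and n must be positive")
    pn = p ** n
    return pn / (pn + p50 ** n)


# ---------------------------------------------------------------------------
# finite-difference reaction-diffusion
# ---------------------------------------------------------------------------

def _assemble_operator(grid: TissueGrid, diffusivity: float, decay,
                       linear_sink, boundary):
    """Sparse operator for −D∇² + λ + a with the requested boundaries.

    Neumann boundaries use the mirrored-ghost stencil; a Dirichlet boundary
    pins the outermost layer of nodes.  Returns (A, dirichlet_mask).
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    h2 = grid.spacing ** 2
    idx = np.arange(n).reshape(grid.shape)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        for side in (-1, 1):
            src = np.roll(idx, -side, axis=axis)
            sl = [slice(None)] * 3
            sl[axis] = slice(1, None) if side == -1 else slice(0, -1)
            interior = idx[tuple(sl)].ravel()
            neighbor = src[tuple(sl)].ravel()
            rows.append(interior)
            cols.append(neighbor)
            vals.append(np.full(len(interior), -diffusivity / h2))
            np.add.at(diag, interior, diffusivity / h2)
            if boundary == "neumann":
                # mirrored ghost: the missing neighbour contributes nothing
                pass
    diag += np.broadcast_to(np.asarray(decay, float).ravel()
                            if np.ndim(decay) else decay, (n,)).copy()
    if linear_sink is not None:
        diag = diag + np.asarray(linear_sink, float).ravel()

    a = sp.coo_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n)]),
          np.concatenate(cols + [np.arange(n)]))),
        shape=(n, n)).tocsr()

    dirichlet = np.zeros(n, dtype=bool)
    if boundary != "neumann":
        shell = np.zeros(grid.shape, dtype=bool)
        shell[0, :, :] = shell[-1, :, :] = True
        shell[:, 0, :] = shell[:, -1, :] = True
        shell[:, :, 0] = shell[:, :, -1] = True
        dirichlet = shell.ravel()
    return a, dirichlet


def _spd_solve(a, rhs, x0=None):
    """Jacobi-preconditioned CG (the operator is SPD); direct fallback."""
    diag = a.diagonal()
    if np.any(diag <= 0):
        return spla.spsolve(a.tocsc(), rhs)
    m = sp.diags(1.0 / diag)
    x, info = spla.cg(a, rhs, x0=x0, rtol=1e-12, atol=0.0, maxiter=5000, M=m)
    if info != 0:
        x = spla.spsolve(a.tocsc(), rhs)
    return x


def _solve_linear(a, rhs, dirichlet, dirichlet_values, x0=None):
    n = a.shape[0]
    x = np.zeros(n) if x0 is None else x0.ravel().copy()
    if dirichlet.any():
        x[dirichlet] = dirichlet_values
        free = ~dirichlet
        a_ff = a[free][:, free].tocsr()
        rhs_f = rhs[free] - a[free][:, dirichlet] @ x[dirichlet]
        x[free] = _spd_solve(a_ff, rhs_f, x0=x[free])
    else:
        x = _spd_solve(a, rhs, x0=x0.ravel() if x0 is not None else None)
    return x


def solve_reaction_diffusion(grid: TissueGrid, field_name: str, diffusivity: float,
                             decay: float = 0.0, source=None, linear_sink_coeff=None,
                             linear_sink_value=None, mm_sink_rate=None,
                             mm_half: float = 1.0, boundary="neumann",
                             boundary_value: float = 0.0,
                             fixed_mask=None, fixed_values=None,
                             tol: float = 1e-6, max_iters: int = 50,
                             clip_min: float | None = 0.0) -> np.ndarray:
    """Steady reaction-diffusion solve for one grid field.

    ``source`` is a volumetric source density (units of field per second);
    ``linear_sink_coeff``/``linear_sink_value`` express exchange terms of
    the form a·(b − c) (e.g. transmural flux toward a vessel value b);
    ``mm_sink_rate`` adds a Michaelis–Menten sink m0·c/(c+mm_half) handled
    by damped lagged-coefficient iteration.  ``fixed_mask`` pins interior
    nodes (e.g. voxels crossed by a vessel in the Krogh scenario).  The
    converged field is written back into the grid and returned.

    Raises :class:`ConvergenceError` with the residual history when the
    nonlinear iteration does not reach ``tol``.
    """
    if min(grid.shape) < 3:
        raise ValueError("grid must be at least 3 nodes per axis")
    if diffusivity < 0 or (np.ndim(decay) == 0 and decay < 0):
        raise ValueError("diffusivity and decay must be non-negative")

    n = grid.n_nodes
    src = np.zeros(n)
    if source is not None:
        src += np.asarray(source, float).ravel()
    a_lin = None
    if linear_sink_coeff is not None:
        a_lin = np.asarray(linear_sink_coeff, float).ravel()
        src = src + a_lin * np.asarray(linear_sink_value, float).ravel()

    c = grid.fields[field_name].ravel().copy()
    fixed = np.zeros(n, dtype=bool)
    fvals = None
    if fixed_mask is not None:
        fixed = np.asarray(fixed_mask, bool).ravel().copy()
        fvals = np.broadcast_to(np.asarray(fixed_values, float).ravel()
                                if np.ndim(fixed_values) else fixed_values,
                                (int(fixed.sum()),))
        c[fixed] = fvals

    mm = None if mm_sink_rate is None else np.asarray(mm_sink_rate, float).ravel()
    residuals = []
    damping = 0.7
    n_pass = 1 if mm is None else max_iters
    for _ in range(n_pass):
        lagged = None if mm is None else mm / (np.maximum(c, 0.0) + mm_half)
        sink = a_lin
        if lagged is not None:
            sink = lagged if sink is None else sink + lagged
        a, shell = _assemble_operator(grid, diffusivity, decay, sink, boundary)
        pin = shell | fixed
        pin_vals = np.where(shell, boundary_value, 0.0)[pin] if fixed.any() or shell.any() else np.zeros(0)
        if fixed.any():
            tmp = np.where(shell, boundary_value, 0.0)
            tmp[fixed] = fvals
            pin_vals = tmp[pin]
        c_new = _solve_linear(a, src, pin, pin_vals, x0=c)
        if clip_min is not None:
            c_new = np.maximum(c_new, clip_min)
        scale = max(np.abs(c_new).max(), 1e-300)
        res = np.abs(c_new - c).max() / scale
        residuals.append(res)
        c = c if mm is None else (1.0 - damping) * c + damping * c_new
        if mm is None:
            c = c_new
            break
        if res < tol:
            c = c_new
            break
    else:
        raise ConvergenceError(
            f"Michaelis-Menten iteration stalled at residual {residuals[-1]:.3e}",
            residuals)
    grid.fields[field_name] = c.reshape(grid.shape)
    return grid.fields[field_name]


# ---------------------------------------------------------------------------
# intravascular oxygen
# ---------------------------------------------------------------------------

def blood_o2_content(p, hematocrit, kappa: float, p50: float, n: float):
    """Total O2 content per unit blood volume, in dissolved-pO2 units.

    content = p + H·κ·S(p): the dissolved part plus the hemoglobin-bound
    part, with κ the bound-capacity in mmHg-equivalents at full saturation.
    """
    return np.asarray(p, float) + hematocrit * kappa * hill_saturation(p, p50, n)


def _content_and_slope(p, h, kappa, p50, n):
    pn = p ** n
    p50n = p50 ** n
    sat = pn / (pn + p50n)
    dsat = n * p ** (n - 1.0) * p50n / (pn + p50n) ** 2 if p > 0 else 0.0
    return p + h * kappa * sat, 1.0 + h * kappa * dsat


def _invert_content(content, hematocrit, kappa, p50, n):
    """pO2 from total content (monotone; Newton with bisection fallback)."""
    if content <= 0:
        return 0.0
    p = min(content, 100.0)
    for _ in range(50):
        c, dc = _content_and_slope(p, hematocrit, kappa, p50, n)
        step = (c - content) / dc
        p_new = p - step
        if p_new <= 0:
            p_new = 0.5 * p
        if abs(p_new - p) < 1e-11 * max(p, 1.0):
            return p_new
        p = p_new
    f = lambda q: blood_o2_content(q, hematocrit, kappa, p50, n) - content
    hi = max(200.0, content)
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 0.0, hi, xtol=1e-10)


def intravascular_po2(net: VesselNetwork, grid: TissueGrid, transfer_coeff: float,
                      inlet_po2: float = 80.0, kappa: float = 1.6e4,
                      p50: float = 27.0, hill_n: float = 2.7,
                      ds: float = 40.0, max_iters: int = 50,
                      tol: float = 1e-6) -> np.ndarray:
    """March oxygen along the flow and set per-node blood pO2.

    Along each perfused segment the O2 content flux Q·C(p) decreases by the
    transmural loss 2πr·γ·(p − p_tissue) integrated over the centreline
    (backward-Euler substeps of length ``ds``).  Inlet boundary nodes take
    the configured arterial pO2; at converging junctions contents mix
    flux-weighted.  Cyclic flow orientations fall back to repeated sweeps.

    Stores blood pO2 in ``net.node_po2`` and returns the per-segment mean
    blood pO2 (the value the tissue coupling exchanges against).
    """
    order, acyclic = flow_topological_order(net)
    sweeps = 1 if acyclic else max_iters
    node_p = np.full(net.n_nodes, inlet_po2, dtype=float)
    seg_mean_p = np.full(net.n_segments, inlet_po2, dtype=float)
    qmax = np.abs(net.flow).max() if net.n_segments else 0.0
    thresh = 1e-12 * max(qmax, 1e-300)

    prev = None
    for _ in range(sweeps):
        before = node_p.copy()
        _march_once(net, grid, node_p, seg_mean_p, order, transfer_coeff,
                    inlet_po2, kappa, p50, hill_n, ds, thresh)
        res = np.abs(node_p - before).max()
        prev = res
        if acyclic or res < tol:
            break
    else:
        raise ConvergenceError(
            f"intravascular relaxation stalled at residual {prev:.3e}")
    net.node_po2 = node_p
    return seg_mean_p


def _march_once(net, grid, node_p, seg_mean_p, order, gamma, inlet_po2,
                kappa, p50, hill_n, ds, thresh):
    n_nodes = net.n_nodes
    content_in = np.zeros(n_nodes)     # accumulated O2 content flux arriving
    flow_in = np.zeros(n_nodes)
    seg_by_tail: list[list[int]] = [[] for _ in range(n_nodes)]
    for s, (a, b) in enumerate(net.seg_nodes):
        if net.collapsed[s] or abs(net.flow[s]) <= thresh:
            continue
        u = a if net.flow[s] > 0 else b
        seg_by_tail[u].append(s)

    # flux-weighted hematocrit of arrivals, accumulated during the march
    h_flux_in = np.zeros(n_nodes)

    for u in order:
        if net.is_boundary[u] and flow_in[u] <= 0:
            node_p[u] = inlet_po2
        elif flow_in[u] > 0:
            h_node = h_flux_in[u] / flow_in[u]
            node_p[u] = _invert_content(content_in[u] / flow_in[u], h_node,
                                        kappa, p50, hill_n)
        # march every segment leaving u
        for s in seg_by_tail[u]:
            a, b = net.seg_nodes[s]
            head = b if net.flow[s] > 0 else a
            q = abs(net.flow[s])
            h = net.hematocrit[s]
            p = float(node_p[u])
            p0 = net.positions[u]
            p1 = net.positions[head]
            length = net.length[s]
            nsub = max(1, int(np.ceil(length / ds)))
            dl = length / nsub
            t = (np.arange(nsub) + 0.5) / nsub
            midpoints = p0 + t[:, None] * (p1 - p0)
            p_tis = _grid_sample(grid, "po2", midpoints) if gamma > 0 else np.zeros(nsub)
            k = 2.0 * np.pi * net.radius[s] * gamma * dl / q
            acc = 0.0
            for i in range(nsub):
                p = _implicit_exchange_step(p, p_tis[i], k, h, kappa, p50, hill_n)
                acc += p
            seg_mean_p[s] = acc / nsub
            content_in[head] += q * blood_o2_content(p, h, kappa, p50, hill_n)
            flow_in[head] += q
            h_flux_in[head] += q * h
            node_p[head] = p   # provisional; overwritten when head is processed


def _implicit_exchange_step(p_in, p_tis, k, h, kappa, p50, n):
    """One backward-Euler substep of C(p1) = C(p0) − k (p1 − p_tis).

    The left side C(p) + k·p is strictly increasing, so Newton from the
    inlet value converges in a few iterations; a bracketing fallback
    guards pathological parameters.
    """
    c0, _ = _content_and_slope(p_in, h, kappa, p50, n)
    target = c0 + k * p_tis
    p = p_in
    for _ in range(50):
        c, dc = _content_and_slope(p, h, kappa, p50, n)
        g = c + k * p - target
        p_new = p - g / (dc + k)
        if p_new <= 0:
            p_new = 0.5 * p
        if abs(p_new - p) < 1e-11 * max(p, 1.0):
            return p_new
        p = p_new
    f = lambda q: blood_o2_content(q, h, kappa, p50, n) + k * (q - p_tis) - c0
    lo, hi = 0.0, max(p_in, p_tis, 1e-6)
    while f(hi) < 0:
        hi = max(hi * 2.0, 1e-3)
    return brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# coupled blood/tissue solve
# ---------------------------------------------------------------------------

def vessel_exchange_stencil(net: VesselNetwork, grid: TissueGrid, gamma: float,
                            ds: float = 40.0):
    """Per-voxel exchange coefficients for all perfused segments.

    Returns (flat voxel indices, a-coefficients, segment index per entry)
    where the tissue-side source is a·(p_blood − p_tissue)/V_voxel with
    a = γ·2πr·Δs for the piece of centreline crossing the voxel.
    """
    idxs, coeffs, segs = [], [], []
    # unperfused segments still exchange (stagnant blood)
    for s in np.flatnonzero(~net.collapsed):
        a, b = net.seg_nodes[s]
        flat, lens, _ = rasterize_segment(grid, net.positions[a], net.positions[b],
                                          ds_target=min(ds, grid.spacing / 2))
        idxs.append(flat)
        coeffs.append(gamma * 2.0 * np.pi * net.radius[s] * lens)
        segs.append(np.full(len(flat), s, dtype=np.int64))
    if not idxs:
        return (np.zeros(0, np.int64), np.zeros(0), np.zeros(0, np.int64))
    return np.concatenate(idxs), np.concatenate(coeffs), np.concatenate(segs)


def coupled_oxygen_solve(net: VesselNetwork, grid: TissueGrid, *,
                         transfer_coeff: float, inlet_po2: float = 80.0,
                         kappa: float = 1.6e4, p50: float = 27.0,
                         hill_n: float = 2.7, d_o2: float = 2000.0,
                         mm_sink_rate=None, mm_half: float = 4.0,
                         ds: float = 40.0, tol: float = 0.1,
                         max_iters: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Alternate intravascular march and tissue solve to convergence.

    ``mm_sink_rate`` is the deposited consumption density (mmHg/s at
    saturation) on grid nodes.  Convergence is declared when the largest
    tissue pO2 change between iterations falls below ``tol`` (mmHg).
    Returns (per-segment mean blood pO2, tissue pO2 field).  Raises
    :class:`ConvergenceError` carrying the residual history otherwise.
    """
    flat_idx, a_coef, seg_of = vessel_exchange_stencil(net, grid, transfer_coeff, ds)
    vvol = grid.voxel_volume
    residuals = []
    seg_p = np.full(net.n_segments, inlet_po2)
    for it in range(max_iters):
        p_before = grid.fields["po2"].copy()
        seg_p = intravascular_po2(net, grid, transfer_coeff, inlet_po2,
                                  kappa, p50, hill_n, ds)
        a_lin = np.zeros(grid.n_nodes)
        b_val = np.zeros(grid.n_nodes)
        if len(flat_idx):
            np.add.at(a_lin, flat_idx, a_coef / vvol)
            np.add.at(b_val, flat_idx, (a_coef / vvol) * seg_p[seg_of])
        with np.errstate(invalid="ignore", divide="ignore"):
            b_val = np.where(a_lin > 0, b_val / np.maximum(a_lin, 1e-300), 0.0)
        solve_reaction_diffusion(
            grid, "po2", d_o2, decay=0.0,
            linear_sink_coeff=a_lin, linear_sink_value=b_val,
            mm_sink_rate=mm_sink_rate, mm_half=mm_half,
            boundary="neumann", tol=1e-8, max_iters=80)
        res = np.abs(grid.fields["po2"] - p_before).max()
        residuals.append(float(res))
        if res < tol:
            break
    else:
        raise ConvergenceError(
            f"coupled oxygen solve stalled: residuals {residuals[-3:]}", residuals)
    return seg_p, grid.fields["po2"]


def oxygen_budget(net: VesselNetwork, grid: TissueGrid, *, transfer_coeff: float,
                  seg_p: np.ndarray, mm_sink_rate=None, mm_half: float = 4.0,
                  ds: float = 40.0) -> tuple[float, float]:
    """(total O2 released by vessels, total consumed by tissue), mmHg·μm³/s."""
    flat_idx, a_coef, seg_of = vessel_exchange_stencil(net, grid, transfer_coeff, ds)
    p_t = grid.fields["po2"].ravel()
    released = float((a_coef * (seg_p[seg_of] - p_t[flat_idx])).sum())
    consumed = 0.0
    if mm_sink_rate is not None:
        m = np.asarray(mm_sink_rate, float).ravel()
        c = np.maximum(p_t, 0.0)
        consumed = float((m * c / (c + mm_half)).sum() * grid.voxel_volume)
    return released, consumed
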