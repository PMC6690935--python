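"""Vascular remodeling under tumour influence.

Four processes reshape the network on the hour timescale once the
growth-factor field has switched angiogenesis on:

* **sprouting** — segment midpoints bathed in VEGF above threshold launch
  tip sprouts with a per-site probability; tips walk one lattice step per
  tick up the VEGF gradient and anastomose when they pass close to
  another vessel, becoming perfusable;
* **dilation** — vessels inside the tumour dilate toward a cap;
* **collapse** — tumour vessels whose wall shear drops below a critical
  value collapse stochastically and are removed at pruning;
* **regression** — immature vessels starved of VEGF for longer than a
  grace period are removed (arteries and veins never regress).

After every tick the network is pruned back to a perfusable graph and the
hemodynamics are re-solved.
"""

from __future__ import annotations

import numpy as np

from . import cells as cellmod
from . import grid as gridmod
from . import vessels as vesmod
from .config import RemodelingConfig
from .vessels import ARTERY, CAPILLARY, SPROUT, VEIN, PerfusionError, VesselNetwork

RemodelingParams = RemodelingConfig

_LATTICE_DIRS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)


def sprouting_step(net: VesselNetwork, grid, params: RemodelingConfig,
                   rng: np.random.Generator, dt_vessel: float,
                   vegf_threshold: float, events: list | None = None) -> VesselNetwork:
    """Launch and extend VEGF-guided sprouts (one lattice step per tick).

    Launch sites are midpoints of non-collapsed segments where the VEGF
    field exceeds ``vegf_threshold``; each fires with probability
    ``sprout_probability × dt_vessel``.  Active tips move along the
    lattice direction best aligned with the VEGF gradient (random
    tie-break), anastomose to a nearby vessel within
    ``anastomosis_radius``, and are abandoned past ``sprout_max_length``.
    """
    h = net.lattice_spacing
    events = events if events is not None else []

    # --- extend existing tips first (deterministic order) ---------------
    still_active = []
    for tip in net.sprout_tips:
        tip_pos = net.positions[tip["tip"]]
        grad = gridmod.sample_gradient(grid, "vegf", tip_pos[None, :])[0]
        scores = _LATTICE_DIRS @ grad
        prev = tip.get("prev_dir")
        if prev is not None:
            scores[np.argmax(_LATTICE_DIRS @ (-np.asarray(prev)))] = -np.inf
        best = scores.max()
        choices = np.flatnonzero(scores >= best - 1e-15 * max(abs(best), 1.0))
        k = int(choices[rng.integers(len(choices))]) if len(choices) > 1 else int(choices[0])
        direction = _LATTICE_DIRS[k]
        new_pos = tip_pos + direction * h
        # the tip walks the same lattice as the mesh: stepping onto an
        # existing node is an anastomosis, never a duplicate node
        hit = _coincident_node(net, new_pos, exclude=tip["tip"])
        if hit is not None:
            if not _segment_exists(net, tip["tip"], hit):
                seg = net.add_segment(tip["tip"], hit, params_radius(net),
                                      SPROUT, hematocrit=0.0)
                tip["segments"].append(seg)
            events.append({"kind": "anastomosis", "position": new_pos.tolist()})
            continue        # tip retired: sprout is connected
        new_node = net.add_node(new_pos)
        seg = net.add_segment(tip["tip"], new_node, params_radius(net), SPROUT,
                              hematocrit=0.0)
        tip["segments"].append(seg)
        tip["tip"] = new_node
        tip["length"] += h
        tip["prev_dir"] = direction.tolist()
        # anastomosis: does the new tip come close to a foreign vessel?
        target = _nearest_foreign_segment(net, new_pos, set(tip["segments"]))
        if target is not None and target[0] <= params.anastomosis_radius:
            _, seg_id = target
            end = _closest_endpoint(net, seg_id, new_pos)
            if end != new_node and not _segment_exists(net, new_node, end) \
                    and np.linalg.norm(net.positions[end] - new_pos) > 1e-9:
                bridge = net.add_segment(new_node, end, params_radius(net),
                                         SPROUT, hematocrit=0.0)
                tip["segments"].append(bridge)
            events.append({"kind": "anastomosis", "position": new_pos.tolist()})
            continue        # tip retired: sprout is connected
        if tip["length"] >= params.sprout_max_length:
            net.remove_segments(tip["segments"])
            events.append({"kind": "sprout_abandoned", "position": new_pos.tolist()})
            continue
        still_active.append(tip)
    net.sprout_tips = still_active

    # --- launch new sprouts ---------------------------------------------
    mids = net.segment_midpoints()
    vegf = gridmod.sample(grid, "vegf", mids) if net.n_segments else np.zeros(0)
    eligible = np.flatnonzero((vegf > vegf_threshold) & ~net.collapsed
                              & (net.vessel_class != SPROUT))
    p_fire = min(params.sprout_probability * dt_vessel, 1.0)
    firing = eligible[rng.random(len(eligible)) < p_fire] if len(eligible) else eligible
    # process launches from the highest segment id down so that the
    # removal-and-split of one parent does not shift the ids of the rest
    for s in sorted((int(x) for x in firing), reverse=True):
        root = net.add_node(mids[s])
        a, b = net.seg_nodes[s]
        # split the parent segment so the sprout root is a real junction
        r, cls, age, hct = (net.radius[s], net.vessel_class[s], net.age[s],
                            net.hematocrit[s])
        net.remove_segments([s])
        s1 = net.add_segment(a, root, r, cls, hematocrit=hct, age=age)
        s2 = net.add_segment(root, b, r, cls, hematocrit=hct, age=age)
        del s1, s2
        net.sprout_tips.append({"tip": root, "segments": [], "length": 0.0,
                                "prev_dir": None})
        events.append({"kind": "sprout", "position": mids[s].tolist()})
    return net


def params_radius(net: VesselNetwork) -> float:
    """Radius of newly formed sprout segments (median capillary radius)."""
    cap = net.radius[net.vessel_class == CAPILLARY]
    return float(np.median(cap)) if len(cap) else 4.0


def _coincident_node(net: VesselNetwork, pos, exclude: int, tol: float = 1e-6):
    d = np.linalg.norm(net.positions - np.asarray(pos, float), axis=1)
    d[exclude] = np.inf
    j = int(np.argmin(d))
    return j if d[j] < tol else None


def _segment_exists(net: VesselNetwork, a: int, b: int) -> bool:
    pair = (min(a, b), max(a, b))
    key = np.sort(net.seg_nodes, axis=1)
    return bool(((key[:, 0] == pair[0]) & (key[:, 1] == pair[1])).any())


def _nearest_foreign_segment(net: VesselNetwork, pos, own: set):
    best = (np.inf, -1)
    p = np.atleast_2d(pos)
    for s in np.flatnonzero(~net.collapsed):
        if s in own:
            continue
        a, b = net.seg_nodes[s]
        from .coupling import point_segment_distance
        d = point_segment_distance(p, net.positions[a], net.positions[b])[0]
        if d < best[0]:
            best = (d, s)
    return None if best[1] < 0 else best


def _closest_endpoint(net: VesselNetwork, seg_id: int, pos) -> int:
    a, b = net.seg_nodes[seg_id]
    da = np.linalg.norm(net.positions[a] - pos)
    db = np.linalg.norm(net.positions[b] - pos)
    return int(a if da <= db else b)


def dilation_collapse_step(net: VesselNetwork, tumour_mask: np.ndarray,
                           params: RemodelingConfig, rng: np.random.Generator,
                           events: list | None = None) -> VesselNetwork:
    """Dilate tumour vessels and stochastically collapse low-shear ones.

    ``tumour_mask`` is a per-segment boolean (inside the tumour region).
    Collapsed segments are flagged, lose their flow and disappear at the
    next pruning.
    """
    events = events if events is not None else []
    net.inside_tumour = np.asarray(tumour_mask, bool)
    inside = net.inside_tumour & ~net.collapsed
    net.radius[inside] = np.minimum(net.radius[inside] + params.dilation_rate,
                                    params.r_max)
    eligible = np.flatnonzero(inside & (net.wall_shear < params.tau_crit))
    if len(eligible):
        fire = rng.random(len(eligible)) < params.collapse_probability
        for s in eligible[fire]:
            net.collapsed[s] = True
            net.flow[s] = 0.0
            net.wall_shear[s] = 0.0
            events.append({"kind": "collapse", "segment": int(s)})
    return net


def regression_step(net: VesselNetwork, grid, params: RemodelingConfig,
                    eligible_mask: np.ndarray | None = None,
                    events: list | None = None) -> VesselNetwork:
    """Remove immature vessels starved of VEGF.

    Capillaries and sprouts older than ``regression_grace`` whose midpoint
    VEGF lies below ``vegf_regress_threshold`` are removed; arteries and
    veins never regress.  ``eligible_mask`` optionally restricts the rule
    to a region (the scheduler passes the tumour neighbourhood).
    """
    events = events if events is not None else []
    if net.n_segments == 0:
        return net
    mids = net.segment_midpoints()
    vegf = gridmod.sample(grid, "vegf", mids)
    immature = np.isin(net.vessel_class, (CAPILLARY, SPROUT))
    protected = np.isin(net.vessel_class, (ARTERY, VEIN))
    active_tip_segs = {s for tip in net.sprout_tips for s in tip["segments"]}
    mask = (immature & ~protected & (net.age >= params.regression_grace)
            & (vegf < params.vegf_regress_threshold) & ~net.collapsed)
    if eligible_mask is not None:
        mask &= np.asarray(eligible_mask, bool)
    mask[list(active_tip_segs)] = False
    removed = np.flatnonzero(mask)
    for s in removed:
        events.append({"kind": "regression", "segment": int(s),
                       "position": mids[s].tolist()})
    if len(removed):
        net.remove_segments(removed)
    return net


def prune_and_recompute(net: VesselNetwork, inlet_hematocrit: float = 0.45,
                        plasma_viscosity: float = 1.2e-3,
                        events: list | None = None) -> VesselNetwork:
    """Strip collapsed segments and dead-end branches, re-solve the flow.

    A segment survives only if it can lie on an inlet→outlet path, i.e.
    after iterative removal of degree-1 interior nodes (active sprout
    chains are exempt while they grow).  Raises :class:`PerfusionError`
    when no inlet-outlet path remains.
    """
    events = events if events is not None else []
    collapsed = np.flatnonzero(net.collapsed)
    if len(collapsed):
        net.remove_segments(collapsed)

    keep_always = {s for tip in net.sprout_tips for s in tip["segments"]}
    while True:
        deg = np.zeros(net.n_nodes, dtype=np.int64)
        np.add.at(deg, net.seg_nodes.ravel(), 1)
        endpoint_deg = deg[net.seg_nodes]
        dead_end = ((endpoint_deg == 1) & ~net.is_boundary[net.seg_nodes]).any(axis=1)
        dead_end[list(keep_always)] = False
        drop = np.flatnonzero(dead_end)
        if len(drop) == 0:
            break
        for s in drop:
            events.append({"kind": "pruned", "segment": int(s)})
        net.remove_segments(drop)
        keep_always = {s for tip in net.sprout_tips for s in tip["segments"]}

    # components cut off from every boundary (e.g. sprout chains whose
    # parent vessel regressed) cannot carry flow and are removed
    if net.n_segments:
        reach_any = vesmod._reachable_nodes(
            net, np.concatenate([net.inlets, net.outlets]))
        floating = np.flatnonzero(~reach_any[net.seg_nodes].all(axis=1))
        if len(floating):
            for s in floating:
                events.append({"kind": "pruned", "segment": int(s)})
            net.remove_segments(floating)
            net.sprout_tips = [t for t in net.sprout_tips if t["segments"]]

    net.drop_orphan_nodes()
    if net.n_segments == 0:
        raise PerfusionError("network fully disconnected after pruning")
    reach = vesmod._reachable_nodes(net, net.inlets)
    if not reach[net.outlets].any():
        raise PerfusionError("no inlet-outlet path remains after pruning")
    vesmod.compute_flow(net, plasma_viscosity=plasma_viscosity)
    vesmod.propagate_hematocrit(net, inlet_hematocrit)
    return net


def segment_tumour_mask(net: VesselNetwork, cells, alpha: float) -> np.ndarray:
    """Per-segment flag: midpoint inside the alpha-shape of the cell cloud."""
    tri, kept = cellmod.alpha_complex_mask(cells, alpha)
    if tri is None:
        return np.zeros(net.n_segments, dtype=bool)
    return cellmod.points_in_alpha_shape(net.segment_midpoints(), tri, kept)


def remodel_tick(state) -> None:
    """One full remodeling pass: sprout, dilate/collapse, regress, prune.

    Also promotes sprouts past the maturation age to capillaries and
    re-solves flow/hematocrit.  Appends structured events to the state.
    """
    cfg = state.config
    params = cfg.remodeling
    net = state.network
    rng = state.rng
    raw: list[dict] = []

    alpha = (params.alpha_factor * max(float(np.mean(state.cells.radius)), 1.0)) ** 2
    sprouting_step(net, state.grid, params, rng, cfg.schedule.dt_vessel,
                   cfg.schedule.vegf_threshold, raw)
    mask = segment_tumour_mask(net, state.cells, alpha)
    dilation_collapse_step(net, mask, params, rng, raw)
    # regression acts in the tumour neighbourhood: inside the alpha shape
    # or within one lattice spacing of it (midpoint near any cell)
    near = mask.copy()
    if len(state.cells):
        from scipy.spatial import cKDTree
        tree = cKDTree(state.cells.position)
        d, _ = tree.query(net.segment_midpoints(), k=1)
        near |= d <= net.lattice_spacing
    regression_step(net, state.grid, params, eligible_mask=near, events=raw)
    prune_and_recompute(net, cfg.vessels.inlet_hematocrit,
                        cfg.vessels.plasma_viscosity, raw)
    mature = (net.vessel_class == SPROUT) & (net.age >= params.maturation_age)
    net.vessel_class[mature] = CAPILLARY
    for ev in raw:
        state.log_event(ev.pop("kind"), **ev)
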