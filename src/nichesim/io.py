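"""Snapshot persistence, VTK export and event logging.

Snapshots are single HDF5 files holding the full simulation state (cell
table, vessel node/segment tables, grid fields, RNG state and a config
echo) with a checked schema version; writing is byte-deterministic
(``track_times`` disabled) so identical states produce identical files.
VTK exports use the legacy ASCII format readable by any VTK-based viewer.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .cells import CellPopulation, _FIELDS
from .config import SimulationConfig
from .grid import TissueGrid
from .vessels import VesselNetwork

SCHEMA_VERSION = 1

_NODE_COLS = ("node_pressure", "node_po2", "is_boundary", "boundary_pressure")
_SEG_COLS = ("radius", "length", "flow", "hematocrit", "wall_shear", "age",
             "vessel_class", "inside_tumour", "collapsed")
_GRID_FIELDS = ("po2", "glucose", "ph", "lactate", "vegf", "o2_sink",
                "glucose_sink", "lactate_source", "vegf_source")


class SnapshotError(RuntimeError):
    pass


def _dset(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def write_snapshot(state, path) -> Path:
    """Write the full state losslessly; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["time"] = state.time
        f.attrs["step"] = state.step
        f.attrs["remodeling_active"] = state.remodeling_active
        f.attrs["config"] = state.config.to_json()
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state,
                                          sort_keys=True)

        cg = f.create_group("cells")
        _dset(cg, "position", state.cells.position)
        for name, _ in _FIELDS:
            _dset(cg, name, getattr(state.cells, name))
        cg.attrs["next_id"] = state.cells.next_id

        vg = f.create_group("vessels")
        _dset(vg, "positions", state.network.positions)
        _dset(vg, "seg_nodes", state.network.seg_nodes)
        for col in _NODE_COLS + _SEG_COLS:
            _dset(vg, col, getattr(state.network, col))
        _dset(vg, "inlets", state.network.inlets)
        _dset(vg, "outlets", state.network.outlets)
        vg.attrs["lattice_spacing"] = state.network.lattice_spacing
        vg.attrs["sprout_tips"] = json.dumps(state.network.sprout_tips,
                                             sort_keys=True)

        gg = f.create_group("fields")
        gg.attrs["origin"] = state.grid.origin
        gg.attrs["spacing"] = state.grid.spacing
        gg.attrs["shape"] = state.grid.shape
        for name in _GRID_FIELDS:
            _dset(gg, name, state.grid.fields[name])

        _dset(f, "events", np.bytes_(json.dumps(state.events)))
    return path


def read_snapshot(path):
    """Reconstruct a SimulationState; refuses unknown schema versions."""
    from .coupling import SimulationState

    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SnapshotError(
                f"snapshot schema version {version} != supported {SCHEMA_VERSION}")
        try:
            config = SimulationConfig.from_json(f.attrs["config"])
            pop = CellPopulation()
            cg = f["cells"]
            pop.position = cg["position"][()]
            for name, _ in _FIELDS:
                setattr(pop, name, cg[name][()])
            pop.next_id = int(cg.attrs["next_id"])
        except KeyError as exc:
            raise SnapshotError(f"corrupt snapshot: missing cell table ({exc})")
        try:
            vg = f["vessels"]
            net = VesselNetwork(vg["positions"][()],
                                float(vg.attrs["lattice_spacing"]))
            net.seg_nodes = vg["seg_nodes"][()]
            for col in _NODE_COLS + _SEG_COLS:
                setattr(net, col, vg[col][()])
            net.is_boundary = net.is_boundary.astype(bool)
            net.inside_tumour = net.inside_tumour.astype(bool)
            net.collapsed = net.collapsed.astype(bool)
            net.inlets = vg["inlets"][()]
            net.outlets = vg["outlets"][()]
            net.sprout_tips = json.loads(vg.attrs["sprout_tips"])
        except KeyError as exc:
            raise SnapshotError(f"corrupt snapshot: missing vessel table ({exc})")
        try:
            gg = f["fields"]
            grid = TissueGrid(np.asarray(gg.attrs["origin"]),
                              float(gg.attrs["spacing"]),
                              tuple(int(x) for x in gg.attrs["shape"]))
            for name in _GRID_FIELDS:
                grid.fields[name] = gg[name][()]
        except KeyError as exc:
            raise SnapshotError(f"corrupt snapshot: missing field table ({exc})")
        rng = np.random.default_rng(0)
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        events = json.loads(bytes(f["events"][()]).decode())
        state = SimulationState(
            time=float(f.attrs["time"]), cells=pop, network=net, grid=grid,
            rng=rng, config=config, step=int(f.attrs["step"]), events=events,
            remodeling_active=bool(f.attrs["remodeling_active"]))
    return state


def write_events(events, path) -> Path:
    """Append-style JSON-lines event log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
    return path


def cells_to_frame(pop: CellPopulation):
    import pandas as pd

    data = {"x": pop.position[:, 0], "y": pop.position[:, 1],
            "z": pop.position[:, 2]}
    for name, _ in _FIELDS:
        data[name] = getattr(pop, name)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# VTK legacy ASCII export
# ---------------------------------------------------------------------------

def _vtk_header(fh, title, dataset):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _write_scalars(fh, name, values, kind="float"):
    fh.write(f"SCALARS {name} {kind} 1\n")
    fh.write("LOOKUP_TABLE default\n")
    for v in values:
        fh.write(f"{v:.9g}\n" if kind == "float" else f"{int(v)}\n")


def export_network_vtk(net: VesselNetwork, path) -> Path:
    """Vessel network as VTK PolyData lines with per-segment attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _vtk_header(fh, "nichesim vessel network", "POLYDATA")
        fh.write(f"POINTS {net.n_nodes} float\n")
        for p in net.positions:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        m = net.n_segments
        fh.write(f"LINES {m} {3 * m}\n")
        for a, b in net.seg_nodes:
            fh.write(f"2 {a} {b}\n")
        fh.write(f"CELL_DATA {m}\n")
        _write_scalars(fh, "radius", net.radius)
        _write_scalars(fh, "flow", net.flow)
        _write_scalars(fh, "shear", net.wall_shear)
        _write_scalars(fh, "hematocrit", net.hematocrit)
        seg_po2 = (net.node_po2[net.seg_nodes[:, 0]]
                   + net.node_po2[net.seg_nodes[:, 1]]) * 0.5 if m else np.zeros(0)
        _write_scalars(fh, "po2", seg_po2)
        _write_scalars(fh, "vessel_class", net.vessel_class, kind="int")
    return path


def export_cells_vtk(pop: CellPopulation, path) -> Path:
    """Cells as a VTK point cloud carrying phase and radius."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(pop)
    with open(path, "w") as fh:
        _vtk_header(fh, "nichesim cells", "POLYDATA")
        fh.write(f"POINTS {n} float\n")
        for p in pop.position:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {n}\n")
        _write_scalars(fh, "radius", pop.radius)
        _write_scalars(fh, "phase", pop.phase, kind="int")
        _write_scalars(fh, "po2", pop.o2_in)
    return path


def export_grid_vtk(grid: TissueGrid, path, fields=("po2", "ph", "vegf")) -> Path:
    """Grid fields as VTK STRUCTURED_POINTS (ImageData-compatible)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        _vtk_header(fh, "nichesim tissue fields", "STRUCTURED_POINTS")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {grid.origin[0]:.6f} {grid.origin[1]:.6f} "
                 f"{grid.origin[2]:.6f}\n")
        fh.write(f"SPACING {grid.spacing:.6f} {grid.spacing:.6f} "
                 f"{grid.spacing:.6f}\n")
        fh.write(f"POINT_DATA {grid.n_nodes}\n")
        for name in fields:
            # VTK structured points expect x varying fastest
            _write_scalars(fh, name, grid.fields[name].transpose(2, 1, 0).ravel())
    return path


def export_vtk(state, prefix) -> list[Path]:
    """Write network, cells and fields next to each other; returns paths."""
    prefix = Path(prefix)
    return [
        export_network_vtk(state.network, prefix.with_name(prefix.name + "_vessels.vtk")),
        export_cells_vtk(state.cells, prefix.with_name(prefix.name + "_cells.vtk")),
        export_grid_vtk(state.grid, prefix.with_name(prefix.name + "_fields.vtk")),
    ]
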