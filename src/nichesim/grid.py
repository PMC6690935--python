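"""Cubic-lattice tissue grid and particle-mesh interpolation kernels.

Scalar fields (pO2, glucose, pH, lactate, VEGF, sinks/sources) live on the
nodes of a regular cubic grid.  Cells exchange with the grid through the
classic cloud-in-cell (trilinear) kernel: deposition spreads each cell's
rate over the 8 enclosing nodes and sampling is the adjoint interpolation,
so a deposit followed by a sample is exactly the trilinear self-weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIELD_NAMES = ("po2", "glucose", "ph", "lactate", "vegf", "o2_sink",
               "glucose_sink", "lactate_source", "vegf_source")


@dataclass
class TissueGrid:
    origin: np.ndarray            # μm, position of node (0,0,0)
    spacing: float                # μm
    shape: tuple[int, int, int]
    fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(n) for n in self.shape)
        for name in FIELD_NAMES:
            self.fields.setdefault(name, np.zeros(self.shape))
        self.fields["ph"][:] = np.where(self.fields["ph"] == 0.0, 7.4,
                                        self.fields["ph"])

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    @property
    def extent(self) -> np.ndarray:
        return self.origin + (np.asarray(self.shape) - 1) * self.spacing

    def node_coordinates(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def copy(self) -> "TissueGrid":
        return TissueGrid(self.origin.copy(), self.spacing, self.shape,
                          {k: v.copy() for k, v in self.fields.items()})

    def validate(self) -> None:
        for name, f in self.fields.items():
            if f.shape != self.shape:
                raise ValueError(f"field {name} has shape {f.shape} != {self.shape}")
            if not np.isfinite(f).all():
                raise ValueError(f"field {name} contains non-finite values")


def make_grid(origin, spacing: float, shape) -> TissueGrid:
    return TissueGrid(np.asarray(origin, float), float(spacing), tuple(shape))


def grid_covering(lo, hi, spacing: float, margin: float = 0.0) -> TissueGrid:
    """Smallest grid at the given spacing that covers [lo-margin, hi+margin]."""
    lo = np.asarray(lo, float) - margin
    hi = np.asarray(hi, float) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return make_grid(lo, spacing, shape)


# ---------------------------------------------------------------------------
# cloud-in-cell kernels
# ---------------------------------------------------------------------------

def _cic_stencil(grid: TissueGrid, points: np.ndarray):
    """Per-point 8-node flat indices and trilinear weights.

    Points outside the grid are clamped onto the nearest face; callers that
    care receive the clamped mask.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = (pts - grid.origin) / grid.spacing
    hi = np.asarray(grid.shape) - 1
    clamped = (rel < 0).any(axis=1) | (rel > hi).any(axis=1)
    rel = np.clip(rel, 0.0, hi - 1e-12)
    i0 = np.minimum(rel.astype(np.int64), hi - 1)
    frac = rel - i0
    nx, ny, nz = grid.shape
    wx = np.stack([1.0 - frac[:, 0], frac[:, 0]], axis=1)
    wy = np.stack([1.0 - frac[:, 1], frac[:, 1]], axis=1)
    wz = np.stack([1.0 - frac[:, 2], frac[:, 2]], axis=1)
    w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :])
    w = w.reshape(len(pts), 8)
    off = np.array([[dx, dy, dz] for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)])
    idx = ((i0[:, None, 0] + off[None, :, 0]) * ny
           + (i0[:, None, 1] + off[None, :, 1])) * nz \
        + (i0[:, None, 2] + off[None, :, 2])
    return idx, w, clamped


def deposit(grid: TissueGrid, field_name: str, points, rates) -> np.ndarray:
    """Cloud-in-cell deposit of per-point rates onto a grid field.

    The deposited total equals ``sum(rates)`` to round-off; the field is
    overwritten with *rates per node* (divide by the voxel volume for a
    density).  Returns the mask of points clamped into the domain.
    """
    f = grid.fields[field_name]
    f[:] = 0.0
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    idx, w, clamped = _cic_stencil(grid, pts)
    flat = np.zeros(grid.n_nodes)
    np.add.at(flat, idx.ravel(), (w * np.asarray(rates, float)[:, None]).ravel())
    f[:] = flat.reshape(grid.shape)
    return clamped


def sample(grid: TissueGrid, field_name: str, points) -> np.ndarray:
    """Trilinear interpolation of a field at arbitrary positions.

    Exact for fields linear in the coordinates; positions outside the grid
    are clamped to the nearest face.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 0:
        return np.zeros(0)
    idx, w, _ = _cic_stencil(grid, pts)
    flat = grid.fields[field_name].ravel()
    return (flat[idx] * w).sum(axis=1)


def sample_gradient(grid: TissueGrid, field_name: str, points) -> np.ndarray:
    """Central-difference gradient of a field, interpolated at positions."""
    gx, gy, gz = np.gradient(grid.fields[field_name], grid.spacing)
    out = np.empty((len(np.atleast_2d(points)), 3))
    for axis, g in enumerate((gx, gy, gz)):
        tmp = TissueGrid(grid.origin, grid.spacing, grid.shape, {"g": g})
        out[:, axis] = sample(tmp, "g", points)
    return out


def rasterize_segment(grid: TissueGrid, p0, p1, ds_target: float | None = None):
    """Distribute a segment's centreline over the voxels it crosses.

    Returns ``(flat_node_indices, lengths, midpoints)`` where lengths sum
    exactly to the segment length.  Sampling at ~half-voxel resolution and
    binning to the nearest node localizes each piece of the centreline,
    which is how vessels exchange substances with the tissue.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    ds = ds_target if ds_target is not None else grid.spacing / 2.0
    n = max(1, int(np.ceil(length / ds)))
    t = (np.arange(n) + 0.5) / n
    pts = p0 + t[:, None] * (p1 - p0)
    rel = np.rint((pts - grid.origin) / grid.spacing).astype(np.int64)
    rel = np.clip(rel, 0, np.asarray(grid.shape) - 1)
    nx, ny, nz = grid.shape
    flat = (rel[:, 0] * ny + rel[:, 1]) * nz + rel[:, 2]
    uniq, inv, counts = np.unique(flat, return_inverse=True, return_counts=True)
    seg_len = counts * (length / n)
    mids = np.zeros((len(uniq), 3))
    np.add.at(mids, inv, pts)
    mids /= counts[:, None]
    return uniq, seg_len, mids
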