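"""Niche analytics: the observables of the tumour microenvironment.

All statistics are pure functions of a snapshot: distance-to-vessel
histograms, per-distance-bin summaries of cell quantities (radius, pO2,
pH), cell-phase composition by distance, the centroid-to-surface distance
distribution (a sphericity probe), and line samples of tissue quantities
between two vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import grid as gridmod
from .cells import DEAD, G1M, G1P, G2, M_PHASE, S_PHASE, CellPopulation

#: phase grouping used for composition plots: early G1 pool, S, the mitotic
#: pool and dead cells.
PHASE_GROUPS = {
    "G1": (G1M, G1P),
    "S": (S_PHASE,),
    "G2M": (G2, M_PHASE),
    "dead": (DEAD,),
}

QUANTITY_GETTERS = {
    "radius": lambda pop: pop.radius,
    "po2": lambda pop: pop.o2_in,
    "ph": lambda pop: pop.env_ph,
}


@dataclass
class NicheStats:
    """Histogram-style result: bin edges, counts and per-bin summaries."""

    bin_edges: np.ndarray
    counts: np.ndarray
    stats: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    sparse: np.ndarray | None = None
    n_total: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        data = {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:],
                "count": self.counts}
        for qname, summ in self.stats.items():
            for sname, arr in summ.items():
                data[f"{qname}_{sname}"] = arr
        if self.sparse is not None:
            data["sparse"] = self.sparse
        return pd.DataFrame(data)


@dataclass
class LineSample:
    endpoints: tuple[np.ndarray, np.ndarray]
    points: np.ndarray             # (n,3)
    mean: np.ndarray
    std: np.ndarray
    from_field: np.ndarray         # True where no cell was in the sphere

    def to_frame(self) -> pd.DataFrame:
        s = np.linalg.norm(self.points - self.points[0], axis=1)
        return pd.DataFrame({"s": s, "mean": self.mean, "std": self.std,
                             "from_field": self.from_field})


def _edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    top = float(values.max()) if len(values) else 0.0
    n = max(1, int(np.floor(top / bin_width)) + 1)
    return bin_width * np.arange(n + 1)


def distance_histogram(distances, bin_width: float = 10.0) -> NicheStats:
    """Histogram of nearest-vessel distances with fixed-width bins from 0."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        return NicheStats(np.array([0.0, bin_width]), np.zeros(1, dtype=np.int64))
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    edges = _edges(d, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return NicheStats(edges, counts.astype(np.int64), n_total=len(d))


def binned_quantity_stats(cells: CellPopulation, distances, quantity: str,
                          bin_width: float = 10.0, min_per_bin: int = 3) -> NicheStats:
    """Median and quartiles of a cell quantity per distance bin.

    ``quantity`` is one of ``radius``, ``po2`` (intracellular pO2, mmHg) or
    ``ph`` (extracellular pH at the cell).  Bins with fewer than
    ``min_per_bin`` cells are flagged sparse and carry NaN summaries.
    """
    if quantity not in QUANTITY_GETTERS:
        raise ValueError(f"unknown quantity {quantity!r}; "
                         f"choose from {sorted(QUANTITY_GETTERS)}")
    d = np.asarray(distances, dtype=float)
    q = np.asarray(QUANTITY_GETTERS[quantity](cells), dtype=float)
    edges = _edges(d, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    nb = len(edges) - 1
    med = np.full(nb, np.nan)
    q1 = np.full(nb, np.nan)
    q3 = np.full(nb, np.nan)
    which = np.clip(np.digitize(d, edges) - 1, 0, nb - 1)
    for b in range(nb):
        vals = q[which == b]
        if len(vals) >= min_per_bin:
            q1[b], med[b], q3[b] = np.percentile(vals, [25, 50, 75])
    sparse = counts < min_per_bin
    return NicheStats(edges, counts.astype(np.int64),
                      stats={quantity: {"median": med, "q1": q1, "q3": q3}},
                      sparse=sparse, n_total=len(d))


def phase_fractions_by_distance(cells: CellPopulation, distances,
                                bin_width: float = 10.0,
                                alive_only: bool = False) -> NicheStats:
    """Per-bin fractions of the phase groups {G1, S, G2M, dead}.

    With ``alive_only`` dead cells are excluded from both numerator and
    denominator (the dead fraction is then identically zero).  Fractions
    sum to 1 in every occupied bin.
    """
    d = np.asarray(distances, dtype=float)
    phases = cells.phase
    include = np.ones(len(d), dtype=bool)
    if alive_only:
        include = phases != DEAD
    d_inc = d[include]
    edges = _edges(d if len(d) else np.zeros(1), bin_width)
    nb = len(edges) - 1
    counts, _ = np.histogram(d_inc, bins=edges)
    which = np.clip(np.digitize(d_inc, edges) - 1, 0, nb - 1)
    stats: dict[str, dict[str, np.ndarray]] = {}
    denom = np.maximum(counts, 1)
    for gname, codes in PHASE_GROUPS.items():
        member = np.isin(phases[include], codes)
        gcount = np.bincount(which[member], minlength=nb)
        frac = np.where(counts > 0, gcount / denom, np.nan)
        stats[gname] = {"fraction": frac}
    return NicheStats(edges, counts.astype(np.int64), stats=stats,
                      n_total=int(include.sum()))


def centroid_surface_distribution(cells: CellPopulation, surface_ids,
                                  bin_width: float = 30.0) -> NicheStats:
    """Distances from the tumour centroid to its surface cells.

    The interquartile range and skewness of the distribution are the
    sphericity indicators: a perfect spherical shell collapses into a
    single bin with zero skew.  Default bin width 30 μm.
    """
    ids = np.asarray(surface_ids, dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("surface set is empty")
    centroid = cells.position.mean(axis=0)
    r = np.linalg.norm(cells.position[ids] - centroid, axis=1)
    edges = _edges(r, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    q1, med, q3 = np.percentile(r, [25, 50, 75])
    mu, sd = r.mean(), r.std()
    skew = float(((r - mu) ** 3).mean() / sd ** 3) if sd > 0 else 0.0
    out = NicheStats(edges, counts.astype(np.int64), n_total=len(ids))
    out.stats["surface_distance"] = {
        "median": np.array([med]), "iqr": np.array([q3 - q1]),
        "skewness": np.array([skew])}
    return out


def line_sample(state, p0, p1, quantity: str = "po2", n_points: int = 30,
                sphere_radius: float = 10.0) -> LineSample:
    """Average a quantity over cells near points along a line.

    At each of ``n_points`` uniformly spaced positions between ``p0`` and
    ``p1``, the quantity (``po2``: intracellular pO2; ``ph``:
    extracellular pH) is averaged over cells whose centres fall within
    ``sphere_radius``; positions with no such cell fall back to the
    interpolated tissue field and are flagged.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if n_points < 2:
        raise ValueError("need at least two sample points")
    if np.allclose(p0, p1):
        raise ValueError("degenerate line: endpoints coincide")
    if quantity not in ("po2", "ph"):
        raise ValueError("quantity must be po2 or ph")
    t = np.linspace(0.0, 1.0, n_points)
    pts = p0 + t[:, None] * (p1 - p0)
    pop = state.cells
    mean = np.zeros(n_points)
    std = np.zeros(n_points)
    from_field = np.zeros(n_points, dtype=bool)
    values = pop.o2_in if quantity == "po2" else pop.env_ph
    tree = cKDTree(pop.position) if len(pop) else None
    field_name = "po2" if quantity == "po2" else "ph"
    fallback = gridmod.sample(state.grid, field_name, pts)
    for i in range(n_points):
        hits = tree.query_ball_point(pts[i], sphere_radius) if tree else []
        if hits:
            vals = values[hits]
            mean[i] = vals.mean()
            std[i] = vals.std()
        else:
            mean[i] = fallback[i]
            std[i] = 0.0
            from_field[i] = True
    return LineSample((p0, p1), pts, mean, std, from_field)
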