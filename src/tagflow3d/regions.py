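"""LV contour handling, sectorization and regional strain reporting.

The left ventricle is partitioned for regional analysis the standard way:
twelve circumferentially equal (30 degree) sectors counted from the
anterior RV insertion point, grouped pairwise into six anatomical regions
(anteroseptal, posteroseptal, posterior, posterolateral, anterolateral,
anterior), and three equal longitudinal levels (apical, mid, basal)
between the apical-most and basal-most contoured slices. Summaries are a
region x level table of mean +/- SD principal strains and a 22-ring x
12-sector bull's-eye map (apex at the inner ring, base at the outer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

from .core import DisplacementField

__all__ = [
    "Contour",
    "ContourSet",
    "REGION_NAMES",
    "LEVEL_NAMES",
    "SectorMap",
    "interpolate_contours",
    "myocardial_mask",
    "sectorize",
    "regional_strain_table",
    "bullseye",
    "circular_contours",
]

#: anatomical region of sector pairs (1,2)->AS, (3,4)->PS, ... in order
REGION_NAMES = ("AS", "PS", "PST", "PL", "AL", "ANT")
LEVEL_NAMES = ("apical", "mid", "basal")


@dataclass
class Contour:
    """A closed polygon on one slice at one phase, vertices in mm (x, y)."""

    slice_index: int
    phase_index: int
    role: str                       # "endo" | "epi"
    vertices: np.ndarray            # (n, 2), closed implicitly
    provenance: str = "given"       # "given" | "interpolated"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.role not in ("endo", "epi"):
            raise ValueError("role must be 'endo' or 'epi'")

    def resample(self, n: int) -> np.ndarray:
        """Arc-length uniform resampling to ``n`` vertices (closed)."""
        v = self.vertices
        closed = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        t = np.linspace(0.0, total, n, endpoint=False)
        return np.stack([np.interp(t, s, closed[:, 0]),
                         np.interp(t, s, closed[:, 1])], axis=1)


class ContourSet:
    """Endo/epi contours keyed by (slice, phase)."""

    def __init__(self, contours: Sequence[Contour] = ()) -> None:
        self._store: dict[tuple[int, int, str], Contour] = {}
        for c in contours:
            self.add(c)

    def add(self, c: Contour) -> None:
        self._store[(c.slice_index, c.phase_index, c.role)] = c

    def get(self, slice_index: int, phase_index: int, role: str) -> Contour:
        return self._store[(slice_index, phase_index, role)]

    def __contains__(self, key: tuple[int, int, str]) -> bool:
        return key in self._store

    def __iter__(self):
        return iter(self._store.values())

    def __len__(self) -> int:
        return len(self._store)

    def slices(self, phase_index: int, role: str) -> list[int]:
        return sorted(s for (s, p, r) in self._store if p == phase_index
                      and r == role)


def circular_contours(center_mm: tuple[float, float], endo_radius_mm: float,
                      epi_radius_mm: float, slice_indices: Sequence[int],
                      phase_index: int = 0, n_vertices: int = 64) -> ContourSet:
    """Concentric circular endo/epi contours (the phantom's analytic wall)."""
    th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cs = ContourSet()
    for s in slice_indices:
        for role, r in (("endo", endo_radius_mm), ("epi", epi_radius_mm)):
            verts = np.stack([center_mm[0] + r * np.cos(th),
                              center_mm[1] + r * np.sin(th)], axis=1)
            cs.add(Contour(s, phase_index, role, verts))
    return cs


# ---------------------------------------------------------------------------
# contour interpolation
# ---------------------------------------------------------------------------

def interpolate_contours(sparse: ContourSet, all_slices: Sequence[int],
                         all_phases: Sequence[int],
                         displacements: Sequence[DisplacementField] | None = None,
                         spacing: Sequence[float] | None = None,
                         n_vertices: int = 64) -> ContourSet:
    """Fill in contours on every slice and phase.

    Spatially, drawn contours (at the single drawn phase) are resampled
    to a fixed vertex count with arc-length parameterization and linearly
    interpolated between drawn slices (end slices are extrapolated by
    copying the nearest drawn contour). Temporally, contours are
    propagated to other phases by warping each vertex with the measured
    displacement field of that phase (``displacements[p]``, reference
    phase 0, voxel units; requires ``spacing`` to convert mm vertices to
    voxel coordinates). Without displacement fields the contours are
    copied across phases unchanged.
    """
    out = ContourSet()
    drawn_phases = sorted({c.phase_index for c in sparse})
    if not drawn_phases:
        raise ValueError("no contours given")
    p0 = drawn_phases[0]

    for role in ("endo", "epi"):
        drawn = sparse.slices(p0, role)
        if len(drawn) < 2:
            raise ValueError(
                f"need contours on >= 2 slices for spatial interpolation "
                f"({role}: {len(drawn)} given)")
        ref = {s: sparse.get(s, p0, role).resample(n_vertices) for s in drawn}
        for s in all_slices:
            if s in ref:
                verts = ref[s]
                prov = "given"
            elif s < drawn[0]:
                verts = ref[drawn[0]]
                prov = "interpolated"
            elif s > drawn[-1]:
                verts = ref[drawn[-1]]
                prov = "interpolated"
            else:
                hi = int(np.searchsorted(drawn, s))
                lo = hi - 1
                s0, s1 = drawn[lo], drawn[hi]
                w = (s - s0) / (s1 - s0)
                verts = (1 - w) * ref[s0] + w * ref[s1]
                prov = "interpolated"
            for p in all_phases:
                v = verts
                pr = prov if p == p0 else "interpolated"
                if displacements is not None and p != p0:
                    v = _warp_vertices(verts, s, displacements[p], spacing)
                out.add(Contour(s, p, role, v, pr))
    return out


def _warp_vertices(verts_mm: np.ndarray, slice_index: int,
                   U: DisplacementField, spacing: Sequence[float]) -> np.ndarray:
    if spacing is None:
        raise ValueError("spacing required to warp mm vertices")
    sx, sy, sz = spacing
    coords = [verts_mm[:, 0] / sx, verts_mm[:, 1] / sy,
              np.full(len(verts_mm), float(slice_index))]
    du = np.stack([ndimage.map_coordinates(U.U[..., a], coords, order=1,
                                           mode="nearest") for a in range(2)],
                  axis=1)
    return verts_mm + du * np.asarray([sx, sy])


# ---------------------------------------------------------------------------
# masking and sectorization
# ---------------------------------------------------------------------------

def myocardial_mask(contours: ContourSet, grid_shape: Sequence[int],
                    spacing: Sequence[float], phase_index: int = 0) -> np.ndarray:
    """Rasterize the wall: voxels inside epi and outside endo, per slice.

    Voxel centres are tested with the even-odd rule. Raises if an
    endocardial vertex falls outside its epicardial polygon; an empty
    wall (endo == epi) yields an empty mask.
    """
    nx, ny, nz = grid_shape
    sx, sy, _ = spacing
    mask = np.zeros((nx, ny, nz), dtype=bool)
    for s in contours.slices(phase_index, "epi"):
        if (s, phase_index, "endo") not in contours:
            continue
        epi = contours.get(s, phase_index, "epi").vertices / (sx, sy)
        endo = contours.get(s, phase_index, "endo").vertices / (sx, sy)
        epi_mask = polygon2mask((nx, ny), epi)
        endo_mask = polygon2mask((nx, ny), endo)
        if (endo_mask & ~epi_mask).any():
            raise ValueError(
                f"endocardial contour leaves the epicardium on slice {s}")
        mask[:, :, s] = epi_mask & ~endo_mask
    return mask


@dataclass
class SectorMap:
    """Per-voxel sector (1-12), anatomical region and longitudinal level.

    ``sector``, ``level`` are 0 outside the mask; ``region`` indexes
    ``REGION_NAMES`` (-1 outside), ``level`` indexes ``LEVEL_NAMES``
    (1=apical .. 3=basal stored as 1-based, matching ``sector``).
    """

    sector: np.ndarray              # int, 1..12, 0 outside
    region: np.ndarray              # int, 0..5 index into REGION_NAMES, -1 outside
    level: np.ndarray               # int, 1..3, 0 outside
    mask: np.ndarray
    centers: dict = field(default_factory=dict)  # slice -> (cx, cy) voxel


def sectorize(mask: np.ndarray, rv_insertion_point: Sequence[float],
              n_sectors: int = 12, clockwise: bool = False) -> SectorMap:
    """Divide the masked wall into circumferential sectors and levels.

    Sector 1 starts at the ray from each slice's endocardial centroid
    through the anterior RV insertion point (given in voxel coordinates
    ``(x, y)`` or ``(x, y, z)``); successive sectors proceed
    counterclockwise viewed from the apex (set ``clockwise`` to flip).
    A voxel exactly on a sector boundary takes the lower sector index.
    Sectors map pairwise onto the six anatomical regions in the order
    AS, PS, PST, PL, AL, ANT. Slices between the apical-most and
    basal-most masked slice are split into three equal longitudinal
    groups (apical, mid, basal — the slice axis is ordered apex
    -> base).
    """
    mask = np.asarray(mask, dtype=bool)
    if rv_insertion_point is None:
        raise ValueError("an RV insertion point is required")
    if n_sectors % len(REGION_NAMES):
        raise ValueError("n_sectors must be a multiple of 6")
    rv = np.asarray(rv_insertion_point, dtype=float)
    nx, ny, nz = mask.shape

    sector = np.zeros(mask.shape, dtype=np.int16)
    region = np.full(mask.shape, -1, dtype=np.int16)
    level = np.zeros(mask.shape, dtype=np.int16)
    centers: dict[int, tuple[float, float]] = {}

    zs = np.where(mask.any(axis=(0, 1)))[0]
    if zs.size == 0:
        return SectorMap(sector, region, level, mask, centers)
    bounds = np.linspace(zs[0], zs[-1] + 1, 4)

    xs = np.arange(nx)
    ys = np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    width = 360.0 / n_sectors
    per_region = n_sectors // len(REGION_NAMES)

    for z in zs:
        sl = mask[:, :, z]
        if not sl.any():
            continue
        # centroid of the cavity boundary ~ centroid of the wall ring
        cx, cy = X[sl].mean(), Y[sl].mean()
        centers[int(z)] = (float(cx), float(cy))
        ref = np.arctan2(rv[1] - cy, rv[0] - cx)
        ang = np.arctan2(Y - cy, X - cx) - ref
        if clockwise:
            ang = -ang
        ang_deg = np.mod(np.degrees(ang), 360.0)
        # boundary ties go to the lower sector; the reference ray itself
        # is the start of sector 1
        sec = np.ceil(ang_deg / width).astype(np.int16)
        sec[ang_deg == 0.0] = 1
        np.clip(sec, 1, n_sectors, out=sec)
        sector[:, :, z][sl] = sec[sl]
        region[:, :, z][sl] = (sec[sl] - 1) // per_region
        lev = int(np.searchsorted(bounds, z, side="right"))
        level[:, :, z][sl] = min(max(lev, 1), 3)

    return SectorMap(sector, region, level, mask, centers)


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------

def regional_strain_table(principal, sectors: SectorMap | Sequence[SectorMap]
                          ) -> pd.DataFrame:
    """Region x level table of mean +/- SD principal strains.

    ``principal`` is a :class:`~tagflow3d.strain.PrincipalStrainField`
    (or a sequence of them for multiple subjects, paired with a sequence
    of sector maps). For a single subject the statistics run over the
    member voxels of each cell; for multiple subjects each subject
    contributes its cell mean and the table reports the across-subject
    mean and sample SD. Cells with no member voxels are reported as NaN.

    The output has a (quantity, statistic) row MultiIndex with quantities
    ``eps1``/``eps3`` and statistics ``mean``/``sd`` per level, and one
    column per anatomical region — 18 mean cells per quantity.
    """
    singles = not isinstance(principal, (list, tuple))
    ps_list = [principal] if singles else list(principal)
    sm_list = [sectors] if singles else list(sectors)
    if len(ps_list) != len(sm_list):
        raise ValueError("one sector map per subject is required")

    per_subject = []
    for ps, sm in zip(ps_list, sm_list):
        cells = {}
        for qname, vals in (("eps1", ps.eps1), ("eps3", ps.eps3)):
            for li, lname in enumerate(LEVEL_NAMES, start=1):
                for ri, rname in enumerate(REGION_NAMES):
                    sel = sm.mask & (sm.level == li) & (sm.region == ri)
                    if ps.mask is not None:
                        sel = sel & ps.mask
                    v = vals[sel]
                    cells[(qname, lname, rname)] = (
                        (float(v.mean()), float(v.std(ddof=0)), v.size)
                        if v.size else (np.nan, np.nan, 0))
        per_subject.append(cells)

    rows = []
    index = []
    for qname in ("eps1", "eps3"):
        for lname in LEVEL_NAMES:
            means, sds = [], []
            for rname in REGION_NAMES:
                if len(per_subject) == 1:
                    m, sd, n = per_subject[0][(qname, lname, rname)]
                else:
                    subj = np.array([s[(qname, lname, rname)][0]
                                     for s in per_subject])
                    subj = subj[~np.isnan(subj)]
                    m = float(subj.mean()) if subj.size else np.nan
                    sd = float(subj.std(ddof=1)) if subj.size > 1 else np.nan
                means.append(m)
                sds.append(sd)
            rows.append(means)
            index.append((qname, lname, "mean"))
            rows.append(sds)
            index.append((qname, lname, "sd"))

    return pd.DataFrame(rows,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["quantity", "level", "stat"]),
                        columns=list(REGION_NAMES))


def bullseye(values: np.ndarray, sectors: SectorMap,
             n_rings: int = 22) -> np.ndarray:
    """Polar (ring x sector) summary map of a per-voxel field.

    Rings are equal longitudinal bins from apex (ring 0, innermost) to
    base (outermost); each cell holds the mean of the member voxels of
    that (ring, sector), NaN where a cell is empty. Default 22 rings x
    12 sectors.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = sectors.mask
    n_sectors = int(sectors.sector.max()) if mask.any() else 12
    n_sectors = max(n_sectors, 1)
    out = np.full((n_rings, n_sectors), np.nan)
    zs = np.where(mask.any(axis=(0, 1)))[0]
    if zs.size == 0:
        return out
    edges = np.linspace(zs[0], zs[-1] + 1, n_rings + 1)

    Z = np.broadcast_to(np.arange(mask.shape[2])[None, None, :], mask.shape)
    ring = np.clip(np.searchsorted(edges, Z[mask], side="right") - 1,
                   0, n_rings - 1)
    sec = sectors.sector[mask] - 1
    vals = values[mask]
    ok = ~np.isnan(vals)
    sums = np.zeros((n_rings, n_sectors))
    counts = np.zeros((n_rings, n_sectors))
    np.add.at(sums, (ring[ok], sec[ok]), vals[ok])
    np.add.at(counts, (ring[ok], sec[ok]), 1)
    nonempty = counts > 0
    out[nonempty] = sums[nonempty] / counts[nonempty]
    return out


def bullseye_plot(matrix: np.ndarray, ax=None, cmap: str = "RdBu_r",
                  title: str | None = None):
    """Render a bull's-eye matrix on a polar axis (optional helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n_rings, n_sectors = matrix.shape
    theta = np.linspace(0, 2 * np.pi, n_sectors + 1)
    r = np.linspace(0, 1, n_rings + 1)
    T, R = np.meshgrid(theta, r)
    pcm = ax.pcolormesh(T, R, matrix, cmap=cmap)
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    ax.figure.colorbar(pcm, ax=ax, shrink=0.8)
    return ax
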