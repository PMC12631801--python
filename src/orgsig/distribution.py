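"""Subcellular distribution profiling: concentric XY rings, angular wedges, Z bins.

The XY axis describes the spread of an object from the nucleus to the cell
membrane.  The cell mask is projected to a 2D footprint; every footprint
pixel gets a normalized radial coordinate

    d = D_nuc / (D_nuc + D_edge)  ∈ [0, 1]

where ``D_nuc`` is the Euclidean distance (physical XY units) to the nucleus
footprint and ``D_edge`` the distance to the background outside the cell
footprint — the proportional-ring construction used by CellProfiler-style
radial distribution modules.  The footprint is divided into ``n_rings``
equal ``d`` intervals; ring 1 additionally contains the nucleus footprint
(and hence the volumes above and below the nucleus).  Each ring is further
cut into ``n_wedges`` equal angular sectors about the nucleus centroid.

The Z axis splits the planes between the lowest and highest plane containing
cell mask into ``n_bins`` contiguous bins whose sizes differ by at most one
plane (extra planes go to the bottom bins).

Object volume per region is normalized to total object volume and region
size:  ``n(r) = (raw(r)/total) / (region cell volume(r)/cell volume)`` — a
density enrichment that is identically 1 for an object occupying the cell
uniformly (and for the cell mask itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CellScaffold, LabelStack, SemanticMask, ValidationError


def _grid_of(obj: SemanticMask | LabelStack | np.ndarray) -> np.ndarray:
    if isinstance(obj, (SemanticMask, LabelStack)):
        return obj.grid > 0
    return np.asarray(obj) > 0


@dataclass(frozen=True)
class XYRegions:
    """Ring and wedge maps over the cell footprint plus per-region cell volumes."""

    ring_map: np.ndarray  # 2D int, 0 outside footprint, 1..n_rings inside
    wedge_map: np.ndarray  # 2D int, 0 outside footprint, 1..n_wedges inside
    column_counts: np.ndarray  # 2D int, cell voxels per XY column
    ring_cell_volume: np.ndarray  # (n_rings,), μm³
    cell_volume: float  # μm³
    voxel_volume: float
    n_rings: int
    n_wedges: int

    @property
    def axis(self) -> str:
        return "XY"


@dataclass(frozen=True)
class ZRegions:
    """Plane→bin assignment plus per-bin cell volumes."""

    plane_bin: np.ndarray  # (n_planes_total,), 0 for planes without cell, else 1..n_bins
    bin_cell_volume: np.ndarray  # (n_bins,), μm³
    cell_volume: float
    voxel_volume: float
    n_bins: int

    @property
    def axis(self) -> str:
        return "Z"


@dataclass(frozen=True)
class RegionProfile:
    """Raw and normalized object volume across the regions of one axis."""

    name: str
    axis: str  # "XY" or "Z"
    raw: np.ndarray  # μm³ per region
    normalized: np.ndarray  # unitless density enrichment
    total: float  # μm³

    @property
    def empty(self) -> bool:
        return self.total == 0.0


def radial_coordinate(
    footprint: np.ndarray, nuc_fp: np.ndarray, sy: float, sx: float
) -> np.ndarray:
    """Normalized radial coordinate d ∈ [0, 1] over a 2D cell footprint.

    0 on the nucleus footprint, approaching 1 at the cell edge; computed from
    Euclidean distance transforms in physical XY units.
    """
    sampling = (sy, sx)
    d_nuc = ndimage.distance_transform_edt(~nuc_fp, sampling=sampling)
    d_edge = ndimage.distance_transform_edt(footprint, sampling=sampling)
    denom = d_nuc + d_edge
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, d_nuc / denom, 0.0)


def build_xy_regions(
    scaffold: CellScaffold, n_rings: int = 5, n_wedges: int = 8
) -> XYRegions:
    """Partition the cell footprint into concentric rings and angular wedges."""
    if n_rings < 1 or n_wedges < 1:
        raise ValidationError("n_rings and n_wedges must be ≥ 1")
    sp = scaffold.spacing
    footprint = scaffold.cell.grid.any(axis=0)
    nuc_fp = scaffold.nucleus.grid.any(axis=0)
    if not nuc_fp.any():
        raise ValidationError("empty-mask: nucleus footprint is empty")

    d = radial_coordinate(footprint, nuc_fp, sp.sy, sp.sx)

    ring = np.zeros(footprint.shape, dtype=np.int32)
    ring[footprint] = np.clip(
        (d[footprint] * n_rings).astype(np.int64) + 1, 1, n_rings
    )
    ring[nuc_fp] = 1  # the central ring contains the nucleus

    # wedges: equal angular sectors about the nucleus centroid, angle 0 = +x
    yy, xx = np.nonzero(nuc_fp)
    cy = float(yy.mean()) * sp.sy
    cx = float(xx.mean()) * sp.sx
    gy, gx = np.mgrid[0 : footprint.shape[0], 0 : footprint.shape[1]]
    ang = np.arctan2(gy * sp.sy - cy, gx * sp.sx - cx) % (2 * math.pi)
    wedge = np.zeros(footprint.shape, dtype=np.int32)
    wedge[footprint] = np.minimum(
        (ang[footprint] / (2 * math.pi / n_wedges)).astype(np.int64) + 1, n_wedges
    )

    col = scaffold.cell.grid.sum(axis=0).astype(np.int64)
    vv = sp.voxel_volume
    ring_vol = np.array(
        [col[ring == r].sum() * vv for r in range(1, n_rings + 1)]
    )
    return XYRegions(
        ring_map=ring,
        wedge_map=wedge,
        column_counts=col,
        ring_cell_volume=ring_vol,
        cell_volume=float(col.sum() * vv),
        voxel_volume=vv,
        n_rings=n_rings,
        n_wedges=n_wedges,
    )


def build_z_regions(scaffold: CellScaffold, n_bins: int = 10) -> ZRegions:
    """Split the cell's occupied plane range into contiguous, near-equal Z bins."""
    if n_bins < 1:
        raise ValidationError("n_bins must be ≥ 1")
    cell = scaffold.cell.grid
    occupied = cell.any(axis=(1, 2))
    planes = np.flatnonzero(occupied)
    z_min, z_max = int(planes[0]), int(planes[-1])
    n_planes = z_max - z_min + 1

    base, extra = divmod(n_planes, n_bins)
    plane_bin = np.zeros(cell.shape[0], dtype=np.int32)
    z = z_min
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        plane_bin[z : z + size] = b
        z += size

    vv = scaffold.spacing.voxel_volume
    per_plane = cell.sum(axis=(1, 2)).astype(np.int64)
    bin_vol = np.array(
        [per_plane[plane_bin == b].sum() * vv for b in range(1, n_bins + 1)]
    )
    return ZRegions(
        plane_bin=plane_bin,
        bin_cell_volume=bin_vol,
        cell_volume=float(per_plane.sum() * vv),
        voxel_volume=vv,
        n_bins=n_bins,
    )


def _normalize(raw: np.ndarray, total: float, region_vol: np.ndarray, cell_vol: float) -> np.ndarray:
    out = np.zeros_like(raw, dtype=float)
    if total > 0:
        ok = region_vol > 0
        out[ok] = (raw[ok] / total) / (region_vol[ok] / cell_vol)
    return out


def profile(
    obj: SemanticMask | LabelStack | np.ndarray,
    regions: XYRegions | ZRegions,
    name: str = "",
) -> RegionProfile:
    """Raw and normalized object volume per XY ring or Z bin.

    Object voxels are assigned to the ring of their (Y, X) column or the bin
    of their Z plane; the profile is flagged empty when the object has no
    voxels.
    """
    grid = _grid_of(obj)
    vv = regions.voxel_volume
    if isinstance(regions, XYRegions):
        zz, yy, xx = np.nonzero(grid)
        labels = regions.ring_map[yy, xx]
        n = regions.n_rings
        region_vol = regions.ring_cell_volume
    else:
        zz = np.nonzero(grid)[0]
        labels = regions.plane_bin[zz]
        n = regions.n_bins
        region_vol = regions.bin_cell_volume
    raw = np.bincount(labels, minlength=n + 1)[1:] * vv
    total = float(raw.sum())
    return RegionProfile(
        name=name,
        axis=regions.axis,
        raw=raw,
        normalized=_normalize(raw, total, region_vol, regions.cell_volume),
        total=total,
    )


def profile_wedges(
    obj: SemanticMask | LabelStack | np.ndarray, regions: XYRegions
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(ring, wedge) raw and normalized object volume.

    Returns ``(raw, normalized, cell_volume)`` arrays of shape
    ``(n_rings, n_wedges)``; normalization uses the same density-enrichment
    formula as :func:`profile` with the wedge cell volumes as region sizes.
    """
    grid = _grid_of(obj)
    nr, nw = regions.n_rings, regions.n_wedges
    zz, yy, xx = np.nonzero(grid)
    rings = regions.ring_map[yy, xx]
    wedges = regions.wedge_map[yy, xx]
    vv = regions.voxel_volume
    inside = rings > 0
    flat = (rings[inside] - 1) * nw + (wedges[inside] - 1)
    raw = (np.bincount(flat, minlength=nr * nw) * vv).reshape(nr, nw)

    col = regions.column_counts
    cell_rw = np.zeros((nr, nw))
    rm, wm = regions.ring_map, regions.wedge_map
    fp = rm > 0
    flat_fp = (rm[fp] - 1) * nw + (wm[fp] - 1)
    cell_rw = (
        np.bincount(flat_fp, weights=col[fp], minlength=nr * nw) * vv
    ).reshape(nr, nw)

    total = float(raw.sum())
    norm = _normalize(raw.ravel(), total, cell_rw.ravel(), regions.cell_volume).reshape(nr, nw)
    return raw, norm, cell_rw


@dataclass(frozen=True)
class DistributionSummary:
    """Mode / SD along one axis, with the median wedge CV for the XY axis.

    * mode — region index with the highest normalized volume (ties → the
      smallest index);
    * SD — spread of the object across region indices: the standard
      deviation of the region index weighted by normalized volume;
    * median CV — per ring, the coefficient of variation (SD/mean, sample
      SD) of the normalized volumes of the eight wedges that contain cell
      volume; summarized as the median over rings with non-zero object
      volume.
    """

    name: str
    axis: str
    mode: float
    sd: float
    median_cv: float = float("nan")

    def as_dict(self, include_cv: bool = True) -> dict[str, float]:
        out = {
            f"{self.name}_{self.axis}_mode": self.mode,
            f"{self.name}_{self.axis}_SD": self.sd,
        }
        if include_cv and self.axis == "XY":
            out[f"{self.name}_XY_median_CV"] = self.median_cv
        return out


def _mode_sd(normalized: np.ndarray) -> tuple[float, float]:
    weights = normalized / normalized.sum()
    idx = np.arange(1, len(normalized) + 1, dtype=float)
    mode = float(np.argmax(normalized) + 1)
    mean = float((weights * idx).sum())
    sd = math.sqrt(float((weights * (idx - mean) ** 2).sum()))
    return mode, sd


def summarize_distribution(
    prof: RegionProfile,
    wedge_norm: np.ndarray | None = None,
    wedge_raw: np.ndarray | None = None,
    wedge_cell_volume: np.ndarray | None = None,
) -> DistributionSummary:
    """Histogram summary of a region profile; all fields NaN for an empty profile."""
    nan = float("nan")
    if prof.empty or prof.normalized.sum() == 0:
        return DistributionSummary(prof.name, prof.axis, nan, nan, nan)
    mode, sd = _mode_sd(prof.normalized)
    median_cv = nan
    if wedge_norm is not None:
        cvs = []
        for r in range(wedge_norm.shape[0]):
            ring_raw = wedge_raw[r] if wedge_raw is not None else wedge_norm[r]
            if ring_raw.sum() <= 0:
                continue  # rings without object volume are excluded
            if wedge_cell_volume is not None:
                vals = wedge_norm[r][wedge_cell_volume[r] > 0]
            else:
                vals = wedge_norm[r]
            if len(vals) < 2:
                continue
            mean = vals.mean()
            if mean > 0:
                cvs.append(float(vals.std(ddof=1) / mean))
        if cvs:
            median_cv = float(np.median(cvs))
    return DistributionSummary(prof.name, prof.axis, mode, sd, median_cv)


def distribution_metrics(
    name: str,
    obj: SemanticMask | LabelStack | np.ndarray,
    xy: XYRegions,
    z: ZRegions,
    include_cv: bool = True,
) -> dict[str, float]:
    """XY mode/SD/median-CV and Z mode/SD for one object, keyed ``<name>_<axis>_<stat>``."""
    xy_prof = profile(obj, xy, name=name)
    raw, norm, cell_rw = profile_wedges(obj, xy)
    xy_sum = summarize_distribution(xy_prof, norm, raw, cell_rw)
    z_sum = summarize_distribution(profile(obj, z, name=name))
    out = xy_sum.as_dict(include_cv=include_cv)
    out.update(z_sum.as_dict())
    return out


__all__ = [
    "radial_coordinate",
    "XYRegions",
    "ZRegions",
    "RegionProfile",
    "DistributionSummary",
    "build_xy_regions",
    "build_z_regions",
    "profile",
    "profile_wedges",
    "summarize_distribution",
    "distribution_metrics",
]
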