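"""Per-object 3D morphometrics in physical units and per-cell summaries.

The metric suite mirrors standard 3D regionprops measurements — volume,
surface area, surface-area-to-volume ratio, equivalent diameter, extent,
Euler number, solidity, major axis length — reported in real-world units
(μm, μm², μm³) rather than voxels.  Conventions:

* surface area is estimated from a triangulated isosurface (marching cubes
  at level 0.5 on the binary object padded by one background voxel, with the
  physical voxel spacing), since counting exposed voxel faces overestimates
  the area of smooth bodies by roughly 1.5×;
* the Euler number is computed on the voxel (cubical) complex with
  26-connectivity foreground, the same topology used for instancing;
* extent and solidity are volume ratios (to the axis-aligned bounding box
  and to the convex hull respectively); both are invariant under the
  per-axis scaling that maps voxel to physical coordinates, so they are
  computed on the voxel grid;
* the major axis length is the ellipsoid-equivalent axis
  ``4·sqrt(λ_max)`` of the object's second central moment matrix computed in
  physical coordinates, so anisotropic spacing enters before the
  eigendecomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay
from skimage import measure as skmeasure

from .core import CellScaffold, LabelStack, ValidationError, VoxelSpacing
from .instancing import as_single_object

#: per-object shape metrics that are summarized per cell by their median
SHAPE_METRICS = (
    "SA_to_volume_ratio",
    "equivalent_diameter",
    "extent",
    "euler_number",
    "solidity",
    "axis_major_length",
)


@dataclass(frozen=True)
class ObjectRecord:
    """Morphology of one segmented object, physical units."""

    label: int
    volume: float  # μm³
    surface_area: float  # μm²
    SA_to_volume_ratio: float  # μm⁻¹
    equivalent_diameter: float  # μm
    extent: float  # ∈ (0, 1]
    euler_number: int
    solidity: float  # ∈ (0, 1]
    axis_major_length: float  # μm
    centroid: tuple[float, float, float]  # (z, y, x), μm
    bbox: tuple[int, int, int, int, int, int]  # voxel index ranges
    intensity: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # intensity: channel -> (min, mean, max)


def _surface_area(image: np.ndarray, spacing: VoxelSpacing) -> float:
    """Triangulated-isosurface area of a binary object, μm².

    The padded mask is lightly smoothed (1-voxel Gaussian) before meshing so
    the staircase artifacts of the voxel surface do not inflate the area of
    smooth bodies; objects too thin to survive the smoothing are meshed from
    the raw mask instead.
    """
    padded = np.pad(image, 4).astype(np.float32)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    level = 0.5
    if smoothed.max() <= level:
        smoothed = padded
    verts, faces, _, _ = skmeasure.marching_cubes(
        smoothed, level=level, spacing=spacing.as_tuple()
    )
    return float(skmeasure.mesh_surface_area(verts, faces))


_CORNERS = np.array(
    [(a, b, c) for a in (-0.5, 0.5) for b in (-0.5, 0.5) for c in (-0.5, 0.5)]
)


def _voxel_solidity(image: np.ndarray) -> float:
    """Volume / convex-hull volume on the voxel grid.

    The hull is taken over the centers of the foreground voxels and its
    volume counted as the voxels whose centers fall inside (boundary
    inclusive), so a digitized convex body has solidity exactly 1.  Flat or
    collinear objects, whose center cloud is rank-deficient, fall back to a
    hull over voxel corner points.  The ratio is invariant under per-axis
    scaling, so anisotropic spacing does not enter.
    """
    nvox = int(image.sum())
    if nvox == 1:
        return 1.0
    # hull vertices can only come from boundary voxels
    boundary = image & ~ndimage.binary_erosion(image)
    pts = np.argwhere(boundary).astype(float)
    try:
        hull = ConvexHull(pts)
        tri = Delaunay(pts[hull.vertices])
    except Exception:  # rank-deficient point cloud (flat/collinear object)
        corners = (pts[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 3)
        hull = ConvexHull(corners)
        tri = Delaunay(corners[hull.vertices])
    centers = np.indices(image.shape).reshape(3, -1).T.astype(float)
    inside = tri.find_simplex(centers) >= 0
    return nvox / float(inside.sum())


def _axis_major_length(coords_phys: np.ndarray) -> float:
    centered = coords_phys - coords_phys.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    lam = float(np.linalg.eigvalsh(cov)[-1])
    return 4.0 * math.sqrt(max(lam, 0.0))


def measure_objects(
    labels: LabelStack,
    intensity_channels: dict[str, np.ndarray] | None = None,
) -> list[ObjectRecord]:
    """Measure every labeled object; returns one record per label, in label order.

    When ``intensity_channels`` is given, per-channel min/mean/max intensity
    over the object's voxels is attached to each record.
    """
    spacing = labels.spacing
    vv = spacing.voxel_volume
    records: list[ObjectRecord] = []
    chan_names = list(intensity_channels) if intensity_channels else []
    for region in skmeasure.regionprops(labels.grid):
        nvox = int(region.area)
        volume = nvox * vv
        eq_diam = (6.0 * volume / math.pi) ** (1.0 / 3.0)
        sa = _surface_area(region.image, spacing)
        coords_phys = region.coords * np.array(spacing.as_tuple())
        centroid = tuple(float(c) for c in coords_phys.mean(axis=0))
        intensity: dict[str, tuple[float, float, float]] = {}
        if chan_names:
            zmin, ymin, xmin, zmax, ymax, xmax = region.bbox
            sel = region.image
            for name in chan_names:
                vals = intensity_channels[name][zmin:zmax, ymin:ymax, xmin:xmax][sel]
                intensity[name] = (float(vals.min()), float(vals.mean()), float(vals.max()))
        records.append(
            ObjectRecord(
                label=int(region.label),
                volume=volume,
                surface_area=sa,
                SA_to_volume_ratio=sa / volume,
                equivalent_diameter=eq_diam,
                extent=float(region.extent),
                euler_number=int(region.euler_number),
                solidity=_voxel_solidity(region.image),
                axis_major_length=_axis_major_length(coords_phys),
                centroid=centroid,  # type: ignore[arg-type]
                bbox=tuple(int(b) for b in region.bbox),  # type: ignore[arg-type]
                intensity=intensity,
            )
        )
    return records


@dataclass(frozen=True)
class OrganelleSummary:
    """Per-cell summary of one organelle's object population.

    Medians summarize each shape metric across objects; the SD of object
    volumes uses the sample (n−1) denominator and is NaN for fewer than two
    objects.  An absent organelle yields count 0, total volume 0 and NaN for
    every median.
    """

    name: str
    count: int
    total_volume: float
    volume_fraction: float
    median_volume: float
    SD_volumes: float
    median_SA_to_volume_ratio: float
    median_equivalent_diameter: float
    median_extent: float
    median_euler_number: float
    median_solidity: float
    median_axis_major_length: float

    def as_dict(self) -> dict[str, float]:
        prefix = self.name
        return {
            f"{prefix}_volume_fraction": self.volume_fraction,
            f"{prefix}_total_volume": self.total_volume,
            f"{prefix}_count": float(self.count),
            f"{prefix}_median_volume": self.median_volume,
            f"{prefix}_SD_volumes": self.SD_volumes,
            f"{prefix}_median_SA_to_volume_ratio": self.median_SA_to_volume_ratio,
            f"{prefix}_median_equivalent_diameter": self.median_equivalent_diameter,
            f"{prefix}_median_extent": self.median_extent,
            f"{prefix}_median_euler_number": self.median_euler_number,
            f"{prefix}_median_solidity": self.median_solidity,
            f"{prefix}_median_axis_major_length": self.median_axis_major_length,
        }


def summarize_organelle(
    name: str, records: list[ObjectRecord], cell_volume: float
) -> OrganelleSummary:
    """Summarize an object population per cell: amount, size and shape."""
    if cell_volume <= 0:
        raise ValidationError(f"cell volume must be positive, got {cell_volume}")
    if not records:
        nan = float("nan")
        return OrganelleSummary(name, 0, 0.0, 0.0, nan, nan, nan, nan, nan, nan, nan, nan)
    volumes = np.array([r.volume for r in records])
    total = float(volumes.sum())
    sd = float(volumes.std(ddof=1)) if len(volumes) > 1 else float("nan")

    def med(attr: str) -> float:
        return float(np.median([getattr(r, attr) for r in records]))

    return OrganelleSummary(
        name=name,
        count=len(records),
        total_volume=total,
        volume_fraction=total / cell_volume,
        median_volume=float(np.median(volumes)),
        SD_volumes=sd,
        median_SA_to_volume_ratio=med("SA_to_volume_ratio"),
        median_equivalent_diameter=med("equivalent_diameter"),
        median_extent=med("extent"),
        median_euler_number=med("euler_number"),
        median_solidity=med("solidity"),
        median_axis_major_length=med("axis_major_length"),
    )


def measure_scaffold(
    scaffold: CellScaffold,
    intensity_channels: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Morphology of the cell and nucleus masks, each as a single object.

    Returns ``cell_*`` and ``nuc_*`` metrics plus the nucleus area fraction
    (nucleus volume / cell volume).  Intensity statistics, when channels are
    given, are attached to the cell mask as ``cell_<channel>_{min,mean,max}_intensity``.
    """
    out: dict[str, float] = {}
    for prefix, mask in (("cell", scaffold.cell), ("nuc", scaffold.nucleus)):
        rec = measure_objects(as_single_object(mask, prefix),
                              intensity_channels if prefix == "cell" else None)[0]
        out[f"{prefix}_volume"] = rec.volume
        out[f"{prefix}_surface_area"] = rec.surface_area
        out[f"{prefix}_SA_to_volume_ratio"] = rec.SA_to_volume_ratio
        out[f"{prefix}_equivalent_diameter"] = rec.equivalent_diameter
        out[f"{prefix}_extent"] = rec.extent
        out[f"{prefix}_euler_number"] = float(rec.euler_number)
        out[f"{prefix}_solidity"] = rec.solidity
        out[f"{prefix}_axis_major_length"] = rec.axis_major_length
        for chan, (imin, imean, imax) in rec.intensity.items():
            out[f"{prefix}_{chan}_min_intensity"] = imin
            out[f"{prefix}_{chan}_mean_intensity"] = imean
            out[f"{prefix}_{chan}_max_intensity"] = imax
    out["nuc_area_fraction"] = out["nuc_volume"] / out["cell_volume"]
    return out


__all__ = [
    "SHAPE_METRICS",
    "ObjectRecord",
    "OrganelleSummary",
    "measure_objects",
    "summarize_organelle",
    "measure_scaffold",
]
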