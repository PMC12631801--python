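"""Shared domain types and validation for the organelle-signature pipeline.

All image arrays are indexed ``(Z, Y, X)`` — plane, row, column — matching the
microscopy stack convention, and carry a physical :class:`VoxelSpacing` in the
same axis order.  Coordinates are 0-based voxel indices; the physical position
of a voxel is its index times the spacing (voxel centers).  All derived
measurements are reported in real-world units (μm, μm², μm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Canonical organelle channel names: endoplasmic reticulum, lysosomes,
#: mitochondria, peroxisomes, Golgi, lipid droplets.
ORGANELLES = ("ER", "LS", "MT", "PO", "GL", "LD")


class ValidationError(ValueError):
    """Raised when a cell image violates a structural invariant."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel in μm, ordered (z, y, x)."""

    sz: float
    sy: float
    sx: float

    def __post_init__(self) -> None:
        if not all(s > 0 for s in (self.sz, self.sy, self.sx)):
            raise ValidationError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, μm³."""
        return self.sz * self.sy * self.sx

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sz, self.sy, self.sx)


@dataclass(frozen=True)
class SemanticMask:
    """Binary foreground mask on a 3D (Z, Y, X) grid."""

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"mask must be 3D (Z, Y, X), got ndim={grid.ndim}")
        object.__setattr__(self, "grid", grid.astype(bool, copy=False))

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume(self) -> float:
        """Physical volume: voxel count × voxel volume, μm³."""
        return self.voxel_count * self.spacing.voxel_volume


@dataclass(frozen=True)
class LabelStack:
    """Instance-labeled 3D grid: 0 = background, labels 1..K with no gaps."""

    grid: np.ndarray
    spacing: VoxelSpacing
    name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"label stack must be 3D, got ndim={grid.ndim}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValidationError(f"label stack must be integer-typed, got {grid.dtype}")
        if grid.size and grid.min() < 0:
            raise ValidationError("label stack contains negative labels")
        labels = np.unique(grid)
        labels = labels[labels > 0]
        k = len(labels)
        if k and (labels[0] != 1 or labels[-1] != k):
            raise ValidationError(f"labels must be contiguous 1..K, got {labels.tolist()}")
        object.__setattr__(self, "grid", grid)

    @property
    def n_objects(self) -> int:
        return int(self.grid.max())

    def as_semantic(self) -> SemanticMask:
        return SemanticMask(self.grid > 0, self.spacing)


@dataclass(frozen=True)
class CellScaffold:
    """Cell and nucleus masks defining the measurement frame.

    Each mask is treated as exactly one object; the nucleus foreground must
    lie inside the cell foreground.
    """

    cell: SemanticMask
    nucleus: SemanticMask

    def __post_init__(self) -> None:
        if self.cell.grid.shape != self.nucleus.grid.shape:
            raise ValidationError(
                "shape-mismatch: cell "
                f"{self.cell.grid.shape} vs nucleus {self.nucleus.grid.shape}"
            )
        if self.cell.spacing != self.nucleus.spacing:
            raise ValidationError("spacing mismatch between cell and nucleus masks")
        if self.cell.voxel_count == 0:
            raise ValidationError("empty-mask: cell mask has no foreground")
        if self.nucleus.voxel_count == 0:
            raise ValidationError("empty-mask: nucleus mask has no foreground")
        if np.any(self.nucleus.grid & ~self.cell.grid):
            raise ValidationError("nucleus-escape: nucleus voxels outside the cell mask")

    @property
    def spacing(self) -> VoxelSpacing:
        return self.cell.spacing


@dataclass(frozen=True)
class CellImage:
    """One cell: scaffold plus organelle channels (binary or instance-labeled).

    ``channels`` maps organelle name → SemanticMask or LabelStack; optional
    ``intensities`` maps organelle name → raw 3D intensity array.
    """

    scaffold: CellScaffold
    channels: Mapping[str, SemanticMask | LabelStack]
    intensities: Mapping[str, np.ndarray] = field(default_factory=dict)

    @property
    def spacing(self) -> VoxelSpacing:
        return self.scaffold.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.scaffold.cell.grid.shape


def validate_cell_image(img: CellImage) -> CellImage:
    """Check structural invariants of a :class:`CellImage`.

    Raises :class:`ValidationError` naming the offending channel on shape or
    spacing mismatch, empty cell mask, or nucleus voxels outside the cell.
    Idempotent: validating a validated image returns an identical structure.
    """
    shape = img.scaffold.cell.grid.shape
    spacing = img.scaffold.spacing
    for name, chan in img.channels.items():
        if chan.grid.shape != shape:
            raise ValidationError(
                f"shape-mismatch: channel {name!r} has shape {chan.grid.shape}, "
                f"expected {shape}"
            )
        if chan.spacing != spacing:
            raise ValidationError(f"spacing mismatch on channel {name!r}")
    for name, arr in img.intensities.items():
        arr = np.asarray(arr)
        if arr.shape != shape:
            raise ValidationError(
                f"shape-mismatch: intensity channel {name!r} has shape {arr.shape}, "
                f"expected {shape}"
            )
        if arr.size and arr.min() < 0:
            raise ValidationError(f"intensity channel {name!r} contains negative values")
    return img


__all__ = [
    "ORGANELLES",
    "ValidationError",
    "VoxelSpacing",
    "SemanticMask",
    "LabelStack",
    "CellScaffold",
    "CellImage",
    "validate_cell_image",
]
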