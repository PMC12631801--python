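"""File I/O: multi-channel TIFF cell images, CSV tables, run configuration.

Cell images are stored as (C, Z, Y, X) TIFF stacks.  Files written by this
package carry a JSON description tag recording channel names and voxel
spacing, so they round-trip without extra arguments; files from elsewhere
need an explicit channel map and spacing.  All tables are plain CSV
(comma-separated, UTF-8, '.' decimal, missing values as empty fields).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    CellImage,
    CellScaffold,
    LabelStack,
    ORGANELLES,
    SemanticMask,
    ValidationError,
    VoxelSpacing,
    validate_cell_image,
)
from .synthetic import GroundTruth


def write_cell_image(img: CellImage, path: str | Path) -> None:
    """Write a cell image as a (C, Z, Y, X) TIFF with channel/spacing metadata."""
    names = ["cell", "nucleus"] + [o for o in ORGANELLES if o in img.channels]
    planes = [img.scaffold.cell.grid, img.scaffold.nucleus.grid]
    planes += [img.channels[o].grid for o in names[2:]]
    data = np.stack([p.astype(np.uint16) for p in planes])
    meta = {
        "channels": names,
        "spacing_um": list(img.spacing.as_tuple()),
        "axes": "CZYX",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_cell_image(
    path: str | Path,
    spacing: VoxelSpacing | None = None,
    channel_map: dict[int, str] | None = None,
) -> CellImage:
    """Read a multi-channel TIFF stack into a validated :class:`CellImage`.

    ``channel_map`` maps channel index → name and must cover ``cell``,
    ``nucleus`` and the six organelles; both it and ``spacing`` default to
    the file's own metadata when the file was written by this package.
    Binary channels are kept semantic (instancing happens downstream);
    integer-labeled channels are accepted as label stacks; float-valued
    channels are rejected.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if spacing is None:
        if "spacing_um" not in meta:
            raise ValidationError(f"{path}: no spacing metadata; pass spacing explicitly")
        spacing = VoxelSpacing(*meta["spacing_um"])
    if channel_map is None:
        if "channels" not in meta:
            raise ValidationError(f"{path}: no channel metadata; pass a channel map")
        channel_map = dict(enumerate(meta["channels"]))
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a (C, Z, Y, X) stack, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer) and not np.issubdtype(data.dtype, np.bool_):
        raise ValidationError(f"{path}: channels must be integer-labeled or binary, got {data.dtype}")

    by_name = {channel_map[i]: data[i] for i in range(data.shape[0]) if i in channel_map}
    for required in ("cell", "nucleus"):
        if required not in by_name:
            raise ValidationError(f"{path}: missing channel {required!r}")
    missing = [o for o in ORGANELLES if o not in by_name]
    if missing:
        raise ValidationError(f"{path}: missing organelle channel(s) {missing}")

    scaffold = CellScaffold(
        SemanticMask(by_name["cell"] > 0, spacing),
        SemanticMask(by_name["nucleus"] > 0, spacing),
    )
    channels: dict[str, SemanticMask | LabelStack] = {}
    for org in ORGANELLES:
        arr = by_name[org]
        if arr.max(initial=0) > 1:
            channels[org] = LabelStack(arr.astype(np.int32), spacing, name=org)
        else:
            channels[org] = SemanticMask(arr > 0, spacing)
    return validate_cell_image(CellImage(scaffold=scaffold, channels=channels))


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Ground truth per organelle as CSV (count, total volume, planted overlaps)."""
    rows = []
    for org, count in gt.counts.items():
        rows.append(
            {
                "organelle": org,
                "count": count,
                "total_volume_um3": gt.total_volumes.get(org, 0.0),
                "seed": gt.seed,
            }
        )
    for pair, n in gt.overlap_counts.items():
        rows.append({"organelle": pair, "count": n, "total_volume_um3": np.nan,
                     "seed": gt.seed})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with stable formatting: empty fields for missing values."""
    df.to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run; defaults match the pipeline defaults."""

    spacing_um: tuple[float, float, float] = (0.25, 0.10, 0.10)
    n_rings: int = 5
    n_z_bins: int = 10
    n_wedges: int = 8
    fdr: float = 0.10
    pca_n_sim: int = 1000
    pca_percentile: float = 95.0
    seed: int = 0
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_rings, self.n_z_bins, self.n_wedges) < 1:
            raise ValidationError("region counts must be ≥ 1")
        if not 0 < self.fdr < 1:
            raise ValidationError("FDR must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are kept under ``extra``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "spacing_um" in kwargs:
        kwargs["spacing_um"] = tuple(kwargs["spacing_um"])
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extra=extra)


__all__ = [
    "write_cell_image",
    "read_cell_image",
    "write_ground_truth",
    "write_table",
    "read_table",
    "RunConfig",
    "load_config",
]
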