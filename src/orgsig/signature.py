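"""Per-cell metric tables: the full panel and the curated 234-metric signature.

Metric names follow an ``<object>_<metric>`` scheme (``LS_total_volume``,
``ER-MT_count``, ``PO_XY_mode``, ``nuc_Z_SD``).  The curated organelle
signature decomposes as

* 65 morphology metrics — 11 per organelle (volume fraction, total volume,
  count, median object volume, SD of object volumes, and the median of six
  shape metrics) minus the ER count, which is constant 1 by construction
  because the ER is segmented as a single object;
* 60 interaction metrics — count, total volume, median site volume and SD of
  site volumes for each of the 15 organelle pairs;
* 109 distribution metrics — XY mode, XY SD, XY median wedge CV, Z mode and
  Z SD for the 6 organelles and 15 pairs, plus XY mode/SD and Z mode/SD for
  the nucleus (no wedge CV).

65 + 60 + 109 = 234.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CellImage, LabelStack, ORGANELLES, SemanticMask, ValidationError, validate_cell_image
from .distribution import build_xy_regions, build_z_regions, distribution_metrics, profile
from .instancing import as_single_object, label_instances
from .interactions import PAIRS, all_pairs
from .morphology import measure_objects, measure_scaffold, summarize_organelle

_MORPH_METRICS = (
    "volume_fraction",
    "total_volume",
    "count",
    "median_volume",
    "SD_volumes",
    "median_SA_to_volume_ratio",
    "median_equivalent_diameter",
    "median_extent",
    "median_euler_number",
    "median_solidity",
    "median_axis_major_length",
)
_INTERACTION_METRICS = ("count", "total_volume", "median_volume", "SD_volumes")
_DIST_METRICS = ("XY_mode", "XY_SD", "XY_median_CV", "Z_mode", "Z_SD")


def curated_columns() -> list[str]:
    """The 234 curated signature column names, in deterministic order."""
    cols: list[str] = []
    for org in ORGANELLES:
        for m in _MORPH_METRICS:
            if org == "ER" and m == "count":
                continue  # constant 1 by construction
            cols.append(f"{org}_{m}")
    for pair in PAIRS:
        for m in _INTERACTION_METRICS:
            cols.append(f"{pair}_{m}")
    for obj in ORGANELLES + PAIRS:
        for m in _DIST_METRICS:
            cols.append(f"{obj}_{m}")
    for m in ("XY_mode", "XY_SD", "Z_mode", "Z_SD"):
        cols.append(f"nuc_{m}")
    return cols


CURATED_COLUMNS = tuple(curated_columns())
MORPHOLOGY_BLOCK = tuple(c for c in CURATED_COLUMNS[: 6 * 11 - 1])
INTERACTION_BLOCK = tuple(CURATED_COLUMNS[65 : 65 + 60])
DISTRIBUTION_BLOCK = tuple(CURATED_COLUMNS[125:])


def _instance_channels(img: CellImage) -> dict[str, LabelStack]:
    """Instance every organelle channel; the ER is forced to a single object."""
    out: dict[str, LabelStack] = {}
    for name, chan in img.channels.items():
        if isinstance(chan, LabelStack):
            out[name] = chan
        elif name == "ER" and chan.voxel_count > 0:
            out[name] = as_single_object(chan, name)
        else:
            out[name] = label_instances(chan, name)
    return out


def quantify_cell(
    img: CellImage,
    n_rings: int = 5,
    n_bins: int = 10,
    n_wedges: int = 8,
    include_region_profiles: bool = True,
) -> dict[str, float]:
    """Run the full per-cell quantification and return the full-panel row.

    Covers organelle morphology summaries, cell/nucleus morphology, the 15
    pairwise interaction summaries (including percent-involved metrics), and
    XY/Z distribution summaries for every organelle, pair and the nucleus.
    Optionally also emits per-region normalized volumes.
    """
    validate_cell_image(img)
    channels = _instance_channels(img)
    cell_volume = img.scaffold.cell.volume

    row: dict[str, float] = {}
    row.update(measure_scaffold(img.scaffold, dict(img.intensities) or None))

    object_masks: dict[str, np.ndarray] = {}
    for org in ORGANELLES:
        if org not in channels:
            raise ValidationError(f"missing organelle channel: {org}")
        stack = channels[org]
        intensities = {org: img.intensities[org]} if org in img.intensities else None
        records = measure_objects(stack, intensities)
        row.update(summarize_organelle(org, records, cell_volume).as_dict())
        object_masks[org] = stack.grid > 0

    pair_results = all_pairs(channels)
    for pair, (sites, summary) in pair_results.items():
        row.update(summary.as_dict(include_percents=True))
        object_masks[pair] = sites.sites.grid > 0

    xy = build_xy_regions(img.scaffold, n_rings=n_rings, n_wedges=n_wedges)
    z = build_z_regions(img.scaffold, n_bins=n_bins)
    for name, mask in object_masks.items():
        row.update(distribution_metrics(name, mask, xy, z, include_cv=True))
        if include_region_profiles:
            for prof, regions in ((profile(mask, xy, name), xy), (profile(mask, z, name), z)):
                for r, val in enumerate(prof.normalized, start=1):
                    row[f"{name}_{prof.axis}_region{r}_norm"] = float(val)
    row.update(
        distribution_metrics("nuc", img.scaffold.nucleus.grid, xy, z, include_cv=False)
    )
    return row


def assemble_cell(
    organelle_summaries: dict[str, float],
    scaffold_metrics: dict[str, float],
    interaction_summaries: dict[str, float],
    distribution_summaries: dict[str, float],
) -> dict[str, float]:
    """Merge precomputed per-cell summary blocks into one full-panel row."""
    row: dict[str, float] = {}
    for block in (
        scaffold_metrics,
        organelle_summaries,
        interaction_summaries,
        distribution_summaries,
    ):
        row.update(block)
    return row


def curate(full_row: dict[str, float]) -> dict[str, float]:
    """Select the 234 curated signature metrics from a full-panel row."""
    missing = [c for c in CURATED_COLUMNS if c not in full_row]
    if missing:
        raise ValidationError(f"missing required full-panel column(s): {missing[:5]}")
    return {c: full_row[c] for c in CURATED_COLUMNS}


def batch_combine(
    rows: list[dict[str, float]],
    cell_ids: list[str] | None = None,
    groups: list[str] | None = None,
    replicates: list[str] | None = None,
) -> pd.DataFrame:
    """Combine per-cell rows into one table, preserving row order.

    Group labels and replicate ids are kept as leading columns so that
    experimental replicates can be combined while remaining inspectable for
    batch effects.  Raises on any column mismatch between rows.
    """
    if not rows:
        raise ValidationError("no rows to combine")
    ref = list(rows[0])
    for i, r in enumerate(rows[1:], start=1):
        if list(r) != ref:
            diff = set(ref).symmetric_difference(r)
            raise ValidationError(f"column mismatch at row {i}: {sorted(diff)[:5]}")
    df = pd.DataFrame(rows)
    df.insert(0, "cell_id", cell_ids if cell_ids is not None else
              [f"cell{i}" for i in range(len(rows))])
    if groups is not None:
        df.insert(1, "group", groups)
    if replicates is not None:
        df.insert(2 if groups is not None else 1, "replicate", replicates)
    return df


__all__ = [
    "CURATED_COLUMNS",
    "MORPHOLOGY_BLOCK",
    "INTERACTION_BLOCK",
    "DISTRIBUTION_BLOCK",
    "curated_columns",
    "quantify_cell",
    "assemble_cell",
    "curate",
    "batch_combine",
]
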