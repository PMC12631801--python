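"""Radial rings, wedges, Z bins: geometry, conservation, normalization identities."""

import math

import numpy as np
import pytest

from orgsig.core import SemanticMask, VoxelSpacing
from orgsig.distribution import (
    RegionProfile,
    XYRegions,
    build_xy_regions,
    build_z_regions,
    profile,
    profile_wedges,
    summarize_distribution,
)

from conftest import make_disc_scaffold

SP = VoxelSpacing(1, 1, 1)


def test_disc_phantom_rings_are_equal_thickness_annuli(disc_scaffold):
    xy = build_xy_regions(disc_scaffold)
    c = disc_scaffold.cell.grid.shape[1] // 2
    # walk outward along +x from the nucleus edge: ring index increases in
    # 5 equal radial intervals between nucleus edge (r=10) and cell edge (r=30)
    for radius, expected in ((5, 1), (11, 1), (15, 2), (19, 3), (23, 4), (27, 5), (30, 5)):
        assert xy.ring_map[c, c + radius] == expected, f"radius {radius}"
    # every footprint pixel has exactly one ring and one wedge
    fp = disc_scaffold.cell.grid.any(axis=0)
    assert ((xy.ring_map > 0) == fp).all()
    assert ((xy.wedge_map > 0) == fp).all()
    # ring volumes sum to the cell volume
    assert xy.ring_cell_volume.sum() == pytest.approx(xy.cell_volume)


def test_nucleus_pixels_are_ring_one(disc_scaffold):
    xy = build_xy_regions(disc_scaffold)
    nuc_fp = disc_scaffold.nucleus.grid.any(axis=0)
    assert (xy.ring_map[nuc_fp] == 1).all()


@pytest.mark.parametrize(
    "n_planes,expected_sizes",
    [
        (20, [2] * 10),
        (23, [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]),
        (5, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),
    ],
)
def test_z_bins_split_plane_range_nearly_equally(n_planes, expected_sizes):
    scaffold = make_disc_scaffold(cell_radius=6, nucleus_radius=2, n_planes=n_planes)
    z = build_z_regions(scaffold, n_bins=10)
    sizes = [int((z.plane_bin == b).sum()) for b in range(1, 11)]
    assert sizes == expected_sizes
    assert z.bin_cell_volume.sum() == pytest.approx(z.cell_volume)


def test_cell_mask_profiles_to_unit_normalized_volume(disc_scaffold):
    xy = build_xy_regions(disc_scaffold)
    z = build_z_regions(disc_scaffold)
    for regions in (xy, z):
        prof = profile(disc_scaffold.cell, regions, name="cell")
        np.testing.assert_allclose(prof.normalized, 1.0)
        assert prof.raw.sum() == pytest.approx(disc_scaffold.cell.volume)


def test_conservation_of_object_volume_across_regions(disc_scaffold):
    rng = np.random.default_rng(5)
    obj = disc_scaffold.cell.grid & (rng.random(disc_scaffold.cell.grid.shape) < 0.1)
    xy = build_xy_regions(disc_scaffold)
    z = build_z_regions(disc_scaffold)
    for regions in (xy, z):
        prof = profile(obj, regions)
        assert prof.raw.sum() == obj.sum()  # exact, in unit spacing


def test_hand_built_two_ring_normalization():
    # 2 rings; object: 4 voxels in ring 1 (ring cell volume 40) and 4 in
    # ring 2 (ring cell volume 120); n = (0.5/0.25, 0.5/0.75) = (2.0, 2/3)
    ring_map = np.zeros((6, 6), np.int32)
    ring_map[:, :3] = 1
    ring_map[:, 3:] = 2
    col = np.zeros((6, 6), np.int64)
    col[0, :3] = [20, 10, 10]  # ring 1 cell volume 40
    col[1, 3:] = [40, 40, 40]  # ring 2 cell volume 120
    regions = XYRegions(
        ring_map=ring_map,
        wedge_map=np.ones((6, 6), np.int32),
        column_counts=col,
        ring_cell_volume=np.array([40.0, 120.0]),
        cell_volume=160.0,
        voxel_volume=1.0,
        n_rings=2,
        n_wedges=1,
    )
    obj = np.zeros((4, 6, 6), bool)
    obj[0, 0, 0:2] = True
    obj[1, 0, 0:2] = True  # 4 voxels in ring 1
    obj[0, 1, 3:5] = True
    obj[1, 1, 3:5] = True  # 4 voxels in ring 2
    prof = profile(obj, regions)
    np.testing.assert_allclose(prof.normalized, [2.0, 2.0 / 3.0])
    # weighted-index summary: mode 1, SD = 0.433
    summ = summarize_distribution(prof)
    assert summ.mode == 1
    assert summ.sd == pytest.approx(math.sqrt(0.1875), abs=1e-6)


def test_point_mass_distribution_summary():
    prof = RegionProfile(name="x", axis="Z", raw=np.array([0, 0, 5.0, 0, 0]),
                         normalized=np.array([0, 0, 2.5, 0, 0]), total=5.0)
    summ = summarize_distribution(prof)
    assert summ.mode == 3
    assert summ.sd == 0.0


def test_empty_profile_yields_missing_summary():
    prof = RegionProfile(name="x", axis="XY", raw=np.zeros(5),
                         normalized=np.zeros(5), total=0.0)
    summ = summarize_distribution(prof)
    assert math.isnan(summ.mode) and math.isnan(summ.sd) and math.isnan(summ.median_cv)


def test_uniform_wedge_occupancy_has_zero_cv(disc_scaffold):
    xy = build_xy_regions(disc_scaffold)
    # object = entire cell: every wedge of every ring uniformly occupied
    raw, norm, cell_rw = profile_wedges(disc_scaffold.cell, xy)
    prof = profile(disc_scaffold.cell, xy, name="cell")
    summ = summarize_distribution(prof, norm, raw, cell_rw)
    assert summ.median_cv == pytest.approx(0.0, abs=1e-9)


def test_rotating_phantom_rotates_ring_assignment_with_it():
    from orgsig.core import CellScaffold

    scaffold = make_disc_scaffold(cell_radius=14, nucleus_radius=5, n_planes=4)
    # break the circular symmetry so the rotation is observable
    cell = scaffold.cell.grid.copy()
    cell[:, :, :4] = False
    rotated = CellScaffold(
        SemanticMask(np.rot90(cell, k=1, axes=(1, 2)), SP),
        SemanticMask(np.rot90(scaffold.nucleus.grid, k=1, axes=(1, 2)), SP),
    )
    xy = build_xy_regions(CellScaffold(SemanticMask(cell, SP), scaffold.nucleus))
    xy_rot = build_xy_regions(rotated)
    np.testing.assert_array_equal(np.rot90(xy.ring_map, k=1), xy_rot.ring_map)


def test_perinuclear_object_concentrates_in_ring_one(disc_scaffold):
    xy = build_xy_regions(disc_scaffold)
    c = disc_scaffold.cell.grid.shape[1] // 2
    obj = np.zeros_like(disc_scaffold.cell.grid)
    obj[2, c - 12 : c + 12, c - 12 : c + 12] = True  # hugging the nucleus
    obj &= disc_scaffold.cell.grid
    prof = profile(obj, xy)
    raw, norm, cell_rw = profile_wedges(obj, xy)
    summ = summarize_distribution(prof, norm, raw, cell_rw)
    assert summ.mode == 1
    assert prof.raw.sum() == obj.sum()
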