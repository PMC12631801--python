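"""Shared fixtures: analytic phantoms and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from orgsig.core import CellImage, CellScaffold, SemanticMask, VoxelSpacing


@pytest.fixture(scope="session")
def unit_spacing() -> VoxelSpacing:
    return VoxelSpacing(1.0, 1.0, 1.0)


def make_disc_scaffold(
    cell_radius: int = 30,
    nucleus_radius: int = 10,
    n_planes: int = 20,
    pad: int = 3,
    spacing: VoxelSpacing = VoxelSpacing(1.0, 1.0, 1.0),
) -> CellScaffold:
    """Cylindrical cell with a central cylindrical nucleus: analytic ring geometry."""
    size = 2 * (cell_radius + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    rho = np.hypot(yy - c, xx - c)
    cell2d = rho <= cell_radius
    nuc2d = rho <= nucleus_radius
    cell = np.repeat(cell2d[None], n_planes, axis=0)
    nuc = np.repeat(nuc2d[None], n_planes, axis=0)
    return CellScaffold(SemanticMask(cell, spacing), SemanticMask(nuc, spacing))


@pytest.fixture(scope="session")
def disc_scaffold() -> CellScaffold:
    return make_disc_scaffold()


def make_cell_image(
    scaffold: CellScaffold, channels: dict[str, np.ndarray]
) -> CellImage:
    sp = scaffold.spacing
    return CellImage(
        scaffold=scaffold,
        channels={k: SemanticMask(v, sp) for k, v in channels.items()},
    )


def random_blob_mask(rng: np.random.Generator, size: int = 12, p: float = 0.25) -> np.ndarray:
    """Random sparse boolean mask for oracle comparisons."""
    return rng.random((size, size, size)) < p


# ---------------------------------------------------------------------------
# independent brute-force oracles


def union_find_components(mask: np.ndarray) -> set[frozenset]:
    """26-connectivity components by explicit union-find over voxel pairs."""
    coords = [tuple(c) for c in np.argwhere(mask)]
    index = {c: i for i, c in enumerate(coords)}
    parent = list(range(len(coords)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (z, y, x), i in index.items():
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    j = index.get((z + dz, y + dy, x + dx))
                    if j is not None:
                        ri, rj = find(i), find(j)
                        if ri != rj:
                            parent[ri] = rj
    groups: dict[int, set] = {}
    for c, i in index.items():
        groups.setdefault(find(i), set()).add(c)
    return {frozenset(g) for g in groups.values()}


def euler_cubical(mask: np.ndarray) -> int:
    """Euler characteristic V − E + F − C of the closed-voxel cubical complex."""
    verts, edges, faces = set(), set(), set()
    cells = 0
    for z, y, x in np.argwhere(mask):
        cells += 1
        corners = [
            (z + a, y + b, x + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
        ]
        verts.update(corners)
        for axis in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    lo = [z, y, x]
                    lo[(axis + 1) % 3] += a
                    lo[(axis + 2) % 3] += b
                    edges.add((tuple(lo), axis))
        for axis in range(3):
            for a in (0, 1):
                lo = [z, y, x]
                lo[axis] += a
                faces.add((tuple(lo), axis))
    return len(verts) - len(edges) + len(faces) - cells


def solidity_halfspace(mask: np.ndarray) -> float:
    """Solidity via hull half-space membership of all foreground centers."""
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask).astype(float)
    hull = ConvexHull(pts)
    centers = np.indices(mask.shape).reshape(3, -1).T.astype(float)
    inside = np.all(
        centers @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-9, axis=1
    )
    return len(pts) / float(inside.sum())


def mwu_exact_two_sided(a, b) -> float:
    """Two-sided exact MWU p by enumerating all group assignments (tie-free)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(a), len(b)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    us = []
    for combo in combinations(range(n + m), n):
        rank_sum = sum(c + 1 for c in combo)
        us.append(rank_sum - n * (n + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)
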