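"""Seeded 3D cell phantoms and point tracks with known ground truth.

The generator emulates the structure of a single adherent cell imaged as a
multi-channel z stack: a smoothed random-blob footprint extruded with a dome
profile in Z (cells spread on a coverslip are widest at the base), an
interior ellipsoidal nucleus, and per-organelle object populations with
configurable count, size and shape distributions, radial
(perinuclear↔peripheral) and Z placement biases, same-channel clustering,
and planted pairwise overlap rates between channels.  Every realized count,
volume and overlap is recorded as ground truth so each downstream pipeline
stage can be tested against known answers.

The ER is generated as a connected tube network (a random-walk skeleton
dilated to tubes) so that topology metrics (Euler number, tunnels) are
exercised; the remaining organelles are spheres or rods.  No attempt is
made to simulate intensities, point-spread functions or spectral mixing —
the phantoms are label images, matching the pipeline's input contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import CellImage, CellScaffold, SemanticMask, ValidationError, VoxelSpacing
from .distribution import radial_coordinate
from .tracks import Track


class InfeasiblePlacementError(ValidationError):
    """Requested objects could not be placed within the retry budget."""


@dataclass(frozen=True)
class ScaffoldParams:
    """Geometry of the phantom cell: grid, spacing, footprint, dome, nucleus."""

    shape: tuple[int, int, int] = (24, 112, 112)  # (Z, Y, X) voxels
    spacing: VoxelSpacing = VoxelSpacing(0.25, 0.10, 0.10)
    cell_radius_um: float = 4.8
    irregularity: float = 0.15  # relative amplitude of footprint harmonics
    dome_height_um: float = 5.5
    nucleus_radii_um: tuple[float, float, float] = (1.1, 1.4, 1.4)  # (z, y, x)
    nucleus_center_z_um: float = 1.3


@dataclass(frozen=True)
class OrganelleSpec:
    """Population model for one organelle channel.

    ``radial_bias`` and ``z_bias`` are Beta(a, b) parameters over the
    normalized radial coordinate d ∈ [0, 1] (0 = nucleus edge, 1 = cell
    edge) and the normalized column height; ``clustering_rate`` is the
    probability that a new object is placed adjacent (≤ 1 voxel) to an
    existing one, in which case the two merge under the instancing rule.
    """

    name: str
    count: int | tuple[int, int] = 0
    shape: str = "sphere"  # sphere | rod | network
    radius_um: float | tuple[float, float] = 0.3
    length_um: float | tuple[float, float] = 1.5  # rods only
    radial_bias: tuple[float, float] = (1.0, 1.0)
    z_bias: tuple[float, float] = (1.0, 1.0)
    clustering_rate: float = 0.0
    n_walks: int = 6  # network only
    n_steps: int = 250  # network only: steps per walk

    def __post_init__(self) -> None:
        cnt = self.count if isinstance(self.count, tuple) else (self.count, self.count)
        if min(cnt) < 0:
            raise ValidationError(f"{self.name}: count must be ≥ 0")
        rad = self.radius_um if isinstance(self.radius_um, tuple) else (self.radius_um,)
        if min(rad) <= 0:
            raise ValidationError(f"{self.name}: radii must be > 0")
        if not 0 <= self.clustering_rate <= 1:
            raise ValidationError(f"{self.name}: clustering rate must be in [0, 1]")
        if self.shape not in ("sphere", "rod", "network"):
            raise ValidationError(f"{self.name}: unknown shape {self.shape!r}")


@dataclass(frozen=True)
class InteractionSpec:
    """Planted overlap: a fraction of ``source`` objects overlap a ``target`` object.

    ``rate`` is the target fraction of source objects placed to overlap;
    ``depth`` the minimum voxels of interpenetration.  The target channel
    must be generated before the source channel.
    """

    source: str
    target: str
    rate: float
    depth: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValidationError("overlap rate must be in [0, 1]")
        if self.depth < 1:
            raise ValidationError("overlap depth must be ≥ 1")


@dataclass
class GroundTruth:
    """What the generator actually placed, consistent with the emitted image."""

    seed: int
    params: dict
    counts: dict[str, int] = field(default_factory=dict)
    total_volumes: dict[str, float] = field(default_factory=dict)  # μm³, final mask
    object_volumes: dict[str, list[float]] = field(default_factory=dict)  # as placed
    centroids: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    overlap_counts: dict[str, int] = field(default_factory=dict)  # "SRC-TGT" -> n placed


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid_offsets(radii_um: tuple[float, float, float], sp: VoxelSpacing) -> np.ndarray:
    """Voxel offsets inside a physical ellipsoid centered on a voxel."""
    rz, ry, rx = radii_um
    nz, ny, nx = (int(rz / sp.sz), int(ry / sp.sy), int(rx / sp.sx))
    dz, dy, dx = np.mgrid[-nz : nz + 1, -ny : ny + 1, -nx : nx + 1]
    inside = (
        (dz * sp.sz / rz) ** 2 + (dy * sp.sy / ry) ** 2 + (dx * sp.sx / rx) ** 2
    ) <= 1.0
    inside[nz, ny, nx] = True  # the center voxel always belongs
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def _sphere_offsets(radius_um: float, sp: VoxelSpacing) -> np.ndarray:
    return _ellipsoid_offsets((radius_um, radius_um, radius_um), sp)


_NEIGH26 = np.array(
    [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
)


def _build_scaffold(params: ScaffoldParams, rng: np.random.Generator) -> CellScaffold:
    nz, ny, nx = params.shape
    sp = params.spacing
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    # smoothed random-blob footprint: low-order harmonics on the radius
    n_harm = 4
    amps = rng.uniform(0.3, 1.0, n_harm) * params.irregularity / math.sqrt(n_harm)
    phases = rng.uniform(0, 2 * math.pi, n_harm)
    gy, gx = np.mgrid[0:ny, 0:nx]
    py, px = (gy - cy) * sp.sy, (gx - cx) * sp.sx
    rho = np.hypot(py, px)
    theta = np.arctan2(py, px)
    r_theta = params.cell_radius_um * (
        1.0
        + sum(a * np.cos((k + 2) * theta + ph) for k, (a, ph) in enumerate(zip(amps, phases)))
    )
    footprint = rho <= r_theta

    # dome profile: full footprint at the base plane, elliptical cap above
    rel = np.clip(rho / np.maximum(r_theta, 1e-9), 0.0, 1.0)
    height = params.dome_height_um * np.sqrt(1.0 - rel**2)
    z_phys = np.arange(nz)[:, None, None] * sp.sz
    cell = footprint[None, :, :] & (
        (z_phys < height[None, :, :]) | (np.arange(nz)[:, None, None] == 0)
    )

    # interior ellipsoidal nucleus
    rz_, ry_, rx_ = params.nucleus_radii_um
    z0 = params.nucleus_center_z_um
    nucleus = (
        ((z_phys - z0) / rz_) ** 2
        + (py[None, :, :] / ry_) ** 2
        + (px[None, :, :] / rx_) ** 2
    ) <= 1.0
    nucleus &= cell
    return CellScaffold(SemanticMask(cell, sp), SemanticMask(nucleus, sp))


# ---------------------------------------------------------------------------
# object placement


class _Placer:
    """Shared placement state for one phantom cell."""

    def __init__(self, scaffold: CellScaffold, rng: np.random.Generator):
        self.rng = rng
        self.sp = scaffold.spacing
        self.cell = scaffold.cell.grid
        self.cyt = self.cell & ~scaffold.nucleus.grid
        footprint = self.cell.any(axis=0)
        nuc_fp = scaffold.nucleus.grid.any(axis=0)
        d = radial_coordinate(footprint, nuc_fp, self.sp.sy, self.sp.sx)
        cyt_fp = self.cyt.any(axis=0)
        pix = np.argwhere(cyt_fp)
        dv = d[pix[:, 0], pix[:, 1]]
        order = np.argsort(dv, kind="stable")
        self._pix = pix[order]
        self._d = dv[order]

    def sample_center(self, radial_bias, z_bias) -> tuple[int, int, int]:
        """Sample a cytoplasm voxel with the requested radial and Z bias."""
        rng = self.rng
        d_star = rng.beta(*radial_bias)
        tol = 0.03
        while True:
            lo = np.searchsorted(self._d, d_star - tol)
            hi = np.searchsorted(self._d, d_star + tol)
            if hi > lo:
                y, x = self._pix[rng.integers(lo, hi)]
                zs = np.flatnonzero(self.cyt[:, y, x])
                if len(zs):
                    u = rng.beta(*z_bias)
                    return int(zs[min(int(u * len(zs)), len(zs) - 1)]), int(y), int(x)
            tol *= 2.0
            if tol > 4.0:
                raise InfeasiblePlacementError("no cytoplasm voxel available")

    def carve(self, voxels: np.ndarray) -> np.ndarray:
        """Clip candidate voxels to the grid and the cytoplasm; return (n,3)."""
        shape = self.cell.shape
        ok = np.all((voxels >= 0) & (voxels < np.array(shape)), axis=1)
        voxels = voxels[ok]
        inside = self.cyt[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        return voxels[inside]


def _rod_voxels(
    center: tuple[int, int, int],
    length_um: float,
    radius_um: float,
    sp: VoxelSpacing,
    rng: np.random.Generator,
) -> np.ndarray:
    az = rng.uniform(0, 2 * math.pi)
    tilt = rng.uniform(-0.25, 0.25)
    v = np.array([tilt, math.sin(az), math.cos(az)])
    v /= np.linalg.norm(v)
    step = 0.5 * min(sp.sy, sp.sx)
    ts = np.arange(-length_um / 2, length_um / 2 + step, step)
    centers_phys = np.array(center) * np.array(sp.as_tuple()) + ts[:, None] * v
    centers_vox = np.rint(centers_phys / np.array(sp.as_tuple())).astype(int)
    offsets = _sphere_offsets(radius_um, sp)
    vox = (centers_vox[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return np.unique(vox, axis=0)


def _network_voxels(
    placer: _Placer, spec: OrganelleSpec, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk skeleton spanning the cytoplasm, dilated to tubes."""
    cyt = placer.cyt
    visited: list[tuple[int, int, int]] = []
    pos = np.array(placer.sample_center((1.0, 6.0), spec.z_bias))
    cyt_idx = np.argwhere(cyt)
    for _ in range(spec.n_walks):
        target = cyt_idx[rng.integers(len(cyt_idx))]
        for _ in range(spec.n_steps):
            step = np.sign(target - pos)
            jitter = rng.integers(-1, 2, 3)
            cand = pos + np.where(rng.random(3) < 0.6, step, jitter)
            cand = np.clip(cand, 0, np.array(cyt.shape) - 1)
            if cyt[tuple(cand)]:
                pos = cand
                visited.append(tuple(pos))
            if np.all(pos == target):
                break
    if not visited:
        raise InfeasiblePlacementError("ER walk found no cytoplasm")
    skel = np.unique(np.array(visited), axis=0)
    radius = spec.radius_um if isinstance(spec.radius_um, float) else spec.radius_um[0]
    offsets = _sphere_offsets(radius, placer.sp)
    vox = (skel[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return np.unique(vox, axis=0)


def _sample(rng: np.random.Generator, value):
    if isinstance(value, tuple):
        lo, hi = value
        if isinstance(lo, int) and isinstance(hi, int):
            return int(rng.integers(lo, hi + 1))
        return float(rng.uniform(lo, hi))
    return value


def generate_cell(
    specs: list[OrganelleSpec],
    interactions: list[InteractionSpec] = (),
    scaffold_params: ScaffoldParams | None = None,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[CellImage, GroundTruth]:
    """Generate one phantom cell and its ground truth; deterministic per seed.

    Channels are generated in the order of ``specs``; an interaction's
    target channel must precede its source.  Objects of a source channel not
    chosen to overlap are placed disjoint from the target, so the realized
    overlap fraction matches the planted rate.
    """
    if len(specs) > 6:
        raise ValidationError("at most 6 organelle channels")
    params = scaffold_params or ScaffoldParams()
    rng = np.random.default_rng(seed)
    scaffold = _build_scaffold(params, rng)
    placer = _Placer(scaffold, rng)
    sp = params.spacing
    vv = sp.voxel_volume

    gt = GroundTruth(
        seed=seed,
        params={
            "scaffold": asdict(params),
            "specs": [asdict(s) for s in specs],
            "interactions": [asdict(i) for i in interactions],
        },
    )
    channels: dict[str, SemanticMask] = {}
    grids: dict[str, np.ndarray] = {}

    by_source: dict[str, list[InteractionSpec]] = {}
    for ispec in interactions:
        by_source.setdefault(ispec.source, []).append(ispec)

    for spec in specs:
        for ispec in by_source.get(spec.name, []):
            if ispec.target not in grids:
                raise ValidationError(
                    f"interaction target {ispec.target!r} must be generated before "
                    f"source {spec.name!r}"
                )
        grid = np.zeros(params.shape, dtype=bool)
        forbidden = np.zeros(params.shape, dtype=bool)  # self + 1-voxel halo
        gt.counts[spec.name] = 0
        gt.object_volumes[spec.name] = []
        gt.centroids[spec.name] = []

        if spec.shape == "network":
            vox = placer.carve(_network_voxels(placer, spec, rng))
            grid[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            gt.counts[spec.name] = 1
            gt.object_volumes[spec.name] = [len(vox) * vv]
            gt.centroids[spec.name] = [
                tuple((vox.mean(axis=0) * np.array(sp.as_tuple())).tolist())
            ]
        else:
            count = _sample(rng, spec.count)
            # which objects are planted to overlap which target
            overlap_plan: list[InteractionSpec | None] = [None] * count
            for ispec in by_source.get(spec.name, []):
                n_overlap = int(round(ispec.rate * count))
                free = [i for i, o in enumerate(overlap_plan) if o is None]
                chosen = rng.choice(len(free), size=min(n_overlap, len(free)), replace=False)
                for c in np.sort(chosen):
                    overlap_plan[free[int(c)]] = ispec
                gt.overlap_counts[f"{ispec.source}-{ispec.target}"] = int(
                    min(n_overlap, len(free))
                )
            avoid_targets = [grids[i.target] for i in by_source.get(spec.name, [])]

            for i in range(count):
                plan = overlap_plan[i]
                if plan is not None and not grids[plan.target].any():
                    plan = None  # nothing to overlap; place freely
                placed = False
                for _ in range(max_attempts):
                    radius = _sample(rng, spec.radius_um)
                    clustered = (
                        grid.any()
                        and plan is None
                        and rng.random() < spec.clustering_rate
                    )
                    if plan is not None:
                        tgt_idx = np.argwhere(grids[plan.target])
                        center = tuple(tgt_idx[rng.integers(len(tgt_idx))])
                    elif clustered:
                        own = np.argwhere(grid)
                        base = own[rng.integers(len(own))]
                        off = rng.integers(-1, 2, 3)
                        center = tuple(np.clip(base + off, 0, np.array(params.shape) - 1))
                    else:
                        center = placer.sample_center(spec.radial_bias, spec.z_bias)
                    if spec.shape == "rod":
                        length = _sample(rng, spec.length_um)
                        cand = _rod_voxels(center, length, radius, sp, rng)
                    else:
                        cand = np.array(center) + _sphere_offsets(radius, sp)
                    vox = placer.carve(cand)
                    if len(vox) < max(1, len(cand) // 2):
                        continue  # clipped too hard by the cell boundary
                    sel = (vox[:, 0], vox[:, 1], vox[:, 2])
                    if plan is not None:
                        tgt = grids[plan.target]
                        if int(tgt[sel].sum()) < plan.depth:
                            continue
                    else:
                        if any(t[sel].any() for t in avoid_targets):
                            continue  # keep the planted overlap rate clean
                    if not clustered and forbidden[sel].any():
                        continue
                    grid[sel] = True
                    halo = (vox[:, None, :] + _NEIGH26[None, :, :]).reshape(-1, 3)
                    halo = halo[
                        np.all((halo >= 0) & (halo < np.array(params.shape)), axis=1)
                    ]
                    forbidden[halo[:, 0], halo[:, 1], halo[:, 2]] = True
                    gt.counts[spec.name] += 1
                    gt.object_volumes[spec.name].append(len(vox) * vv)
                    gt.centroids[spec.name].append(
                        tuple((vox.mean(axis=0) * np.array(sp.as_tuple())).tolist())
                    )
                    placed = True
                    break
                if not placed:
                    raise InfeasiblePlacementError(
                        f"could not place object {i + 1}/{count} of {spec.name} "
                        f"after {max_attempts} attempts"
                    )
        grids[spec.name] = grid
        channels[spec.name] = SemanticMask(grid, sp)
        gt.total_volumes[spec.name] = float(grid.sum()) * vv

    img = CellImage(scaffold=scaffold, channels=channels)
    return img, gt


# ---------------------------------------------------------------------------
# presets: planted cell-type contrasts


def preset(name: str) -> tuple[list[OrganelleSpec], list[InteractionSpec]]:
    """Organelle and interaction specs for a planted cell-type phenotype.

    ``neuron_like`` plants a higher MT count and total volume and a higher
    MT-on-ER overlap rate; ``astrocyte_like`` plants a larger, perinuclear,
    partly clustered LS population and a higher PO-on-LS overlap rate.
    Channel order puts interaction targets before their sources.
    """
    common = dict(z_bias=(2.0, 2.0))
    if name == "neuron_like":
        specs = [
            OrganelleSpec("ER", count=1, shape="network", radius_um=0.12,
                          n_walks=6, n_steps=250, **common),
            OrganelleSpec("LS", count=13, radius_um=(0.22, 0.35),
                          radial_bias=(2.0, 2.5), **common),
            OrganelleSpec("GL", count=6, radius_um=(0.30, 0.50),
                          radial_bias=(1.2, 5.0), **common),
            OrganelleSpec("MT", count=40, shape="rod", radius_um=0.15,
                          length_um=(1.0, 2.0), radial_bias=(2.0, 2.0), **common),
            OrganelleSpec("PO", count=24, radius_um=(0.15, 0.28),
                          radial_bias=(2.5, 2.0), **common),
            OrganelleSpec("LD", count=10, radius_um=(0.20, 0.32),
                          radial_bias=(3.0, 1.5), **common),
        ]
        inter = [
            InteractionSpec("MT", "ER", rate=0.45, depth=1),
            InteractionSpec("PO", "LS", rate=0.08, depth=1),
        ]
    elif name == "astrocyte_like":
        specs = [
            OrganelleSpec("ER", count=1, shape="network", radius_um=0.12,
                          n_walks=5, n_steps=250, **common),
            OrganelleSpec("LS", count=24, radius_um=(0.25, 0.40),
                          radial_bias=(1.0, 6.0), clustering_rate=0.25, **common),
            OrganelleSpec("GL", count=6, radius_um=(0.30, 0.50),
                          radial_bias=(1.2, 5.0), **common),
            OrganelleSpec("MT", count=16, shape="rod", radius_um=0.15,
                          length_um=(1.0, 2.0), radial_bias=(2.0, 2.0), **common),
            OrganelleSpec("PO", count=16, radius_um=(0.18, 0.32),
                          radial_bias=(2.5, 2.0), **common),
            OrganelleSpec("LD", count=12, radius_um=(0.20, 0.35),
                          radial_bias=(3.0, 1.5), **common),
        ]
        inter = [
            InteractionSpec("MT", "ER", rate=0.10, depth=1),
            InteractionSpec("PO", "LS", rate=0.55, depth=1),
        ]
    else:
        raise ValidationError(f"unknown preset {name!r}")
    return specs, inter


# ---------------------------------------------------------------------------
# point tracks


def generate_tracks(
    n_tracks: int,
    motion: str,
    speed: float = 0.2,
    frames: int = 60,
    frame_interval: float = 5.0,
    seed: int = 0,
    noise_um: float = 0.0,
) -> list[Track]:
    """Generate seeded 2D point tracks with directed, diffusive or stationary motion.

    ``speed`` is the nominal step speed in μm/s; directed tracks move along
    a fixed random heading (tortuosity → 1 as noise → 0), diffusive tracks
    take isotropic Gaussian steps with the same mean step length, and
    stationary tracks stay put (plus optional localization noise).
    """
    if frames < 2:
        raise ValidationError("tracks need at least 2 frames")
    if motion not in ("directed", "diffusive", "stationary"):
        raise ValidationError(f"unknown motion model {motion!r}")
    rng = np.random.default_rng(seed)
    step_len = speed * frame_interval
    out = []
    for t in range(n_tracks):
        start = rng.uniform(0, 50, 2)
        if motion == "directed":
            ang = rng.uniform(0, 2 * math.pi)
            heading = np.array([math.cos(ang), math.sin(ang)])
            steps = np.tile(heading * step_len, (frames - 1, 1))
        elif motion == "diffusive":
            sigma = step_len / math.sqrt(math.pi / 2.0)  # mean step length = step_len
            steps = rng.normal(0.0, sigma, (frames - 1, 2))
        else:
            steps = np.zeros((frames - 1, 2))
        pts = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if noise_um > 0:
            pts = pts + rng.normal(0.0, noise_um, pts.shape)
        out.append(
            Track(points=pts, frames=np.arange(frames),
                  frame_interval=frame_interval, track_id=f"{motion}{t}")
        )
    return out


__all__ = [
    "InfeasiblePlacementError",
    "ScaffoldParams",
    "OrganelleSpec",
    "InteractionSpec",
    "GroundTruth",
    "generate_cell",
    "preset",
    "generate_tracks",
]
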