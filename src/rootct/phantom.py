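"""Synthetic undisturbed-soil CT phantoms with voxel-accurate ground truth.

The generator emulates the obstacles that make root segmentation in field
cores hard: partial-volume ("mixed") voxels from Gaussian blur at material
interfaces, organic debris with root-like gray values, root systems that are
*not* connected (cut segments from several plants in one core), inhomogeneous
moisture as a gray drift, and an optional container wall.

Roots are random-walk tubes with gentle taper and optional branching,
rasterised with 3x supersampling (a voxel is root when at least half of its
27 sub-samples fall inside the tube).  Mineral aggregates are overlapping
random ellipsoids grown to a target fill fraction.  Per-voxel Gaussian class
noise is applied before the blur, and all truth masks come from the
pre-noise rasterisation, so the ground truth is exact by construction.

Gray-value ordering follows soil CT practice: air < (water) < roots < minerals,
with PVC container walls close to the mineral level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ROIMask, VoxelVolume
from .surface import MaterialExample

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "phantom_series",
    "example_coordinates",
]

_MARGIN = 3          # voxels kept clear of the grid faces
_ROOT_CLEARANCE = 3  # voxels between unconnected roots / debris and roots

_DEFAULT_GRAY_MEANS = {"air": 5000.0, "water": 12000.0, "root": 18000.0,
                       "mineral": 45000.0, "wall": 43000.0}
_DEFAULT_GRAY_SDS = {"air": 1500.0, "water": 1500.0, "root": 1500.0,
                     "mineral": 1500.0, "wall": 1500.0}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic soil-core phantom.

    Defaults describe a moist loamy core at 0.05 mm voxels: three unconnected
    root segments of 0.25-0.5 mm radius, mineral aggregates filling half the
    volume, twenty sub-filter-size organic debris blobs, and a one-voxel
    partial-volume blur.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: float = 0.05
    n_roots: int = 3
    root_radius_range_mm: tuple[float, float] = (0.25, 0.5)
    root_taper: float = 0.02              # radius fraction lost per mm of length
    branching_probability: float = 0.0    # branches per mm of centerline
    roots_connected: bool = False
    mineral_fill_fraction: float = 0.5
    aggregate_radius_range_mm: tuple[float, float] = (0.2, 0.6)
    n_debris: int = 20
    debris_size_range_voxels: tuple[int, int] = (50, 2000)
    gray_means: dict = field(default_factory=lambda: dict(_DEFAULT_GRAY_MEANS))
    gray_sds: dict = field(default_factory=lambda: dict(_DEFAULT_GRAY_SDS))
    blur_sigma_voxels: float = 1.0
    moisture_gradient: float = 0.0        # total pore gray drift over the z extent
    container_wall: str = "none"          # none | pvc_like | pe_like
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError(f"phantom shape must be at least 32^3, got {self.shape}")
        if self.mineral_fill_fraction > 0.9:
            raise ValueError("mineral fill fraction above 0.9 is infeasible")
        gm = self.gray_means
        if not gm["air"] < gm["root"] < gm["mineral"]:
            raise ValueError("gray means must be ordered air < root < mineral")
        if self.container_wall not in ("none", "pvc_like", "pe_like"):
            raise ValueError(f"unknown container_wall: {self.container_wall}")


@dataclass
class PhantomTruth:
    """Exact ground truth of a phantom: masks, root volume and diameter profile."""

    root_mask: ROIMask
    mineral_mask: ROIMask
    debris_mask: ROIMask
    root_volume_mm3: float
    centerlines: list            # one dict per root: points (n,3), radii_voxels (n,)
    surface_histogram: pd.DataFrame
    wall_mask: ROIMask | None = None


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _walk_centerline(rng, start, direction, r0_vox, spec, nz_stop) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk tube centerline from ``start`` until it leaves the core."""
    shape = np.asarray(spec.shape, float)
    taper_per_vox = spec.root_taper * spec.voxel_size_mm
    pts, radii = [np.asarray(start, float)], [r0_vox]
    d = _unit(np.asarray(direction, float))
    r = r0_vox
    for step in range(int(4 * shape[0])):
        d = _unit(d + rng.normal(0.0, 0.06, 3) + np.array([0.02, 0.0, 0.0]))
        p = pts[-1] + d
        r = max(r0_vox * 0.3, r * (1.0 - taper_per_vox))
        if (p < _MARGIN).any() or (p > shape - 1 - _MARGIN).any() or p[0] >= nz_stop:
            break
        pts.append(p)
        radii.append(r)
    return np.array(pts), np.array(radii)


def _densify(pts: np.ndarray, radii: np.ndarray, ds: float = 0.25):
    """Resample a polyline (and its radius profile) at ``ds``-voxel spacing."""
    if len(pts) < 2:
        return pts, radii
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    snew = np.arange(0.0, s[-1] + ds / 2, ds)
    dense = np.stack([np.interp(snew, s, pts[:, k]) for k in range(3)], axis=1)
    rdense = np.interp(snew, s, radii)
    return dense, rdense


def _rasterize_tubes(samples: np.ndarray, radii: np.ndarray, shape) -> np.ndarray:
    """Supersampled (3x, >=50 % rule) rasterisation of a union of tube samples."""
    mask = np.zeros(shape, bool)
    if len(samples) == 0:
        return mask
    tree = cKDTree(samples)
    rmax = float(radii.max())
    lo = np.maximum(np.floor(samples.min(axis=0) - rmax - 1).astype(int), 0)
    hi = np.minimum(np.ceil(samples.max(axis=0) + rmax + 2).astype(int), shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    d, i = tree.query(centers, k=1)
    signed = d - radii[i]
    # half the sub-voxel cube diagonal: beyond it the 27-sample vote is decided
    sub_margin = np.sqrt(3.0) / 3.0
    inside = signed <= -sub_margin
    band = np.abs(signed) < sub_margin
    if band.any():
        offs = np.array(np.meshgrid(*[(-1 / 3, 0, 1 / 3)] * 3, indexing="ij")).reshape(3, -1).T
        votes = np.zeros(int(band.sum()), int)
        bandpts = centers[band]
        for o in offs:
            dd, ii = tree.query(bandpts + o, k=1)
            votes += (dd <= radii[ii]).astype(int)
        inside_band = votes >= 14  # at least half of the 27 sub-samples
        inside = inside.copy()
        inside[np.nonzero(band)[0][~inside_band]] = False
        inside[np.nonzero(band)[0][inside_band]] = True
    sel = centers[inside].astype(int)
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def _make_roots(rng, spec: PhantomSpec):
    """Generate root centerlines + masks; unconnected roots keep a clearance gap."""
    shape = spec.shape
    vs = spec.voxel_size_mm
    r_lo, r_hi = (r / vs for r in spec.root_radius_range_mm)
    if r_lo < 1.0:
        warnings.warn("root radius below one voxel; clamping to 1 voxel", stacklevel=3)
        r_lo = max(r_lo, 1.0)
        r_hi = max(r_hi, 1.0)
    union = np.zeros(shape, bool)
    centerlines = []
    crown = np.array([_MARGIN + 1.0,
                      shape[1] / 2.0, shape[2] / 2.0])
    for k in range(spec.n_roots):
        for attempt in range(30):
            if spec.roots_connected:
                start = crown + rng.normal(0, 0.5, 3)
                start[0] = crown[0]
            else:
                start = np.array([
                    rng.uniform(_MARGIN + 1, shape[0] * 0.3),
                    rng.uniform(shape[1] * 0.15, shape[1] * 0.85),
                    rng.uniform(shape[2] * 0.15, shape[2] * 0.85)])
            direction = np.array([1.0, rng.normal(0, 0.35), rng.normal(0, 0.35)])
            r0 = rng.uniform(r_lo, r_hi)
            pts, radii = _walk_centerline(rng, start, direction, r0, spec,
                                          nz_stop=shape[0] - _MARGIN)
            if len(pts) < max(10, shape[0] // 4):
                continue
            samples = [np.column_stack([pts, radii])]
            # optional branching: spawn side tubes at a per-mm rate
            if spec.branching_probability > 0:
                per_step = spec.branching_probability * vs
                for j in range(1, len(pts)):
                    if rng.uniform() < per_step:
                        bdir = _unit(rng.normal(0, 1, 3) + np.array([0.8, 0, 0]))
                        bpts, bradii = _walk_centerline(
                            rng, pts[j], bdir, radii[j] * 0.6, spec,
                            nz_stop=shape[0] - _MARGIN)
                        if len(bpts) >= 5:
                            samples.append(np.column_stack([bpts, bradii]))
            allpts = np.vstack([s[:, :3] for s in samples])
            allr = np.concatenate([s[:, 3] for s in samples])
            dense_pts, dense_r = [], []
            off = 0
            for s in samples:
                dp, dr = _densify(s[:, :3], s[:, 3])
                dense_pts.append(dp)
                dense_r.append(dr)
            dp = np.vstack(dense_pts)
            dr = np.concatenate(dense_r)
            cand = _rasterize_tubes(dp, dr, shape)
            if not cand.any():
                continue
            if not spec.roots_connected and union.any():
                grown = ndimage.binary_dilation(
                    cand, structure=np.ones((3, 3, 3), bool),
                    iterations=_ROOT_CLEARANCE)
                if (grown & union).any():
                    continue  # too close to an existing root: resample
            union |= cand
            centerlines.append({"points": allpts, "radii_voxels": allr,
                                "dense_points": dp, "dense_radii_voxels": dr})
            break
    return union, centerlines


def _random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q


def _paint_ellipsoid(mask: np.ndarray, center, semi_axes, rot) -> int:
    """Paint one rotated ellipsoid; returns the number of newly set voxels."""
    shape = mask.shape
    rmax = float(max(semi_axes))
    lo = np.maximum(np.floor(np.asarray(center) - rmax - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + rmax + 2).astype(int), shape)
    if (hi <= lo).any():
        return 0
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = rel @ rot
    q = (local / np.asarray(semi_axes)) ** 2
    inside = q.sum(axis=-1) <= 1.0
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    new = int((inside & ~sub).sum())
    sub |= inside
    return new


def _make_minerals(rng, spec: PhantomSpec, forbidden: np.ndarray) -> np.ndarray:
    """Overlapping random ellipsoids until the target fill fraction is reached."""
    shape = spec.shape
    vs = spec.voxel_size_mm
    a_lo, a_hi = (r / vs for r in spec.aggregate_radius_range_mm)
    mineral = np.zeros(shape, bool)
    total = int(np.prod(shape))
    target = int(spec.mineral_fill_fraction * total)
    painted = 0
    for _ in range(200_000):
        if painted >= target:
            break
        center = rng.uniform(_MARGIN, np.asarray(shape, float) - _MARGIN)
        axes = rng.uniform(a_lo, a_hi, 3)
        painted += _paint_ellipsoid(mineral, center, axes, _random_rotation(rng))
    mineral &= ~forbidden
    return mineral


def _make_debris(rng, spec: PhantomSpec, forbidden: np.ndarray) -> np.ndarray:
    """Small root-gray blobs in the pore space, below the size filter by default."""
    shape = spec.shape
    debris = np.zeros(shape, bool)
    s_lo, s_hi = spec.debris_size_range_voxels
    for _ in range(spec.n_debris):
        for attempt in range(20):
            size = rng.uniform(s_lo, s_hi)
            base = (size * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            aniso = np.exp(rng.normal(0, 0.3, 3))
            aniso /= aniso.prod() ** (1.0 / 3.0)
            axes = base * aniso
            center = rng.uniform(_MARGIN, np.asarray(shape, float) - _MARGIN)
            blob = np.zeros(shape, bool)
            _paint_ellipsoid(blob, center, axes, _random_rotation(rng))
            blob &= ~forbidden
            if blob.any():
                debris |= blob
                break
    return debris


def _make_wall(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    y, x = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    r_out = min(ny, nx) / 2.0 - 1.0
    ring = (rad <= r_out) & (rad > r_out - 3.0)
    return np.broadcast_to(ring[None], spec.shape).copy()


def _truth_surface_histogram(centerlines, voxel_size_mm: float) -> pd.DataFrame:
    """Analytic surface-diameter histogram: each centerline sample contributes
    a lateral surface patch 2*pi*r*ds weighted into its diameter bin."""
    bw = voxel_size_mm
    diam, weight = [], []
    for cl in centerlines:
        r = cl["dense_radii_voxels"]
        diam.append(2.0 * r * voxel_size_mm)
        weight.append(2.0 * np.pi * r * 0.25)
    if not diam:
        return pd.DataFrame(columns=["bin_low_mm", "bin_high_mm", "count", "frequency"])
    diam = np.concatenate(diam)
    weight = np.concatenate(weight)
    n_bins = int(np.ceil(diam.max() / bw)) + 1
    edges = np.arange(n_bins + 1) * bw
    counts, _ = np.histogram(diam, bins=edges, weights=weight)
    return pd.DataFrame({
        "bin_low_mm": edges[:-1], "bin_high_mm": edges[1:],
        "count": counts, "frequency": counts / counts.sum(),
    })


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Generate one phantom volume and its exact ground truth.

    Identical specs (including the seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    vs = spec.voxel_size_mm

    root, centerlines = _make_roots(rng, spec)

    wall = _make_wall(spec) if spec.container_wall != "none" else None
    if wall is not None:
        root &= ~wall

    # a thin air film separates roots from minerals and debris (rhizosphere gap)
    root_zone = ndimage.binary_dilation(root, np.ones((3, 3, 3), bool))
    forbidden = root_zone.copy()
    if wall is not None:
        forbidden |= wall
    mineral = _make_minerals(rng, spec, forbidden)

    debris_forbidden = (mineral | root_zone |
                        ndimage.binary_dilation(root, np.ones((3, 3, 3), bool),
                                                iterations=_ROOT_CLEARANCE))
    if wall is not None:
        debris_forbidden |= wall
    debris = _make_debris(rng, spec, debris_forbidden)

    gm, gs = spec.gray_means, spec.gray_sds
    mean_map = np.full(shape, gm["air"], np.float32)
    sd_map = np.full(shape, gs["air"], np.float32)
    if spec.moisture_gradient != 0.0:
        # inhomogeneous moisture: pore gray drifts linearly along depth
        drift = (np.arange(shape[0], dtype=np.float32) / max(shape[0] - 1, 1) - 0.5)
        mean_map += spec.moisture_gradient * drift[:, None, None]
    for m, cls in ((debris, "root"), (root, "root"), (mineral, "mineral")):
        mean_map[m] = gm[cls]
        sd_map[m] = gs[cls]
    if wall is not None:
        cls = "wall" if spec.container_wall == "pvc_like" else "water"
        mean_map[wall] = gm[cls]
        sd_map[wall] = gs[cls]

    gray = mean_map + rng.standard_normal(shape).astype(np.float32) * sd_map
    if spec.blur_sigma_voxels > 0:
        gray = ndimage.gaussian_filter(gray, spec.blur_sigma_voxels)
    data = np.clip(np.rint(gray), 0, 65535).astype(np.uint16)

    volume = VoxelVolume(data, vs, source_dtype="uint16")
    truth = PhantomTruth(
        root_mask=ROIMask(root, vs, label="root_truth"),
        mineral_mask=ROIMask(mineral, vs, label="mineral_truth"),
        debris_mask=ROIMask(debris, vs, label="debris_truth"),
        root_volume_mm3=float(root.sum()) * vs**3,
        centerlines=centerlines,
        surface_histogram=_truth_surface_histogram(centerlines, vs),
        wall_mask=None if wall is None else ROIMask(wall, vs, label="wall_truth"),
    )
    return volume, truth


def phantom_series(
    base_spec: PhantomSpec,
    n_volumes: int,
    root_content_gradient: int = 1,
    seed: int = 0,
) -> list[tuple[VoxelVolume, PhantomTruth]]:
    """Series of phantoms with strictly increasing ground-truth root volume.

    Root content grows by ``root_content_gradient`` roots per phantom; the
    per-phantom seeds derive deterministically from ``seed``.
    """
    if n_volumes < 3:
        raise ValueError("a series needs at least 3 volumes")
    out = []
    prev = -np.inf
    for i in range(n_volumes):
        n_roots = base_spec.n_roots + i * root_content_gradient
        for retry in range(20):
            s = (seed * 1_000_003 + i * 7_919 + retry * 104_729) % (2**31)
            spec_i = replace(base_spec, n_roots=n_roots, seed=s)
            vol, truth = generate_phantom(spec_i)
            if truth.root_volume_mm3 > prev:
                break
        prev = truth.root_volume_mm3
        out.append((vol, truth))
    return out


def _sample_coords(rng, mask: np.ndarray, n: int, erode: int) -> np.ndarray:
    """Sample ``n`` coordinates from a mask, eroded to avoid mixed voxels."""
    m = mask
    for e in range(erode, -1, -1):
        m = (ndimage.binary_erosion(mask, np.ones((3, 3, 3), bool), iterations=e)
             if e > 0 else mask)
        if m.sum() >= n:
            break
    coords = np.argwhere(m)
    if len(coords) == 0:
        raise ValueError("cannot sample example coordinates: class region is empty")
    pick = rng.choice(len(coords), size=min(n, len(coords)), replace=False)
    return coords[pick]


def example_coordinates(
    volume: VoxelVolume,
    truth: PhantomTruth,
    n: int = 200,
    seed: int = 0,
) -> tuple[MaterialExample, MaterialExample]:
    """Operator-style example areas drawn from phantom ground truth.

    Emulates clicking clearly identifiable voxels: pure pore air away from any
    interface (background), aggregate interiors (mineral material) and root
    interiors (root material).  Returns ``(soil_examples, root_examples)``
    ready for the five-step protocol; ``root_examples`` is None when the
    phantom contains no roots.
    """
    rng = np.random.default_rng(seed)
    occupied = truth.root_mask.data | truth.mineral_mask.data | truth.debris_mask.data
    if truth.wall_mask is not None:
        occupied |= truth.wall_mask.data
    air = ~occupied
    air[: _MARGIN] = air[-_MARGIN:] = False
    air_coords = _sample_coords(rng, air, n, erode=2)
    mineral_coords = _sample_coords(rng, truth.mineral_mask.data, n, erode=2)
    soil = MaterialExample.from_volume(volume, air_coords, mineral_coords)
    if not truth.root_mask.data.any():
        return soil, None
    root_coords = _sample_coords(rng, truth.root_mask.data, n, erode=1)
    roots = MaterialExample.from_volume(volume, air_coords, root_coords)
    return soil, roots
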