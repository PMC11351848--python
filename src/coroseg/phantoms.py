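"""Synthetic cardiac phantoms with exact ground truth.

The phantoms emulate the structure the pipeline targets in contrast-enhanced
CTA at desk scale: a bright ellipsoidal "heart" containing thin, brighter
tubular trees (coronary stand-ins, radii of a few voxels) against a darker
background, plus Gaussian acquisition noise. Each phantom comes with paired
binary truths for both cascade stages (heart mask, vessel-tree mask), so
every stage — preprocessing, vesselness, training, the full cascade — can be
exercised and scored without external data.

Intensity ordering is fixed: background < heart < vessels, mirroring
contrast-filled arteries being the brightest soft-tissue structure in CTA.
Trees are built from straight cylindrical segments joined at nodes; there is
no curvature model. Geometry is voxelized by exact distance-to-centerline
tests, so mask volumes converge to the analytic cylinder/sphere/slab volumes
as radii grow.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .volume import Mask, Volume, write_volume

__all__ = [
    "PhantomSpec",
    "TubeSegment",
    "make_tube",
    "make_blob",
    "make_plate",
    "make_cardiac_phantom",
    "make_dataset",
]

Point = Tuple[float, float, float]


@dataclass(frozen=True)
class TubeSegment:
    """A straight cylindrical segment: endpoints in (z, y, x) voxels."""

    start: Point
    end: Point
    radius: float


@dataclass
class PhantomSpec:
    """Geometry and intensity recipe for one cardiac phantom.

    Intensities must be ordered background < heart < vessel. All geometry is
    in voxel units on an isotropic grid of edge ``size``.
    """

    size: int = 64
    heart_center: Point = (32.0, 32.0, 32.0)
    heart_axes: Point = (22.0, 24.0, 24.0)
    background_intensity: float = 0.05
    heart_intensity: float = 0.5
    vessel_intensity: float = 0.78
    vessels: List[TubeSegment] = field(default_factory=list)
    vessel_radius_range: Tuple[float, float] = (2.0, 4.0)
    vessel_profile: str = "flat"
    noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.background_intensity < self.heart_intensity < self.vessel_intensity
        ):
            raise ValueError(
                "intensities must be ordered background < heart < vessel, got "
                f"{self.background_intensity}, {self.heart_intensity}, "
                f"{self.vessel_intensity}"
            )
        if self.vessel_profile not in ("gaussian", "flat"):
            raise ValueError(
                f"vessel_profile must be 'gaussian' or 'flat', got "
                f"{self.vessel_profile!r}"
            )
        for seg in self.vessels:
            _check_tube_in_grid((self.size,) * 3, seg)


def _grid(shape: Tuple[int, int, int]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        np.arange(shape[2], dtype=np.float64),
        indexing="ij",
    )


def _check_tube_in_grid(shape: Tuple[int, int, int], seg: TubeSegment) -> None:
    if seg.radius < 1.0:
        raise ValueError(f"tube radius must be >= 1 voxel, got {seg.radius}")
    for p in (seg.start, seg.end):
        for coord, n in zip(p, shape):
            if coord - seg.radius < -0.5 or coord + seg.radius > n - 0.5:
                raise ValueError(
                    f"tube endpoint {p} with radius {seg.radius} exceeds grid {shape}"
                )


def _segment_distance(
    shape: Tuple[int, int, int], seg: TubeSegment
) -> np.ndarray:
    """Per-voxel Euclidean distance to the segment's centerline."""
    zz, yy, xx = _grid(shape)
    p = np.stack([zz, yy, xx], axis=-1)
    a = np.asarray(seg.start, dtype=np.float64)
    b = np.asarray(seg.end, dtype=np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def make_tube(
    size: int | Tuple[int, int, int],
    segment: TubeSegment | None = None,
    *,
    axis: int | None = None,
    radius: float | None = None,
    contrast: float = 1.0,
    gaussian_profile: bool = False,
) -> Tuple[Volume, Mask]:
    """Voxelize one cylindrical tube; returns (intensity volume, mask).

    Pass either an explicit ``segment`` or ``axis``+``radius`` for a
    grid-spanning cylinder through the centre along that axis (0=z, 1=y,
    2=x). The mask is the set of voxels within ``radius`` of the
    centerline; intensity is ``contrast`` inside (optionally a Gaussian
    radial profile of sigma = radius) and 0 outside.
    """
    shape = (size,) * 3 if isinstance(size, int) else tuple(size)
    if segment is None:
        if axis is None or radius is None:
            raise ValueError("provide a TubeSegment or axis and radius")
        # integer-centre tube: keeps the voxelized cross-section close to
        # the analytic disc area (off-lattice centres overcount)
        centre = [float(n // 2) for n in shape]
        start, end = list(centre), list(centre)
        start[axis] = 0.0
        end[axis] = shape[axis] - 1.0
        segment = TubeSegment(tuple(start), tuple(end), radius)
        # a spanning tube touches the axis-aligned faces by design; only
        # check the cross-sectional extent
        for ax_ in range(3):
            if ax_ == axis:
                continue
            if centre[ax_] - radius < -0.5 or centre[ax_] + radius > shape[ax_] - 0.5:
                raise ValueError("tube radius exceeds grid cross-section")
        if radius < 1.0:
            raise ValueError(f"tube radius must be >= 1 voxel, got {radius}")
    else:
        _check_tube_in_grid(shape, segment)

    d = _segment_distance(shape, segment)
    mask = (d <= segment.radius).astype(np.uint8)
    if gaussian_profile:
        vol_data = contrast * np.exp(-(d**2) / (2.0 * segment.radius**2)) * mask
    else:
        vol_data = contrast * mask.astype(np.float64)
    return Volume(data=vol_data), Mask(data=mask)


def make_blob(
    size: int | Tuple[int, int, int],
    center: Point | None = None,
    radius: float = 5.0,
    contrast: float = 1.0,
) -> Tuple[Volume, Mask]:
    """Voxelized sphere with exact analytic mask."""
    shape = (size,) * 3 if isinstance(size, int) else tuple(size)
    if center is None:
        center = tuple(float(n // 2) for n in shape)
    for coord, n in zip(center, shape):
        if coord - radius < -0.5 or coord + radius > n - 0.5:
            raise ValueError(f"sphere of radius {radius} at {center} exceeds {shape}")
    zz, yy, xx = _grid(shape)
    d = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    mask = (d <= radius).astype(np.uint8)
    return Volume(data=contrast * mask.astype(np.float64)), Mask(data=mask)


def make_plate(
    size: int | Tuple[int, int, int],
    axis: int = 0,
    thickness: int = 3,
    contrast: float = 1.0,
) -> Tuple[Volume, Mask]:
    """Grid-spanning slab of integer thickness centred on the mid-plane."""
    shape = (size,) * 3 if isinstance(size, int) else tuple(size)
    if thickness < 1 or thickness > shape[axis]:
        raise ValueError(f"slab thickness {thickness} outside grid axis {shape[axis]}")
    lo = (shape[axis] - thickness) // 2
    mask = np.zeros(shape, dtype=np.uint8)
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, lo + thickness)
    mask[tuple(sl)] = 1
    return Volume(data=contrast * mask.astype(np.float64)), Mask(data=mask)


def _default_tree(
    rng: np.random.Generator,
    center: Point,
    axes: Point,
    radius_range: Tuple[float, float],
    size: int,
) -> List[TubeSegment]:
    """A branching tree of straight segments inside the ellipsoid.

    Real coronary trees course from the heart base toward the apex, so
    nearly every axial slice of a heart ROI intersects some vessel. The
    default tree mirrors that: a long main trunk spanning most of the
    heart's z-extent, a shorter secondary trunk on the other side, and
    branches peeling off laterally.
    """
    c = np.asarray(center)
    ax = np.asarray(axes)

    def inside(p: np.ndarray, margin: float) -> bool:
        rel = (p - c) / (ax - margin)
        in_ellipsoid = float(rel @ rel) <= 1.0
        in_grid = bool(
            np.all(p - margin >= 0.0) and np.all(p + margin <= size - 1.0)
        )
        return in_ellipsoid and in_grid

    def polar_point(z_rel: float, margin: float) -> np.ndarray:
        """A point near relative height z_rel with lateral jitter that keeps
        it inside the ellipsoid (with margin)."""
        for _ in range(200):
            p = c + np.array(
                [
                    z_rel * ax[0],
                    rng.uniform(-0.3, 0.3) * ax[1],
                    rng.uniform(-0.3, 0.3) * ax[2],
                ]
            )
            if inside(p, margin):
                return p
        return c + np.array([z_rel * ax[0] * 0.9, 0.0, 0.0])  # pragma: no cover

    segments: List[TubeSegment] = []
    lo, hi = radius_range
    r_trunk = rng.uniform(max(lo, 0.6 * hi), hi)
    start = polar_point(-rng.uniform(0.72, 0.82), r_trunk + 1)
    end = polar_point(+rng.uniform(0.72, 0.82), r_trunk + 1)
    segments.append(TubeSegment(tuple(start), tuple(end), r_trunk))

    r_second = rng.uniform(lo, r_trunk)
    start2 = polar_point(-rng.uniform(0.45, 0.6), r_second + 1)
    end2 = polar_point(+rng.uniform(0.45, 0.6), r_second + 1)
    segments.append(TubeSegment(tuple(start2), tuple(end2), r_second))

    # lateral branches from points along the main trunk
    for frac in (0.3, 0.6, 0.85):
        node = start + frac * (end - start)
        r_branch = max(lo, r_trunk * rng.uniform(0.6, 0.85))
        for _ in range(200):
            direction = rng.normal(size=3)
            direction[0] *= 0.3  # mostly lateral
            direction /= np.linalg.norm(direction)
            length = rng.uniform(0.35, 0.6) * float(np.min(ax))
            tip = node + direction * length
            if inside(tip, r_branch + 1):
                segments.append(TubeSegment(tuple(node), tuple(tip), r_branch))
                break
    return segments


def make_cardiac_phantom(
    spec: PhantomSpec | None = None,
) -> Tuple[Volume, Mask, Mask]:
    """Composite phantom: (noisy volume, heart mask, vessel mask).

    Composition order is vessels over heart over background; Gaussian noise
    of sd ``spec.noise_sd`` is added afterwards (seeded). With an empty
    ``spec.vessels`` list a default branching tree is generated from the
    spec's seed.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size,) * 3

    zz, yy, xx = _grid(shape)
    c, ax = spec.heart_center, spec.heart_axes
    heart = (
        ((zz - c[0]) / ax[0]) ** 2
        + ((yy - c[1]) / ax[1]) ** 2
        + ((xx - c[2]) / ax[2]) ** 2
        <= 1.0
    ).astype(np.uint8)

    vessels = spec.vessels or _default_tree(
        rng, spec.heart_center, spec.heart_axes, spec.vessel_radius_range, spec.size
    )
    vessel_mask = np.zeros(shape, dtype=np.uint8)
    # partial-volume-like rendering: peak contrast on the centerline falling
    # off toward the lumen boundary (sigma = r/2), as thin vessels appear in
    # CT; "flat" renders hard binary-intensity tubes instead
    lumen_weight = np.zeros(shape, dtype=np.float64)
    for seg in vessels:
        d = _segment_distance(shape, seg)
        vessel_mask |= (d <= seg.radius).astype(np.uint8)
        if spec.vessel_profile == "gaussian":
            w = np.exp(-(d**2) / (2.0 * (seg.radius / 2.0) ** 2))
        else:
            w = (d <= seg.radius).astype(np.float64)
        np.maximum(lumen_weight, w, out=lumen_weight)

    data = np.full(shape, spec.background_intensity, dtype=np.float64)
    data[heart == 1] = spec.heart_intensity
    data += (spec.vessel_intensity - data) * lumen_weight
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, shape)

    return (
        Volume(data=data),
        Mask(data=heart),
        Mask(data=vessel_mask),
    )


def make_dataset(
    n_cases: int,
    out_dir: str | os.PathLike,
    *,
    size: int = 64,
    seed: int = 0,
    noise_sd: float = 0.08,
    radius_range: Tuple[float, float] = (2.0, 4.0),
) -> dict:
    """Write ``n_cases`` phantom cases (NIfTI triplets) plus a manifest.

    Each case directory holds ``volume.nii.gz``, ``heart.nii.gz`` and
    ``vessels.nii.gz``; geometry is randomized per case within the given
    ranges. The JSON manifest lists case ids and per-case seeds so an 80/20
    case-level split can be formed downstream. The same call is
    byte-reproducible for a fixed seed.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases to allow a train/validation split")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest = {"seed": seed, "size": size, "cases": []}
    for i in range(n_cases):
        case_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(case_seed)
        centre = size / 2.0 + rng.uniform(-3, 3, 3)
        axes = np.array([0.34, 0.37, 0.37]) * size * rng.uniform(0.92, 1.08, 3)
        spec = PhantomSpec(
            size=size,
            heart_center=tuple(centre),
            heart_axes=tuple(axes),
            vessel_radius_range=radius_range,
            noise_sd=noise_sd,
            seed=case_seed,
        )
        vol, heart, vessel = make_cardiac_phantom(spec)
        case_id = f"case_{i:03d}"
        case_dir = os.path.join(out_dir, case_id)
        os.makedirs(case_dir, exist_ok=True)
        write_volume(vol, os.path.join(case_dir, "volume.nii.gz"))
        write_volume(heart, os.path.join(case_dir, "heart.nii.gz"))
        write_volume(vessel, os.path.join(case_dir, "vessels.nii.gz"))
        manifest["cases"].append(
            {
                "id": case_id,
                "seed": case_seed,
                "radius_range": list(radius_range),
                "noise_sd": noise_sd,
            }
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
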