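"""Synthetic voxel stacks with known ground truth.

The paper-style confocal data (a quasi-spherical main colony, a handful of
small detached satellites, additive sensor noise and isolated bright speckle)
are emulated so the morphology pipeline can be validated without any
experimental images.  Default scales follow the colonies the pipeline is
meant for: main-colony volumes of order 10^5 um^3, satellite volumes well
below 10^3 um^3 and satellite centre-of-mass distances of order 100 um.

Also hosts the bridge from simulated lattices to the imaging pipeline
(:func:`lattice_to_stack` / :func:`stack_to_sites`): a site list becomes a
padded binary stack whose origin metadata makes the round trip the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .morphology import VoxelStack

__all__ = [
    "Satellite",
    "FixtureSpec",
    "TruthObject",
    "FixtureTruth",
    "make_stack",
    "random_fixture_spec",
    "lattice_to_stack",
    "stack_to_sites",
]


@dataclass(frozen=True)
class Satellite:
    """A spherical satellite: centre (z, y, x) in um, radius in um."""

    center: tuple
    radius: float
    intensity: float = 200.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic grayscale stack.

    The main colony is an axis-aligned ellipsoid; satellites are spheres.
    All geometry is physical (um, (z, y, x) order).  ``noise_sd`` is the SD
    of the additive Gaussian intensity noise; ``speckle_rate`` plants
    isolated single bright voxels (clusters far below the 11 um^3 noise
    filter) at that per-voxel rate.
    """

    shape: tuple = (256, 256, 256)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    main_center: Optional[tuple] = None  # um; default: stack centre
    main_semiaxes: Optional[tuple] = (30.0, 33.0, 36.0)  # um; None: no main object
    main_intensity: float = 200.0
    satellites: tuple = ()
    background: float = 20.0
    noise_sd: float = 18.0
    speckle_rate: float = 1e-5
    speckle_intensity: float = 200.0
    seed: int = 0

    def resolved_main_center(self) -> tuple:
        if self.main_center is not None:
            return tuple(float(c) for c in self.main_center)
        return tuple(s * v / 2.0 for s, v in zip(self.shape, self.voxel_size))


@dataclass(frozen=True)
class TruthObject:
    """Ground truth for one planted object."""

    kind: str  # "main" | "satellite"
    n_voxels: int
    volume: float  # um^3
    com: tuple  # (z, y, x) physical um


@dataclass
class FixtureTruth:
    """Noise-free ground truth derived deterministically from the spec."""

    mask: np.ndarray  # boolean foreground of the planted objects (no speckle)
    objects: list  # TruthObject, main first
    n_speckle: int

    def expected_object_count(self, min_volume: float = 11.0) -> int:
        """Planted objects that survive a ``min_volume`` um^3 filter."""
        return sum(1 for o in self.objects if o.volume >= min_volume)


def _rasterize_ellipsoid(shape, voxel_size, center, semiaxes):
    """Voxels whose centre lies inside the analytic ellipsoid.

    Returns ``(bbox_slices, bbox_mask)``; evaluation is restricted to the
    ellipsoid's bounding box so large stacks stay cheap.
    """
    slices = []
    for n, v, c, a in zip(shape, voxel_size, center, semiaxes):
        lo = max(int(np.floor((c - a) / v - 0.5)), 0)
        hi = min(int(np.ceil((c + a) / v - 0.5)) + 1, n)
        if hi <= lo:
            return tuple(slice(0, 0) for _ in shape), np.zeros((0, 0, 0), dtype=bool)
        slices.append(slice(lo, hi))
    axes = [
        (np.arange(sl.start, sl.stop) + 0.5) * v
        for sl, v in zip(slices, voxel_size)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((xx - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0
    return tuple(slices), mask


def _boxes_gap(a: tuple, b: tuple) -> int:
    """Minimum index gap between two bounding boxes (0 when they touch/overlap)."""
    gap = 0
    for sa, sb in zip(a, b):
        if sa.stop <= sb.start:
            gap = max(gap, sb.start - sa.stop)
        elif sb.stop <= sa.start:
            gap = max(gap, sa.start - sb.stop)
    return gap


def make_stack(spec: FixtureSpec) -> tuple:
    """Render a fixture spec into ``(VoxelStack, FixtureTruth)``.

    A voxel is foreground when its centre lies inside the analytic solid.
    Objects must not overlap or touch (checked after rasterisation with a
    one-voxel clearance, naming the offending pair).  Identical specs give
    identical stacks bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    vs = tuple(float(v) for v in spec.voxel_size)
    vv = float(np.prod(vs))
    center = spec.resolved_main_center()

    boxes = []
    names = []
    if spec.main_semiaxes is not None:
        boxes.append(_rasterize_ellipsoid(shape, vs, center, spec.main_semiaxes))
        names.append("main")
    for i, sat in enumerate(spec.satellites):
        boxes.append(
            _rasterize_ellipsoid(
                shape, vs, sat.center, (sat.radius, sat.radius, sat.radius)
            )
        )
        names.append(f"satellite[{i}]")

    # pairwise clearance: objects must stay >= 2 voxels apart (Chebyshev) so
    # they can never merge under 26-connectivity
    structure = np.ones((3, 3, 3), dtype=bool)
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if _boxes_gap(boxes[i][0], boxes[j][0]) >= 2:
                continue
            lo = [min(a.start, b.start) for a, b in zip(boxes[i][0], boxes[j][0])]
            hi = [max(a.stop, b.stop) for a, b in zip(boxes[i][0], boxes[j][0])]
            sub_i = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=bool)
            sub_j = np.zeros_like(sub_i)
            sl_i = tuple(
                slice(s.start - l, s.stop - l) for s, l in zip(boxes[i][0], lo)
            )
            sl_j = tuple(
                slice(s.start - l, s.stop - l) for s, l in zip(boxes[j][0], lo)
            )
            sub_i[sl_i] = boxes[i][1]
            sub_j[sl_j] = boxes[j][1]
            if np.any(ndimage.binary_dilation(sub_i, structure=structure) & sub_j):
                raise ValueError(
                    f"fixture objects {names[i]} and {names[j]} overlap or touch"
                )

    values = np.full(shape, spec.background, dtype=np.float32)
    foreground = np.zeros(shape, dtype=bool)
    intensities = [spec.main_intensity] * (len(boxes) - len(spec.satellites)) + [
        s.intensity for s in spec.satellites
    ]
    truth_objects = []
    for (sl, mask), name, inten in zip(boxes, names, intensities):
        coords = np.argwhere(mask)
        if coords.size == 0:
            raise ValueError(f"fixture object {name} rasterised to zero voxels")
        sub = values[sl]
        sub[mask] = inten
        foreground[sl] |= mask
        offset = np.array([s.start for s in sl], dtype=np.int64)
        com = tuple((coords + offset + 0.5).mean(axis=0) * np.asarray(vs))
        truth_objects.append(
            TruthObject(
                kind="main" if name == "main" else "satellite",
                n_voxels=len(coords),
                volume=len(coords) * vv,
                com=com,
            )
        )

    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal(shape, dtype=np.float32)

    # isolated bright voxels: far below the small-cluster filter, at least
    # one empty voxel away from any object and from each other
    n_speckle = 0
    if spec.speckle_rate > 0:
        n_target = int(round(spec.speckle_rate * float(np.prod(shape))))
        attempts = 0
        while n_speckle < n_target and attempts < 50 * max(n_target, 1):
            attempts += 1
            pos = tuple(int(rng.integers(1, s - 1)) for s in shape)
            neighborhood = foreground[
                pos[0] - 1 : pos[0] + 2,
                pos[1] - 1 : pos[1] + 2,
                pos[2] - 1 : pos[2] + 2,
            ]
            if neighborhood.any():
                continue
            values[pos] = spec.speckle_intensity
            foreground[pos] = True  # reserve: keeps later speckles isolated
            n_speckle += 1
        # drop the speckle reservations from the truth mask
        foreground = np.zeros(shape, dtype=bool)
        for (sl, mask) in boxes:
            foreground[sl] |= mask

    stack = VoxelStack(values, voxel_size=vs)
    truth = FixtureTruth(mask=foreground, objects=truth_objects, n_speckle=n_speckle)
    return stack, truth


def random_fixture_spec(
    seed: int,
    n_satellites: int = 5,
    satellite_radius: tuple = (2.5, 4.0),
    satellite_distance: tuple = (80.0, 125.0),
    **overrides,
) -> FixtureSpec:
    """Place satellites at random directions/distances around the main colony.

    Satellite centres are drawn uniformly on the sphere at distances drawn
    uniformly from ``satellite_distance`` (um from the main centre), rejecting
    placements that would overlap the main colony, another satellite, or
    leave the stack.  Deterministic given ``seed``.
    """
    base = FixtureSpec(seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    center = np.asarray(base.resolved_main_center())
    extent = np.asarray(base.shape) * np.asarray(base.voxel_size)
    clearance = max(base.main_semiaxes)
    sats: list[Satellite] = []
    guard = 0
    while len(sats) < n_satellites:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("could not place satellites without overlap")
        radius = float(rng.uniform(*satellite_radius))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = float(rng.uniform(*satellite_distance))
        pos = center + direction * dist
        if dist < clearance + radius + 3:
            continue
        if np.any(pos - radius < 2) or np.any(pos + radius > extent - 2):
            continue
        if any(
            np.linalg.norm(pos - np.asarray(s.center)) < radius + s.radius + 3
            for s in sats
        ):
            continue
        sats.append(Satellite(center=tuple(float(p) for p in pos), radius=radius))
    return replace(base, satellites=tuple(sats))


def lattice_to_stack(
    sites: np.ndarray, pad: int = 2, voxel_size: float = 1.0
) -> VoxelStack:
    """Binary stack from an (n, 3) site list (x, y, z columns), cropped to
    the bounding box plus a ``pad``-voxel empty margin.

    The stack origin records the crop offset so
    ``stack_to_sites(lattice_to_stack(s))`` returns ``s`` (sorted).
    """
    sites = np.asarray(sites, dtype=np.int64).reshape(-1, 3)
    if len(sites) == 0:
        raise ValueError("empty site list")
    if pad < 1:
        raise ValueError("pad must be >= 1")
    zyx = sites[:, ::-1]
    mins = zyx.min(axis=0) - pad
    maxs = zyx.max(axis=0) + pad
    shape = tuple(int(s) for s in (maxs - mins + 1))
    values = np.zeros(shape, dtype=bool)
    rel = zyx - mins
    values[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    vs = (float(voxel_size),) * 3
    origin = tuple(float(m) * voxel_size for m in mins)
    return VoxelStack(values, voxel_size=vs, origin=origin)


def stack_to_sites(stack: VoxelStack) -> np.ndarray:
    """Inverse of :func:`lattice_to_stack`: foreground voxels as (x, y, z)
    integer sites in the original lattice frame, lexicographically sorted."""
    if not stack.is_binary:
        raise ValueError("stack_to_sites requires a binary stack")
    offset = np.array(
        [round(o / v) for o, v in zip(stack.origin, stack.voxel_size)], dtype=np.int64
    )
    zyx = np.argwhere(stack.values) + offset
    sites = zyx[:, ::-1]
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    return sites[order]
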