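"""3D colony-morphology quantification.

Reimplements the BiofilmQ-style analysis chain applied to confocal z-stacks
of gel-embedded colonies and, identically, to simulated lattices: Otsu
thresholding (skipped for binary input), removal of connected components
smaller than a volume cutoff (11 um^3 by default), connected-component
labelling, and per-object metrics — volume, centre of mass, convexity
(solidity), satellite count, satellite-to-main centre-of-mass distances and
nearest-neighbour objects.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` (TIFF page order); ``voxel_size`` is aligned
with the array axes, i.e. ``(dz, dy, dx)`` in um/voxel.  Voxel *centres* sit
at ``(index + 0.5) * voxel_size + origin`` and all distances, centres of mass
and hull volumes are physical (um).  A "satellite" is any connected component
other than the largest one — i.e. a cluster completely detached from the main
colony under the chosen connectivity (26 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelStack",
    "LabeledObjects",
    "ObjectMetrics",
    "MorphologyReport",
    "PipelineConfig",
    "otsu_threshold",
    "remove_small_components",
    "label_components",
    "component_metrics",
    "satellite_statistics",
    "crop_half",
    "analyze",
]

_CONNECTIVITY_TO_RANK = {6: 1, 18: 2, 26: 3}

#: Objects with at most this many voxels get convexity 1 by definition
#: (their 3D convex hull is degenerate or meaninglessly small).
DEGENERATE_HULL_MAX_VOXELS = 4

_AXIS_NAMES = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class VoxelStack:
    """A 3D image: intensity (grayscale) or boolean (binary) voxel array.

    ``values`` has axes (z, y, x); ``voxel_size`` and ``origin`` are aligned
    with those axes, in um.
    """

    values: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.values.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size[0] * self.voxel_size[1] * self.voxel_size[2]

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool

    def with_values(self, values: np.ndarray) -> "VoxelStack":
        return VoxelStack(values, self.voxel_size, self.origin)


@dataclass
class LabeledObjects:
    """Connected components of a binary stack.

    Labels are renumbered deterministically: object 1 holds the smallest
    linear (z, y, x raster) voxel index, object 2 the next, and so on.
    """

    labels: np.ndarray
    object_ids: np.ndarray
    connectivity: int
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)


@dataclass
class ObjectMetrics:
    """Physical metrics of one labelled object."""

    id: int
    n_voxels: int
    volume: float  # um^3
    com: tuple  # (z, y, x) physical, um
    convexity: float  # volume / convex hull volume
    degenerate_hull: bool = False

    @property
    def com_xyz(self) -> tuple:
        return (self.com[2], self.com[1], self.com[0])


@dataclass
class MorphologyReport:
    """Colony-level summary: main object, satellites, distances, volumes."""

    objects: list
    main_id: Optional[int]
    n_satellites: int
    satellite_ids: list
    satellite_volumes: list  # um^3
    com_distances: list  # um, satellite COM -> main COM, parallel to satellite_ids
    nearest_neighbor: dict  # object id -> (other id, COM distance um)
    total_volume: float  # um^3
    main_volume: float  # um^3
    convexity_main: Optional[float] = None

    @property
    def main_fraction(self) -> float:
        """Share of the total filtered volume held by the main colony."""
        return self.main_volume / self.total_volume if self.total_volume > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "main_id": self.main_id,
            "n_satellites": self.n_satellites,
            "satellite_ids": list(map(int, self.satellite_ids)),
            "satellite_volumes": list(map(float, self.satellite_volumes)),
            "com_distances": list(map(float, self.com_distances)),
            "nearest_neighbor": {
                int(k): [int(v[0]), float(v[1])] for k, v in self.nearest_neighbor.items()
            },
            "total_volume": float(self.total_volume),
            "main_volume": float(self.main_volume),
            "main_fraction": float(self.main_fraction),
            "convexity_main": None
            if self.convexity_main is None
            else float(self.convexity_main),
            "objects": [
                {
                    "id": int(m.id),
                    "n_voxels": int(m.n_voxels),
                    "volume_um3": float(m.volume),
                    "com_x": float(m.com[2]),
                    "com_y": float(m.com[1]),
                    "com_z": float(m.com[0]),
                    "convexity": float(m.convexity),
                    "degenerate_hull": bool(m.degenerate_hull),
                }
                for m in self.objects
            ],
        }

    def to_dataframe(self):
        """Per-object table (id, volume, COM, convexity, main/satellite role)."""
        import pandas as pd

        main_com = None
        for m in self.objects:
            if m.id == self.main_id:
                main_com = np.array(m.com)
        rows = []
        for m in self.objects:
            dist = (
                float(np.linalg.norm(np.array(m.com) - main_com))
                if main_com is not None and m.id != self.main_id
                else 0.0
            )
            nn = self.nearest_neighbor.get(m.id)
            rows.append(
                {
                    "id": m.id,
                    "volume_um3": m.volume,
                    "com_x": m.com[2],
                    "com_y": m.com[1],
                    "com_z": m.com[0],
                    "convexity": m.convexity,
                    "is_main": m.id == self.main_id,
                    "dist_to_main_um": dist,
                    "nn_id": nn[0] if nn else pd.NA,
                    "nn_dist_um": nn[1] if nn else pd.NA,
                }
            )
        return pd.DataFrame(rows)


def otsu_threshold(stack: VoxelStack) -> VoxelStack:
    """Binarise a grayscale stack at the Otsu threshold.

    The threshold maximises between-class variance over a 256-bin histogram of
    the observed intensity range; voxels strictly above the threshold become
    foreground.
    """
    values = stack.values
    vmin = values.min()
    vmax = values.max()
    if vmin == vmax:
        raise ValueError(
            "cannot Otsu-threshold a constant-intensity stack "
            f"(all voxels = {vmin})"
        )
    thresh = threshold_otsu(values, nbins=256)
    return stack.with_values(values > thresh)


def _require_binary(stack: VoxelStack, op: str) -> np.ndarray:
    if stack.is_binary:
        return stack.values
    vals = np.unique(stack.values)
    if len(vals) <= 2 and np.all(np.isin(vals, (0, 1))):
        return stack.values.astype(bool)
    raise ValueError(f"{op} requires a binary stack; threshold first")


def remove_small_components(
    binary: VoxelStack, min_volume: float = 11.0, connectivity: int = 26
) -> VoxelStack:
    """Drop connected components with physical volume below ``min_volume`` um^3.

    A component of volume exactly ``min_volume`` is retained. No foreground
    voxel is ever added; an empty result is allowed.
    """
    mask = _require_binary(binary, "remove_small_components")
    if min_volume <= 0 or not mask.any():
        return binary.with_values(mask.copy())
    if connectivity not in _CONNECTIVITY_TO_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26 (got {connectivity})")
    min_count = int(math.ceil(min_volume / binary.voxel_volume - 1e-9))
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_TO_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return binary.with_values(mask.copy())
    counts = np.bincount(labels.ravel())
    keep = counts >= min_count
    keep[0] = False
    return binary.with_values(keep[labels])


def label_components(binary: VoxelStack, connectivity: int = 26) -> LabeledObjects:
    """Label connected components with deterministic ordering.

    Components are numbered by the raster position of their first voxel, so
    the labelling is independent of the underlying library's scan strategy.
    """
    if connectivity not in _CONNECTIVITY_TO_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26 (got {connectivity})")
    mask = _require_binary(binary, "label_components")
    raw = measure.label(mask, connectivity=_CONNECTIVITY_TO_RANK[connectivity])
    n = int(raw.max())
    if n == 0:
        return LabeledObjects(
            np.zeros_like(raw, dtype=np.int32),
            np.empty(0, dtype=np.int32),
            connectivity,
            binary.voxel_size,
            binary.origin,
        )
    linear = np.arange(raw.size, dtype=np.int64).reshape(raw.shape)
    ids = np.arange(1, n + 1)
    first = np.atleast_1d(ndimage.minimum(linear, labels=raw, index=ids))
    order = np.argsort(first, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[ids[order]] = np.arange(1, n + 1, dtype=np.int32)
    labels = remap[raw]
    return LabeledObjects(
        labels,
        np.arange(1, n + 1, dtype=np.int32),
        connectivity,
        binary.voxel_size,
        binary.origin,
    )


def _voxelized_hull_count(coords: np.ndarray) -> Optional[int]:
    """Number of voxels in the convex hull image of a voxel set.

    The hull is taken over the centres of the object's surface voxels and
    voxels are counted when their centre lies inside it (the regionprops /
    BiofilmQ solidity convention), so any convex digitised solid has
    convexity exactly 1.  Voxel anisotropy cancels from the ratio because
    point-in-hull membership is affine invariant.  Returns None for
    degenerate (coplanar) objects.
    """
    mins = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - mins + 1)
    sub = np.zeros(shape, dtype=bool)
    rel = coords - mins
    sub[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    interior = ndimage.binary_erosion(sub)
    surf = np.argwhere(sub & ~interior)
    try:
        hull = ConvexHull(surf.astype(np.float64))
    except QhullError:
        return None
    eqs = hull.equations  # rows: (a, b, c, d) with a*z + b*y + c*x + d <= 0
    eps = 1e-7
    c_min = 1e-6  # facets with |x-coefficient| below this act as feasibility cuts
    nz, ny, nx = shape
    zz, yy = np.meshgrid(np.arange(nz), np.arange(ny), indexing="ij")
    zy = np.column_stack([zz.ravel(), yy.ravel()]).astype(np.float64)
    # per column (z, y): hull membership in x is an interval; bound it with
    # every facet, treating x-independent facets as feasibility tests.
    # The constraint c*x <= rhs is relaxed by eps so points exactly on the
    # hull boundary are kept.
    x_lo = np.full(len(zy), 0.0)
    x_hi = np.full(len(zy), float(nx - 1))
    feasible = np.ones(len(zy), dtype=bool)
    for a, b, c, d in eqs:
        rhs = -(d + a * zy[:, 0] + b * zy[:, 1]) + eps
        if c > c_min:
            np.minimum(x_hi, rhs / c, out=x_hi)
        elif c < -c_min:
            np.maximum(x_lo, rhs / c, out=x_lo)
        else:
            feasible &= rhs >= 0
    counts = np.floor(x_hi + eps) - np.ceil(x_lo - eps) + 1
    counts = np.where(feasible & (counts > 0), counts, 0.0)
    return int(counts.sum())


def component_metrics(objects: LabeledObjects) -> list:
    """Volume, physical centre of mass and convexity for every object.

    COM is the unweighted mean of voxel centres; convexity is object volume
    divided by convex-hull volume.  Objects of <= 4 voxels, or whose hull is
    degenerate (coplanar voxels), are assigned convexity 1 and flagged.
    """
    vs = np.asarray(objects.voxel_size)
    origin = np.asarray(objects.origin)
    vv = float(np.prod(vs))
    out: list[ObjectMetrics] = []
    if objects.n_objects == 0:
        return out
    slices = ndimage.find_objects(objects.labels)
    for oid in objects.object_ids:
        sl = slices[oid - 1]
        offset = np.array([s.start for s in sl], dtype=np.int64)
        coords = np.argwhere(objects.labels[sl] == oid) + offset
        n_vox = len(coords)
        volume = n_vox * vv
        com = tuple((coords + 0.5).mean(axis=0) * vs + origin)
        degenerate = False
        if n_vox <= DEGENERATE_HULL_MAX_VOXELS:
            convexity = 1.0
            degenerate = True
        else:
            hull_count = _voxelized_hull_count(coords)
            if hull_count is None or hull_count <= 0:
                convexity = 1.0
                degenerate = True
                logger.debug("object %d: degenerate convex hull", oid)
            else:
                convexity = n_vox / hull_count
        out.append(
            ObjectMetrics(
                id=int(oid),
                n_voxels=n_vox,
                volume=volume,
                com=com,
                convexity=convexity,
                degenerate_hull=degenerate,
            )
        )
    return out


def satellite_statistics(metrics: Sequence[ObjectMetrics]) -> MorphologyReport:
    """Summarise objects into main colony + satellites.

    The main colony is the largest object by volume (ties broken toward the
    smallest label); every other component is a satellite.  Distances are
    COM-to-COM in um.
    """
    metrics = sorted(metrics, key=lambda m: m.id)
    if not metrics:
        return MorphologyReport(
            objects=[],
            main_id=None,
            n_satellites=0,
            satellite_ids=[],
            satellite_volumes=[],
            com_distances=[],
            nearest_neighbor={},
            total_volume=0.0,
            main_volume=0.0,
        )
    main = max(metrics, key=lambda m: (m.volume, -m.id))
    main_com = np.array(main.com)
    satellites = [m for m in metrics if m.id != main.id]
    com_distances = [
        float(np.linalg.norm(np.array(m.com) - main_com)) for m in satellites
    ]
    nearest: dict[int, tuple] = {}
    if len(metrics) > 1:
        coms = np.array([m.com for m in metrics])
        d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        for i, m in enumerate(metrics):
            j = int(np.argmin(d[i]))
            nearest[m.id] = (metrics[j].id, float(d[i, j]))
    return MorphologyReport(
        objects=metrics,
        main_id=main.id,
        n_satellites=len(satellites),
        satellite_ids=[m.id for m in satellites],
        satellite_volumes=[m.volume for m in satellites],
        com_distances=com_distances,
        nearest_neighbor=nearest,
        total_volume=float(sum(m.volume for m in metrics)),
        main_volume=float(main.volume),
        convexity_main=main.convexity,
    )


def crop_half(
    stack: VoxelStack,
    axis: Union[int, str] = "z",
    keep: str = "lower",
    connectivity: int = 26,
) -> VoxelStack:
    """Zero out one half of a binary stack along ``axis``.

    The cut plane passes through the main (largest) object's centre of mass:
    with ``keep='lower'`` voxel planes with index < the COM plane survive,
    with ``keep='upper'`` the complement, so the two choices partition the
    foreground exactly.  Mirrors restricting confocal stacks to the
    half-colony closest to the objective.
    """
    if axis not in _AXIS_NAMES:
        raise ValueError(f"axis must be one of z, y, x (got {axis!r})")
    ax = _AXIS_NAMES[axis]
    if keep not in ("lower", "upper"):
        raise ValueError(f"keep must be 'lower' or 'upper' (got {keep!r})")
    mask = _require_binary(stack, "crop_half")
    if stack.values.shape[ax] < 2:
        raise ValueError(f"axis {axis!r} is degenerate (size {stack.values.shape[ax]})")
    labeled = label_components(stack.with_values(mask), connectivity=connectivity)
    if labeled.n_objects == 0:
        raise ValueError("crop_half needs at least one foreground object")
    counts = np.bincount(labeled.labels.ravel())
    counts[0] = 0
    main_id = int(np.argmax(counts))
    coords_ax = np.nonzero(labeled.labels == main_id)[ax]
    cut = int(round(float(coords_ax.mean()) + 0.5))  # first plane of the upper half
    out = mask.copy()
    sl: list = [slice(None)] * 3
    if keep == "lower":
        sl[ax] = slice(cut, None)
    else:
        sl[ax] = slice(None, cut)
    out[tuple(sl)] = False
    return stack.with_values(out)


@dataclass
class PipelineConfig:
    """Configuration of the full analysis chain."""

    min_volume: float = 11.0  # um^3, small-cluster noise filter
    connectivity: int = 26
    crop: Optional[tuple] = None  # e.g. ("z", "lower")
    assume_binary: bool = False  # skip thresholding (simulated colonies)

    def __post_init__(self) -> None:
        if self.connectivity not in _CONNECTIVITY_TO_RANK:
            raise ValueError(
                f"connectivity must be one of 6, 18, 26 (got {self.connectivity})"
            )
        if self.min_volume < 0:
            raise ValueError(f"min_volume must be >= 0 (got {self.min_volume})")


def analyze(stack: VoxelStack, config: Optional[PipelineConfig] = None) -> MorphologyReport:
    """Full pipeline: threshold -> (crop) -> filter -> label -> metrics -> report.

    Grayscale input is Otsu-thresholded first; binary input (or
    ``config.assume_binary``) skips thresholding, as is done for simulated
    colonies.  The small-object filter is applied after the optional
    half-colony crop.
    """
    if config is None:
        config = PipelineConfig()
    if stack.is_binary or config.assume_binary:
        binary = stack.with_values(_require_binary(stack, "analyze").copy())
    else:
        binary = otsu_threshold(stack)
    if config.crop is not None:
        axis, keep = config.crop
        binary = crop_half(binary, axis=axis, keep=keep, connectivity=config.connectivity)
    binary = remove_small_components(binary, config.min_volume, config.connectivity)
    labeled = label_components(binary, config.connectivity)
    metrics = component_metrics(labeled)
    return satellite_statistics(metrics)
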