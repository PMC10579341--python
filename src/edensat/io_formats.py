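"""Readers, writers and configuration shared by all modules.

Formats: multi-page TIFF for voxel stacks (voxel size and origin carried in
the ImageDescription tag as JSON), a raw-array dialect (.npy plus a .json
sidecar), CSV for site lists / event logs / sweep tables, JSON for reports
and run manifests, YAML or JSON for configs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .eden_core import EventLog, SimParams, Trajectory
from .experiments import RegimeThresholds, SweepSpec
from .fixtures import FixtureSpec, Satellite
from .morphology import PipelineConfig, VoxelStack

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "read_stack",
    "write_stack",
    "write_sites_csv",
    "read_sites_csv",
    "write_event_log_csv",
    "write_trajectory_csv",
    "load_config",
    "load_sim_config",
    "load_sweep_config",
    "load_fixture_config",
    "file_checksum",
]


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    tool: str = "edensat"
    version: str = __version__
    command: str = ""
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    status: str = ""
    n_cells: Optional[int] = None
    wall_clock: Optional[float] = None
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path: Union[str, Path]) -> None:
        path = Path(path)
        self.outputs[path.name] = file_checksum(path)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# voxel stacks


def _stack_metadata(stack: VoxelStack) -> dict:
    return {
        "voxel_size": list(stack.voxel_size),
        "origin": list(stack.origin),
        "binary": stack.is_binary,
    }


def write_stack(stack: VoxelStack, path: Union[str, Path]) -> None:
    """Write a stack as multi-page TIFF (or .npy + .json sidecar).

    Binary stacks are stored as 8-bit 0/255; grayscale values are stored
    unscaled.  Geometry metadata travels in the TIFF description tag or the
    sidecar.
    """
    path = Path(path)
    meta = _stack_metadata(stack)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = stack.values
        if stack.is_binary:
            values = values.astype(np.uint8) * 255
        tifffile.imwrite(
            path, values, photometric="minisblack", description=json.dumps(meta)
        )
    elif path.suffix == ".npy":
        np.save(path, stack.values)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r} (use .tif or .npy)")


def read_stack(
    path: Union[str, Path],
    voxel_size: Optional[tuple] = None,
    binary: Optional[bool] = None,
) -> VoxelStack:
    """Read a TIFF or .npy stack back into a :class:`VoxelStack`.

    Geometry comes from the embedded metadata (TIFF description tag or JSON
    sidecar); an explicit ``voxel_size`` overrides it with a logged notice.
    Missing voxel size with no override is an error.  ``binary`` forces
    boolean interpretation (nonzero = foreground).
    """
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    elif path.suffix == ".npy":
        values = np.load(path)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r} (use .tif or .npy)")
    if values.ndim == 2:
        values = values[None, ...]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {values.shape}")
    if voxel_size is not None:
        if "voxel_size" in meta and tuple(meta["voxel_size"]) != tuple(voxel_size):
            logger.info(
                "%s: overriding stored voxel size %s with %s",
                path,
                meta["voxel_size"],
                voxel_size,
            )
        vs = tuple(voxel_size)
    elif "voxel_size" in meta:
        vs = tuple(meta["voxel_size"])
    else:
        raise ValueError(
            f"{path}: no voxel size metadata found; pass voxel_size explicitly"
        )
    origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    if binary is None:
        binary = bool(meta.get("binary", False))
    if binary and values.dtype != bool:
        values = values > 0
    return VoxelStack(values, voxel_size=vs, origin=origin)


# ---------------------------------------------------------------------------
# site lists, event logs, trajectories


def write_sites_csv(sites: np.ndarray, path: Union[str, Path]) -> None:
    """Write an (n, 3) site list as CSV with x,y,z columns (0-based ints)."""
    sites = np.asarray(sites).reshape(-1, 3)
    pd.DataFrame(sites, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_sites_csv(path: Union[str, Path]) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[["x", "y", "z"]].to_numpy(dtype=np.int64)


def write_event_log_csv(log: EventLog, path: Union[str, Path]) -> None:
    """Event log CSV: event_index, t, tau, event_type, from_*, to_* (from_*
    empty for divisions)."""
    log.to_dataframe().to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "t": traj.times,
            "n_cells": traj.populations,
            "event_type": traj.event_types,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configs


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON mapping."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


def _check_keys(data: dict, allowed: set, context: str) -> None:
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(
            f"{context}: unknown keys {unknown}; allowed keys are {sorted(allowed)}"
        )


def _build_sim_params(data: dict, context: str = "simulation config") -> SimParams:
    allowed = {f.name for f in dataclasses.fields(SimParams)}
    _check_keys(data, allowed, context)
    try:
        return SimParams(**data)
    except ValueError as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_sim_config(source: Union[str, Path, dict]) -> SimParams:
    """Resolve a simulation config (YAML/JSON path or dict) into SimParams.

    An empty config yields the full documented defaults; unknown keys and
    invariant violations are reported together, naming every offending key.
    """
    data = source if isinstance(source, dict) else load_config(source)
    return _build_sim_params(dict(data))


def _build_pipeline(data: dict, context: str) -> PipelineConfig:
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    _check_keys(data, allowed, context)
    if "crop" in data and data["crop"] is not None:
        crop = data["crop"]
        if isinstance(crop, str):
            axis, _, keep = crop.partition(":")
            data["crop"] = (axis, keep or "lower")
        else:
            data["crop"] = tuple(crop)
    return PipelineConfig(**data)


def load_sweep_config(source: Union[str, Path, dict]) -> SweepSpec:
    """Resolve a sweep config into a SweepSpec.

    Recognised keys: sigma_values, ks_values, replicates, base_seed,
    store_trajectories, base_params (SimParams mapping), pipeline
    (PipelineConfig mapping), thresholds (RegimeThresholds mapping).
    """
    data = dict(source if isinstance(source, dict) else load_config(source))
    allowed = {
        "sigma_values",
        "ks_values",
        "replicates",
        "base_seed",
        "store_trajectories",
        "base_params",
        "pipeline",
        "thresholds",
    }
    _check_keys(data, allowed, "sweep config")
    kwargs: dict = {}
    for key in ("sigma_values", "ks_values"):
        if key in data:
            kwargs[key] = tuple(float(v) for v in data[key])
    for key in ("replicates", "base_seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "store_trajectories" in data:
        kwargs["store_trajectories"] = bool(data["store_trajectories"])
    if "base_params" in data:
        kwargs["base_params"] = _build_sim_params(
            dict(data["base_params"]), "sweep config: base_params"
        )
    if "pipeline" in data:
        kwargs["pipeline"] = _build_pipeline(
            dict(data["pipeline"]), "sweep config: pipeline"
        )
    if "thresholds" in data:
        tdata = dict(data["thresholds"])
        _check_keys(
            tdata,
            {f.name for f in dataclasses.fields(RegimeThresholds)},
            "sweep config: thresholds",
        )
        kwargs["thresholds"] = RegimeThresholds(**tdata)
    return SweepSpec(**kwargs)


def load_fixture_config(source: Union[str, Path, dict]) -> FixtureSpec:
    """Resolve a fixture config into a FixtureSpec.

    ``satellites`` entries are mappings with center, radius and optional
    intensity.
    """
    data = dict(source if isinstance(source, dict) else load_config(source))
    allowed = {f.name for f in dataclasses.fields(FixtureSpec)}
    _check_keys(data, allowed, "fixture config")
    if "satellites" in data:
        sats = []
        for i, s in enumerate(data["satellites"]):
            s = dict(s)
            _check_keys(
                s,
                {f.name for f in dataclasses.fields(Satellite)},
                f"fixture config: satellites[{i}]",
            )
            s["center"] = tuple(float(c) for c in s["center"])
            sats.append(Satellite(**s))
        data["satellites"] = tuple(sats)
    for key in ("shape", "voxel_size", "main_center", "main_semiaxes"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return FixtureSpec(**data)
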