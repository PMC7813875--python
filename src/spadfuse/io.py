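"""File interchange: TIFF stacks for cubes and images, YAML for configs.

Transient cubes travel as multi-frame TIFFs (time axis = page axis) with a
JSON sidecar (``<path>.json``) holding the time-bin width and grid
identity, so integer count data round-trips bit-exactly through the
microscopy ecosystem's standard container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward_model import FusionGeometry
from .reconstruction import WEIGHT_PRESETS, RegularizationWeights
from .types import HIGH, IntensityImage, TransientCube

__all__ = [
    "read_cube",
    "write_cube",
    "read_image",
    "write_image",
    "load_geometry",
    "save_geometry",
    "load_weights",
    "save_weights",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_cube(cube: TransientCube, path: str | Path) -> Path:
    """Write a cube as a multi-frame TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, cube.values, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"bin_width_ps": cube.bin_width, "grid": cube.grid, "kind": "cube"})
    )
    return path


def read_cube(path: str | Path) -> TransientCube:
    """Read a cube written by :func:`write_cube` (lossless round trip)."""
    path = Path(path)
    values = np.asarray(tifffile.imread(path))
    if values.ndim == 2:  # single-page stack
        values = values[None, :, :]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D TIFF, got ndim={values.ndim}")
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("kind") != "cube":
        raise ValueError(f"{meta_path}: sidecar does not describe a cube")
    return TransientCube(values, bin_width=float(meta["bin_width_ps"]), grid=meta["grid"])


def write_image(image: IntensityImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.values, photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"grid": image.grid, "kind": "image"}))
    return path


def read_image(path: str | Path) -> IntensityImage:
    path = Path(path)
    values = np.asarray(tifffile.imread(path))
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame TIFF, got ndim={values.ndim}")
    meta_path = _sidecar(path)
    grid = HIGH
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("kind") != "image":
            raise ValueError(f"{meta_path}: sidecar does not describe an image")
        grid = meta["grid"]
    return IntensityImage(values, grid=grid)


# ---------------------------------------------------------------------------
# Flat key-value configuration

def save_geometry(geometry: FusionGeometry, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "M": geometry.M,
        "N": geometry.N,
        "m": geometry.m,
        "n": geometry.n,
        "blur_sigma": float(geometry.blur_sigma),
        "active_offsets": sorted([list(t) for t in geometry.active_offsets]),
        "dead_pixels": sorted([list(t) for t in geometry.dead_pixels]),
        "boundary_mode": geometry.boundary_mode,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_geometry(path: str | Path) -> FusionGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return FusionGeometry(
        M=int(data["M"]),
        N=int(data["N"]),
        m=int(data["m"]),
        n=int(data["n"]),
        blur_sigma=float(data.get("blur_sigma", 0.0)),
        active_offsets=(
            frozenset(tuple(t) for t in data["active_offsets"])
            if data.get("active_offsets")
            else None
        ),
        dead_pixels=frozenset(tuple(t) for t in data.get("dead_pixels", []) or []),
        boundary_mode=data.get("boundary_mode", "reflect"),
    )


def save_weights(weights: RegularizationWeights, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {
                "alpha": weights.alpha,
                "beta": weights.beta,
                "gamma": weights.gamma,
                "delta": weights.delta,
            }
        )
    )
    return path


def load_weights(source: str | Path) -> RegularizationWeights:
    """Load weights from a preset name (``lidar``/``flim``) or a YAML file."""
    if isinstance(source, str) and source in WEIGHT_PRESETS:
        return WEIGHT_PRESETS[source]
    data = yaml.safe_load(Path(source).read_text())
    return RegularizationWeights(
        alpha=float(data["alpha"]),
        beta=float(data["beta"]),
        gamma=float(data["gamma"]),
        delta=float(data["delta"]),
    )
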