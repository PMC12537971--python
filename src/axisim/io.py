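"""File I/O: multi-page TIFF volumes/stacks, JSON sidecars, YAML configs.

Image data is written as 32-bit float TIFF.  4-D stacks (t, z, y, x) use
ImageJ-style hyperstack ordering with the dimension order recorded in a
JSON sidecar so round-trips are unambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "write_volume",
    "read_volume",
    "write_stack",
    "read_stack",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
]


def write_volume(path, volume: np.ndarray, lateral_spacing: float,
                 axial_spacing: float, meta: dict | None = None) -> Path:
    """Write a 3-D (z, y, x) volume as a 32-bit float multi-page TIFF with
    a JSON sidecar recording voxel spacings and any extra metadata."""
    path = Path(path)
    v = np.asarray(volume, dtype=np.float32)
    if v.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) volume")
    tifffile.imwrite(path, v, imagej=True,
                     resolution=(1e7 / lateral_spacing, 1e7 / lateral_spacing),
                     metadata={"spacing": axial_spacing / 1000.0,
                               "unit": "um", "axes": "ZYX"})
    sidecar = {"axes": "ZYX", "lateral_spacing_nm": lateral_spacing,
               "axial_spacing_nm": axial_spacing}
    if meta:
        sidecar.update(meta)
    write_json(path.with_suffix(".json"), sidecar)
    return path


def read_volume(path) -> tuple[np.ndarray, dict]:
    """Read a volume TIFF and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar = {}
    sc = path.with_suffix(".json")
    if sc.exists():
        sidecar = read_json(sc)
    return data, sidecar


def write_stack(path, stack: np.ndarray, lateral_spacing: float,
                z_step: float, frame_interval: float,
                meta: dict | None = None) -> Path:
    """Write a 4-D (t, z, y, x) acquisition as a 32-bit float TIFF
    hyperstack, with the dimension order in the JSON sidecar."""
    path = Path(path)
    s = np.asarray(stack, dtype=np.float32)
    if s.ndim != 4:
        raise ValueError("expected a 4-D (t, z, y, x) stack")
    # ImageJ hyperstack axis order is TZCYX; write as TZYX
    tifffile.imwrite(path, s, imagej=True, metadata={"axes": "TZYX"})
    sidecar = {"axes": "TZYX", "lateral_spacing_nm": lateral_spacing,
               "z_step_nm": z_step, "frame_interval_s": frame_interval}
    if meta:
        sidecar.update(meta)
    write_json(path.with_suffix(".json"), sidecar)
    return path


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a 4-D stack TIFF and its JSON sidecar."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4 dimensions, got {data.ndim}")
    sidecar = {}
    sc = path.with_suffix(".json")
    if sc.exists():
        sidecar = read_json(sc)
    return data, sidecar


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_jsonable) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_yaml(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_yaml(path) -> dict:
    """Read a YAML (or JSON — valid YAML) mapping."""
    out = yaml.safe_load(Path(path).read_text())
    if not isinstance(out, dict):
        raise ValueError("config file must contain a mapping")
    return out
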