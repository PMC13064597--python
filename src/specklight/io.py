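"""File formats: multi-page TIFF stacks with JSON sidecars, single-page
float TIFF maps, JSON ROIs, CSV tables.

Conventions: the stack's time axis maps to TIFF pages; maps carry a units
tag ("s" for decorrelation time, "" for contrast) in their sidecar so that
statistics never mix modalities; 0-based (row, col) pixel coordinates
throughout. Nothing is overwritten unless ``overwrite=True``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .dcs import TauCMap
from .lsci import ContrastMap
from .roi import ROIMask, polygon_to_mask
from .stack import SpeckleStack

__all__ = [
    "sidecar_path",
    "write_stack",
    "load_stack",
    "write_map",
    "load_map",
    "write_mask",
    "load_roi",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_stack(stack: SpeckleStack, path, spec=None, overwrite: bool = False) -> Path:
    """Write a stack as a multi-page grayscale TIFF plus a JSON sidecar.

    Float stacks are written at native precision so that a write/load round
    trip is bit-identical; quantized (integer-valued) stacks survive as
    integers-in-float. The sidecar records fps, exposure and, if given, the
    full phantom spec.
    """
    path = Path(path)
    _check_overwrite(path, overwrite)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    side = {
        "fps": stack.fps,
        "exposure_us": stack.exposure_us,
        "meta": stack.meta,
    }
    if spec is not None:
        side["phantom_spec"] = dataclasses.asdict(spec)
    sidecar_path(path).write_text(json.dumps(side, indent=1, default=_json_default))
    return path


def load_stack(path, fps: float | None = None, exposure_us: float | None = None) -> SpeckleStack:
    """Load a multi-page TIFF stack; acquisition metadata comes from the
    JSON sidecar or, failing that, the ``fps`` argument."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.dtype == object or arr.ndim != 3:
        raise ValueError(
            f"{path} is not a T x H x W stack with consistent page shapes "
            f"(got dtype={arr.dtype}, ndim={arr.ndim})"
        )
    meta: dict = {"source": str(path)}
    side = sidecar_path(path)
    if side.exists():
        info = json.loads(side.read_text())
        fps = fps if fps is not None else info.get("fps")
        exposure_us = (
            exposure_us if exposure_us is not None else info.get("exposure_us", 0.0)
        )
        meta.update(info.get("meta", {}))
    if fps is None:
        raise ValueError(
            f"frame rate unknown for {path}: provide fps= explicitly or write a "
            f"JSON sidecar ({side.name}) with an 'fps' field"
        )
    frames = np.asarray(arr)
    if not np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float64)  # lossless for <= 32-bit integers
    return SpeckleStack(
        frames=frames, fps=float(fps), exposure_us=float(exposure_us or 0.0), meta=meta
    )


def write_map(map_obj, path, overwrite: bool = False) -> Path:
    """Write a TauCMap or ContrastMap as 32-bit float TIFF with a JSON
    sidecar (units, method, validity handling); TauCMap validity is written
    alongside as ``<stem>_valid.tif`` (uint8)."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    if isinstance(map_obj, TauCMap):
        tifffile.imwrite(path, map_obj.tau_c.astype(np.float32))
        vpath = path.with_name(path.stem + "_valid.tif")
        tifffile.imwrite(vpath, map_obj.valid.astype(np.uint8))
        side = {
            "kind": "tau_c",
            "units": "s",
            "method": map_obj.method_tag,
            "valid_mask": vpath.name,
            "meta": map_obj.meta,
        }
    elif isinstance(map_obj, ContrastMap):
        tifffile.imwrite(path, map_obj.K.astype(np.float32))
        side = {
            "kind": "speckle_contrast",
            "units": "",
            "window_len": map_obj.window_len,
            "stride": map_obj.stride,
            "meta": map_obj.meta,
        }
    else:
        tifffile.imwrite(path, np.asarray(map_obj, dtype=np.float32))
        side = {"kind": "generic", "units": ""}
    sidecar_path(path).write_text(json.dumps(side, indent=1, default=_json_default))
    return path


def load_map(path):
    """Load a map written by :func:`write_map`; returns the matching object
    (TauCMap / ContrastMap) when the sidecar identifies one, else an array."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    side = sidecar_path(path)
    if not side.exists():
        return arr
    info = json.loads(side.read_text())
    if info.get("kind") == "tau_c":
        vpath = path.with_name(info["valid_mask"])
        valid = tifffile.imread(vpath).astype(bool)
        tau = np.where(valid, arr, np.nan)
        return TauCMap(
            tau_c=tau,
            valid=valid,
            reason=np.where(valid, 0, 2).astype(np.uint8),
            method_tag=info.get("method", "dcs"),
            meta=info.get("meta", {}),
        )
    if info.get("kind") == "speckle_contrast":
        return ContrastMap(
            K=arr,
            window_len=int(info["window_len"]),
            stride=int(info["stride"]),
            meta=info.get("meta", {}),
        )
    return arr


def write_mask(mask: np.ndarray, path, overwrite: bool = False) -> Path:
    path = Path(path)
    _check_overwrite(path, overwrite)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def load_roi(path, shape: tuple[int, int] | None = None, label: str = "tumour") -> ROIMask:
    """Load an ROI from a single-page TIFF mask or a polygon-vertex JSON
    (``{"vertices": [[row, col], ...]}``; requires ``shape``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        info = json.loads(path.read_text())
        if shape is None:
            raise ValueError("rasterizing a polygon ROI requires the image shape")
        return polygon_to_mask(info["vertices"], shape, label=label)
    mask = tifffile.imread(path).astype(bool)
    return ROIMask(mask=mask, label=label, provenance=f"mask file {path.name}")
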