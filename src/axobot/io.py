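"""File formats: multi-page TIFF z-stacks with JSON sidecars, JSONL records.

A stack is written as one TIFF page per z-slice plus ``<path>.json`` holding
the metadata needed to reconstruct it (pixel size, z positions, channel,
magnification).  Per-worm automation records stream as JSON lines.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .focus_metrics import ZStack
from .virtual_rig.render import CameraFrame

__all__ = ["write_stack", "read_stack", "sidecar_path", "write_records",
           "read_records"]

_SIDECAR_FIELDS = ("pixel_size_um", "z_positions_um", "channel",
                   "magnification_name")


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: ZStack, path, extra_metadata: dict | None = None) -> None:
    """Write a z-stack as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    first = stack.frames[0]
    data = np.stack([f.raster.astype(np.float32) for f in stack.frames])
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_um": first.pixel_size,
        "z_positions_um": [float(z) for z in stack.z_positions],
        "channel": first.channel,
        "magnification_name": first.magnification_name,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ZStack:
    """Read a stack written by :func:`write_stack`.

    Raises :class:`FormatError` when the sidecar is missing/incomplete or
    the page count disagrees with the z-position list.
    """
    path = Path(path)
    sidecar = sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"missing sidecar {sidecar}; required fields: {', '.join(_SIDECAR_FIELDS)}"
        )
    meta = json.loads(sidecar.read_text())
    missing = [f for f in _SIDECAR_FIELDS if f not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar} lacks fields: {', '.join(missing)}")

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    zs = meta["z_positions_um"]
    if len(zs) != len(data):
        raise FormatError(
            f"stack has {len(data)} pages but sidecar lists {len(zs)} z positions"
        )
    frames = [
        CameraFrame(raster=page.astype(float),
                    magnification_name=meta["magnification_name"],
                    pixel_size=float(meta["pixel_size_um"]),
                    z_position=float(z),
                    channel=meta["channel"])
        for page, z in zip(data, zs)
    ]
    return ZStack(frames, np.asarray(zs, dtype=float))


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_records(records, path) -> None:
    """Write automation records as JSON lines."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(_to_jsonable(rec)) + "\n")


def read_records(path) -> list[dict]:
    """Read JSON-line records back as plain dictionaries."""
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]
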