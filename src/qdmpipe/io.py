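"""File interchange: multi-page TIFF stacks and maps with JSON sidecars.

Every numeric artifact is a 32/64-bit float TIFF plus a JSON sidecar that
records the axes (frequencies in MHz or dark times in seconds), pixel size,
applied field, sensor configuration and seed.  NaN encodes masked/invalid
pixels everywhere.  Sidecar paths are the TIFF path with ``.json`` swapped
in for the suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .sensor import FieldMap, SensorConfig
from .synth import ODMRStack, T1Stack

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "sidecar_path",
    "parse_scene",
]


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def _dump_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_stack(stack, tiff_path) -> Path:
    """Write an ODMR or T1 stack as multi-page TIFF + JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack.frames))
    side = dict(stack.meta)
    if isinstance(stack, ODMRStack):
        side["freqs_MHz"] = [float(f) for f in stack.freqs]
    elif isinstance(stack, T1Stack):
        side["taus_s"] = [float(t) for t in stack.taus]
    else:
        raise TypeError(f"unsupported stack type {type(stack)!r}")
    side["mask_encoding"] = "NaN"
    _dump_json(sidecar_path(tiff_path), side)
    return tiff_path


def read_stack(tiff_path):
    """Read a stack written by :func:`write_stack`; type from the sidecar."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    with open(sidecar_path(tiff_path)) as fh:
        meta = json.load(fh)
    meta.pop("mask_encoding", None)
    if "freqs_MHz" in meta:
        freqs = np.asarray(meta.pop("freqs_MHz"))
        return ODMRStack(frames=frames, freqs=freqs, meta=meta)
    if "taus_s" in meta:
        taus = np.asarray(meta.pop("taus_s"))
        return T1Stack(frames=frames, taus=taus, meta=meta)
    raise ValueError("sidecar lacks both freqs_MHz and taus_s")


def write_map(fmap: FieldMap, tiff_path, units: str = "gauss", extra: dict | None = None) -> Path:
    """Write a field map as single-plane float32 TIFF + JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, fmap.values.astype(np.float32))
    side = {
        "units": units,
        "pixel_m": fmap.pixel,
        "origin_m": list(map(float, fmap.origin)),
        "mask_encoding": "NaN",
    }
    if extra:
        side.update(extra)
    _dump_json(sidecar_path(tiff_path), side)
    return tiff_path


def read_map(tiff_path) -> FieldMap:
    tiff_path = Path(tiff_path)
    values = tifffile.imread(tiff_path).astype(float)
    with open(sidecar_path(tiff_path)) as fh:
        side = json.load(fh)
    return FieldMap(values, side["pixel_m"], tuple(side.get("origin_m", (0.0, 0.0))))


def parse_scene(doc: dict):
    """Parse a scene JSON document into particles and an applied field.

    Schema::

        {"particles": [{"center_nm": [x, y, height], "diameter_nm": 365,
                        "chi_v": 0.053, "packing": 0.7,
                        "easy_axis": [ex, ey, ez] | null,
                        "superparamagnetic": false}, ...],
         "applied_field": {"gauss": 1400,
                           "direction": [bx, by, bz] | "nv_axis"}}

    Returns ``(particles, applied_field_or_None, sensor)``; the sensor comes
    from an optional ``"sensor"`` block with the sidecar key names.
    """
    from .magnetostatics import AppliedField, ParticleModel

    sensor = SensorConfig.from_dict(doc.get("sensor", {}))
    particles = []
    for p in doc.get("particles", []):
        center = np.asarray(p["center_nm"], dtype=float) * 1e-9
        particles.append(ParticleModel(
            center=tuple(center),
            diameter=p["diameter_nm"] * 1e-9,
            chi_v=p["chi_v"],
            packing_fraction=p.get("packing", 0.7),
            easy_axis=p.get("easy_axis"),
            superparamagnetic=p.get("superparamagnetic", False),
        ))
    applied = None
    if "applied_field" in doc:
        af = doc["applied_field"]
        direction = af.get("direction", "nv_axis")
        if isinstance(direction, str):
            if direction != "nv_axis":
                raise ValueError(f"unknown field direction {direction!r}")
            direction = sensor.nv_axis
        applied = AppliedField.from_gauss(af["gauss"], direction)
    return particles, applied, sensor
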