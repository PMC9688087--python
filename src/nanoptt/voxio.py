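"""Voxel-map I/O: Analyze-7.5 .img/.hdr pairs plus a raw+sidecar fallback.

Energy and temperature volumes are exchanged as paired header/raw files in
the Analyze 7.5 layout (little-endian, float32 by default), written and read
through nibabel.  Analyze headers have no origin field, so the world origin
is recorded in the header's free-text ``descrip`` field and recovered on
read; third-party viewers still get dimensions, pitch and data type from the
standard fields.

The fallback format is a bare ``.raw`` payload with a ``.json`` sidecar
describing shape, dtype, byte order, pitch and origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelMap", "VoxelMapError", "write_map", "read_map", "write_raw", "read_raw"]


class VoxelMapError(IOError):
    """Malformed, truncated or unsupported voxel-map file."""


@dataclass
class VoxelMap:
    """A 3-D scalar field on a uniform grid (pitch in mm, origin at grid corner)."""

    values: np.ndarray
    pitch: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise VoxelMapError("voxel map must be 3-D")


_SUPPORTED = (np.float32, np.float64)


def write_map(field: VoxelMap, path: str | Path) -> Path:
    """Write an .img/.hdr pair; returns the .hdr path.

    Values must be finite float32/float64; the round trip through
    :func:`read_map` is bit-exact.
    """
    path = Path(path)
    if path.suffix in (".img", ".hdr"):
        path = path.with_suffix("")
    values = np.asarray(field.values)
    if values.dtype not in [np.dtype(d) for d in _SUPPORTED]:
        raise VoxelMapError(f"unsupported dtype {values.dtype}; use float32/float64")
    if not np.isfinite(values).all():
        raise VoxelMapError("voxel map contains non-finite values")
    affine = np.diag([field.pitch, field.pitch, field.pitch, 1.0])
    img = nib.AnalyzeImage(values, affine)
    hdr = img.header
    hdr.set_data_dtype(values.dtype)
    hdr["pixdim"][1:4] = field.pitch
    hdr["descrip"] = f"origin_mm={field.origin[0]:.6g},{field.origin[1]:.6g},{field.origin[2]:.6g}".encode()
    nib.save(img, str(path.with_suffix(".img")))
    return path.with_suffix(".hdr")


def read_map(path: str | Path) -> VoxelMap:
    """Read an .img/.hdr pair written by :func:`write_map`."""
    path = Path(path)
    if path.suffix in (".img", ".hdr"):
        path = path.with_suffix("")
    hdr_path, img_path = path.with_suffix(".hdr"), path.with_suffix(".img")
    if not hdr_path.exists() or not img_path.exists():
        raise VoxelMapError(f"missing header or payload for {path}")
    try:
        img = nib.load(str(img_path))
    except Exception as exc:  # nibabel raises several error types here
        raise VoxelMapError(f"cannot parse {img_path}: {exc}") from exc
    hdr = img.header
    dtype = np.dtype(hdr.get_data_dtype())
    if dtype not in [np.dtype(d) for d in _SUPPORTED]:
        raise VoxelMapError(f"unsupported on-disk dtype {dtype}")
    shape = hdr.get_data_shape()
    expected = int(np.prod(shape)) * dtype.itemsize
    actual = img_path.stat().st_size
    if actual < expected:
        raise VoxelMapError(
            f"{img_path.name}: payload is {actual} bytes, header promises {expected}"
        )
    values = np.asarray(img.dataobj, dtype=dtype)
    pitch = float(hdr["pixdim"][1])
    origin = np.zeros(3)
    descrip = bytes(hdr["descrip"].tobytes()).split(b"\x00", 1)[0].decode(errors="ignore")
    if descrip.startswith("origin_mm="):
        try:
            origin = np.array([float(v) for v in descrip[len("origin_mm="):].split(",")])
        except ValueError:
            pass
    return VoxelMap(values=values, pitch=pitch, origin=origin)


def write_raw(field: VoxelMap, path: str | Path) -> Path:
    """Raw little-endian payload + JSON sidecar fallback; returns the sidecar path."""
    path = Path(path)
    if path.suffix in (".raw", ".json"):
        path = path.with_suffix("")
    values = np.asarray(field.values)
    if values.dtype not in [np.dtype(d) for d in _SUPPORTED]:
        raise VoxelMapError(f"unsupported dtype {values.dtype}")
    payload = values.astype(values.dtype.newbyteorder("<"), copy=False)
    path.with_suffix(".raw").write_bytes(payload.tobytes(order="C"))
    sidecar = {
        "shape": list(values.shape),
        "dtype": values.dtype.name,
        "byteorder": "little",
        "pitch_mm": field.pitch,
        "origin_mm": [float(v) for v in field.origin],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".json")


def read_raw(path: str | Path) -> VoxelMap:
    path = Path(path)
    if path.suffix in (".raw", ".json"):
        path = path.with_suffix("")
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
        shape = tuple(int(n) for n in meta["shape"])
        dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    except (FileNotFoundError, KeyError, ValueError, TypeError) as exc:
        raise VoxelMapError(f"bad sidecar for {path}: {exc}") from exc
    blob = path.with_suffix(".raw").read_bytes()
    expected = int(np.prod(shape)) * dtype.itemsize
    if len(blob) != expected:
        raise VoxelMapError(f"{path.name}.raw: {len(blob)} bytes, expected {expected}")
    values = np.frombuffer(blob, dtype=dtype).reshape(shape).astype(dtype.newbyteorder("="))
    return VoxelMap(values=values, pitch=float(meta["pitch_mm"]), origin=np.array(meta["origin_mm"]))
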