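"""Reading, writing and rescaling of CT volumes and masks as TIFF stacks.

Volumes are stored as ``(slice/z, row/y, column/x)`` arrays of 16-bit unsigned
gray values with an isotropic voxel edge length in mm.  Raw reconstructions
delivered as 32-bit float are downscaled to 16 bit on ingest; 8-bit previews
are promoted by left-shift scaling.  Every stack written by this module gets a
JSON sidecar carrying the voxel size and provenance so that physical units
survive round trips through plain TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelVolume",
    "ROIMask",
    "DegenerateVolumeError",
    "load_stack",
    "save_stack",
    "rescale_to_uint16",
]


class DegenerateVolumeError(ValueError):
    """Raised when a volume has no gray-value dynamic range at all."""


@dataclass
class VoxelVolume:
    """A 3D gray-value grid with physical voxel size.

    Parameters
    ----------
    data:
        ``(nz, ny, nx)`` array of ``uint16`` gray values.
    voxel_size_mm:
        Isotropic voxel edge length in millimetres (strictly positive).
    source_dtype:
        Dtype tag of the original samples before ingest (``"uint16"``,
        ``"uint8"`` or ``"float32"``).
    """

    data: np.ndarray
    voxel_size_mm: float
    source_dtype: str = "uint16"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if self.data.dtype != np.uint16:
            raise ValueError(f"volume data must be uint16 after ingest, got {self.data.dtype}")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_volume_mm3(self) -> float:
        """Total physical volume of the grid in mm³."""
        return float(self.data.size) * self.voxel_size_mm**3


@dataclass
class ROIMask:
    """A binary region of interest aligned to a parent :class:`VoxelVolume`."""

    data: np.ndarray
    voxel_size_mm: float
    label: str = "roi"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1, 255)).all():
                raise ValueError("mask values must be strictly binary")
            arr = arr > 0
        self.data = arr
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * self.voxel_size_mm**3


def rescale_to_uint16(
    data: np.ndarray,
    clip_quantiles: tuple[float, float] = (0.0005, 0.0005),
) -> np.ndarray:
    """Downscale a float volume to 16-bit unsigned by a clipped linear map.

    The gray range between the lower and ``1 - upper`` quantiles is mapped
    linearly onto ``[0, 65535]``; values outside that range saturate.  The
    symmetric default clip of 0.05% per tail protects against isolated
    reconstruction outliers without visibly compressing the histogram.

    Raises
    ------
    DegenerateVolumeError
        If the input is constant (zero dynamic range).
    ValueError
        For non-finite input or invalid quantiles.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("input contains non-finite values")
    q_lo, q_hi = clip_quantiles
    if not (0 <= q_lo < 0.5 and 0 <= q_hi < 0.5):
        raise ValueError(f"clip_quantiles must lie in [0, 0.5), got {clip_quantiles}")
    lo = float(np.quantile(data, q_lo))
    hi = float(np.quantile(data, 1.0 - q_hi))
    if hi <= lo:
        lo = float(data.min())
        hi = float(data.max())
        if hi <= lo:
            raise DegenerateVolumeError("volume has zero dynamic range; cannot rescale")
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * 65535.0
    return np.rint(scaled).astype(np.uint16)


def _ingest(arr: np.ndarray, voxel_size_mm: float) -> VoxelVolume:
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype == np.uint16:
        return VoxelVolume(arr, voxel_size_mm, source_dtype="uint16")
    if arr.dtype == np.uint8:
        # left-shift promotion keeps 8-bit gray ordering and spreads it over 16 bits
        return VoxelVolume((arr.astype(np.uint16) << 8), voxel_size_mm, source_dtype="uint8")
    if arr.dtype in (np.float32, np.float64):
        return VoxelVolume(rescale_to_uint16(arr, clip_quantiles=(0.0, 0.0)), voxel_size_mm,
                           source_dtype="float32")
    raise ValueError(f"unsupported sample format: {arr.dtype}")


def load_stack(path: str | Path, voxel_size_mm: float) -> VoxelVolume:
    """Load a CT volume from a multi-page TIFF or a directory of slice TIFFs.

    Slices in a directory are ordered lexicographically by filename.  8-bit
    input is promoted to 16 bit by left-shift scaling; 32-bit float input is
    linearly rescaled so its minimum maps to 0 and its maximum to 65535.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slices have mismatched dimensions: {sorted(shapes)}")
        arr = np.stack(slices, axis=0)
    else:
        arr = tifffile.imread(path)
    return _ingest(arr, voxel_size_mm)


def save_stack(obj: VoxelVolume | ROIMask, path: str | Path) -> Path:
    """Write a volume (16-bit) or mask (8-bit, foreground 255) as a multi-page TIFF.

    A JSON sidecar ``<path>.json`` records voxel size and provenance so the
    physical scale is never lost.  ``load_stack(save_stack(x))`` reproduces the
    voxel data exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ROIMask):
        tifffile.imwrite(path, obj.data.astype(np.uint8) * 255)
        meta = {"kind": "mask", "label": obj.label}
    else:
        tifffile.imwrite(path, obj.data)
        meta = {"kind": "volume", "source_dtype": obj.source_dtype}
    meta.update({"voxel_size_mm": obj.voxel_size_mm, "shape": list(obj.shape),
                 "axis_order": "zyx", "writer": "rootct"})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_mask(path: str | Path, voxel_size_mm: float, label: str = "roi") -> ROIMask:
    """Load a binary mask written by :func:`save_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ROIMask(arr > 0, voxel_size_mm, label=label)
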