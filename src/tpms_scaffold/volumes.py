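"""Voxel containers shared across the package.

Arrays are indexed ``(x, y, z)`` and carry physical spacing (mm/voxel) and an
``origin``: the physical coordinate of the *center* of voxel ``(0, 0, 0)``.
The physical bounding box therefore extends half a voxel beyond the first and
last voxel centers on each axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Domain",
    "VoxelVolume",
    "BinaryVolume",
    "save_volume",
    "load_volume",
]


@dataclass(frozen=True)
class Domain:
    """An axis-aligned sampling box: physical corners in mm and voxel counts."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    resolution: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        res = np.asarray(self.resolution, dtype=int)
        if lo.shape != (3,) or hi.shape != (3,) or res.shape != (3,):
            raise ValueError("lower, upper and resolution must each have 3 entries")
        if not np.all(hi > lo):
            raise ValueError("upper corner must exceed lower corner on every axis")
        if not np.all(res >= 2):
            raise ValueError("resolution must be at least 2 voxels per axis")

    @classmethod
    def cube(cls, size: float, resolution: int, lower: float = 0.0) -> "Domain":
        return cls(
            (lower, lower, lower),
            (lower + size, lower + size, lower + size),
            (resolution, resolution, resolution),
        )

    @property
    def spacing(self) -> np.ndarray:
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        return (hi - lo) / np.asarray(self.resolution, float)

    @property
    def origin(self) -> np.ndarray:
        """Center of the first voxel (half-voxel inset from the lower corner)."""
        return np.asarray(self.lower, float) + 0.5 * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis."""
        org, sp = self.origin, self.spacing
        return tuple(
            org[i] + sp[i] * np.arange(self.resolution[i]) for i in range(3)
        )

    def grid(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center positions."""
        ax, ay, az = self.axes()
        out = np.empty((*self.resolution, 3))
        out[..., 0] = ax[:, None, None]
        out[..., 1] = ay[None, :, None]
        out[..., 2] = az[None, None, :]
        return out

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.resolution))


@dataclass
class VoxelVolume:
    """A 3D scalar field sampled at voxel centers."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def box_volume(self) -> float:
        return float(np.prod(np.asarray(self.shape) * np.asarray(self.spacing)))

    def binarize(self, level: float) -> "BinaryVolume":
        """Solid phase is {value <= level} (package-wide sign convention)."""
        return BinaryVolume(self.values <= level, self.spacing, self.origin)


@dataclass
class BinaryVolume:
    """A solid/pore mask with physical spacing; ``True`` marks solid voxels."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def box_volume(self) -> float:
        return float(np.prod(np.asarray(self.shape) * np.asarray(self.spacing)))

    @property
    def solid_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def solid_volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-9))

    def invert(self) -> "BinaryVolume":
        return BinaryVolume(~self.mask, self.spacing, self.origin)


def save_volume(vol: VoxelVolume | BinaryVolume, path: str) -> None:
    """Write a volume as a multipage TIFF with spacing/origin in the metadata.

    The array is stored in (z, y, x) page order; masks are stored as uint8.
    """
    arr = vol.mask.astype(np.uint8) if isinstance(vol, BinaryVolume) else vol.values
    meta = {
        "spacing_mm": list(vol.spacing),
        "origin_mm": list(vol.origin),
        "binary": isinstance(vol, BinaryVolume),
        "axes_order": "xyz",
    }
    tifffile.imwrite(
        path,
        np.ascontiguousarray(np.transpose(arr, (2, 1, 0))),
        description=json.dumps(meta),
    )


def load_volume(path: str) -> VoxelVolume | BinaryVolume:
    """Read a volume written by :func:`save_volume`."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (ValueError, TypeError):
                meta = {}
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D TIFF stack, got ndim={arr.ndim}")
    arr = np.transpose(arr, (2, 1, 0))
    spacing = tuple(meta.get("spacing_mm", (1.0, 1.0, 1.0)))
    origin = tuple(meta.get("origin_mm", tuple(0.5 * s for s in spacing)))
    if meta.get("binary", False):
        return BinaryVolume(arr > 0, spacing, origin)
    return VoxelVolume(arr.astype(float), spacing, origin)
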