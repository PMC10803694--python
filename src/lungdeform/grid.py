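"""Axis-aligned 3D image grids, masks and NIfTI round-tripping.

All volumes in this package live on axis-aligned grids: array index
``(i, j, k)`` maps to world position ``origin + index * spacing`` in mm,
with array axis 0/1/2 corresponding to world x/y/z.  Oblique orientations
are out of scope; NIfTI files with non-diagonal affines are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Geometry", "ImageVolume", "BinaryMask", "read_nifti", "write_nifti"]


@dataclass(frozen=True)
class Geometry:
    """Shape, voxel spacing (mm) and world origin (mm) of a grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"invalid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of world x, y, z for every voxel (each of ``shape``)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (..., 3)."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains_world(self, points_mm: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points_mm)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)


@dataclass
class ImageVolume:
    """A scalar 3D volume with grid geometry."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"data shape {self.data.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume contains non-finite values")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.geometry.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.geometry)


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} mask sharing ImageVolume geometry semantics."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("BinaryMask values must be 0/1")
            self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.geometry)


def _affine_from_geometry(geom: Geometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(geom.spacing)
    aff[:3, 3] = geom.origin
    return aff


def write_nifti(path, volume: ImageVolume) -> None:
    """Write a volume as NIfTI, encoding spacing/origin in a diagonal affine."""
    img = nib.Nifti1Image(np.asarray(volume.data), _affine_from_geometry(volume.geometry))
    img.header.set_zooms(volume.geometry.spacing)
    nib.save(img, str(path))


def read_nifti(path, as_mask: bool = False) -> ImageVolume:
    """Read an axis-aligned NIfTI volume (diagonal affine required)."""
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: non-axis-aligned NIfTI not supported")
    spacing = tuple(float(s) for s in np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: negative/zero spacing in affine")
    geom = Geometry(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=spacing,
        origin=tuple(float(v) for v in aff[:3, 3]),
    )
    data = np.asanyarray(img.dataobj)
    if as_mask:
        return BinaryMask((data > 0.5).astype(np.uint8), geom)
    return ImageVolume(np.asarray(data, dtype=np.float64), geom)
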