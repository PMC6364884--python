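"""Lightweight 3D image containers and NIfTI-1 I/O.

Conventions used throughout the package:

* volumes and masks are dense 3D arrays on a shared voxel lattice;
* the first array axis is the in-plane left--right axis, the second the
  in-plane anterior--posterior axis, and the third axis indexes axial slices;
* voxel sizes are given in millimetres per axis.

Images read from disk are reoriented to the closest RAS-like orientation via
nibabel before the axis convention above is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "BinaryMask", "GridMismatchError",
           "load_volume", "load_mask", "save_volume", "save_mask"]


class GridMismatchError(ValueError):
    """Raised when two images do not share the same voxel lattice."""


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar intensity image.

    Parameters
    ----------
    data:
        Intensity array of shape ``(nx, ny, nslices)``; axial slices are
        indexed by the third axis.
    voxel_size_mm:
        Physical voxel dimensions ``(dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive floats, got {vs}")
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VolumeImage | BinaryMask") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size_mm, other.voxel_size_mm))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean ROI mask on the same lattice as its companion volume."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    role: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask data must be boolean or 0/1")
            arr = arr.astype(bool)
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "VolumeImage | BinaryMask") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size_mm, other.voxel_size_mm))

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self, other)
        return BinaryMask(self.data & other.data, self.voxel_size_mm)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _require_same_grid(self, other)
        return BinaryMask(self.data | other.data, self.voxel_size_mm)


def _require_same_grid(a, b) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"grids differ: {a.shape}@{a.voxel_size_mm} vs {b.shape}@{b.voxel_size_mm}")


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def load_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume, reoriented to the canonical axis convention."""
    data, zooms = _load(path)
    return VolumeImage(np.asarray(data, dtype=np.float64), zooms)


def load_mask(path: str | Path, role: str = "") -> BinaryMask:
    """Read a NIfTI-1 binary mask (any nonzero voxel counts as inside)."""
    data, zooms = _load(path)
    return BinaryMask(np.asarray(data) != 0, zooms, role=role)


def save_volume(volume: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size_mm))
    img.header.set_zooms(mask.voxel_size_mm)
    nib.save(img, str(path))
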