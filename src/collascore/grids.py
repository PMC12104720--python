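"""Volumetric containers and NIfTI input/output.

Conventions used throughout the package: voxel indices are 0-based; axis 0
is sagittal (left-right), axis 1 is coronal, axis 2 is axial
(feet-head), so an axial slice is ``data[:, :, k]``.  World coordinates are
``origin + index * spacing`` (no rotation in the affine we write).  Volumes
carry an ``intensity_kind`` tag: ``"hu"`` for raw Hounsfield-unit data and
``"normalized"`` for window-normalized data in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "VesselMask", "load_volume", "load_mask"]


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and world origin."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "hu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.intensity_kind not in ("hu", "normalized"):
            raise ValueError(f"unknown intensity_kind {self.intensity_kind!r}")
        if self.intensity_kind == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized volume must lie in [0, 1], got range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def with_data(self, data: np.ndarray, intensity_kind: str | None = None) -> "VolumeGrid":
        return replace(
            self, data=data, intensity_kind=intensity_kind or self.intensity_kind
        )

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))


@dataclass
class VesselMask:
    """A binary 3D mask aligned to a :class:`VolumeGrid`.

    Used both for segmented vessels and for territory / hemisphere region
    masks — anything that partitions voxels.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume_mm3

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, zooms, origin


def load_volume(path: str | Path, intensity_kind: str = "hu") -> VolumeGrid:
    """Read a NIfTI scalar volume."""
    data, zooms, origin = _load(path)
    return VolumeGrid(np.asarray(data, dtype=np.float64), zooms, origin, intensity_kind)


def load_mask(path: str | Path) -> VesselMask:
    """Read a NIfTI binary mask (any nonzero voxel is foreground)."""
    data, zooms, origin = _load(path)
    return VesselMask(data > 0, zooms, origin)
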