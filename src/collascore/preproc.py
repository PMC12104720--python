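"""Intensity windowing, midline-symmetric alignment, hemisphere partition.

Intensity normalization maps the annotation display window (level 100 HU,
width 600 HU, i.e. [-200, 400] HU) linearly onto [0, 1] with clipping —
the same window the vessels were traced under.

Alignment is rigid and template-free: the transform (3 rotations, 3
translations) is chosen to maximize the correlation between the volume and
its own sagittal mirror image, which centres the head's midsagittal plane on
the grid's midplane.  Hemisphere comparison downstream only needs that
midline consistency, not inter-subject registration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .grids import VesselMask, VolumeGrid

__all__ = [
    "normalize_window",
    "align_midline",
    "split_hemispheres",
    "HemispherePartition",
    "RigidTransform",
    "DEFAULT_WINDOW_LEVEL_HU",
    "DEFAULT_WINDOW_WIDTH_HU",
]

DEFAULT_WINDOW_LEVEL_HU = 100.0
DEFAULT_WINDOW_WIDTH_HU = 600.0


def normalize_window(
    vol: VolumeGrid,
    level: float = DEFAULT_WINDOW_LEVEL_HU,
    width: float = DEFAULT_WINDOW_WIDTH_HU,
) -> VolumeGrid:
    """Clip-linear map of ``[level - width/2, level + width/2]`` onto [0, 1]."""
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = level - width / 2.0
    out = np.clip((np.asarray(vol.data, dtype=np.float64) - lo) / width, 0.0, 1.0)
    return vol.with_data(out, intensity_kind="normalized")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: rotations (rad, about sagittal/coronal/axial axes)
    and translations (voxel units), applied about the grid centre."""

    rotations_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_params(self) -> np.ndarray:
        return np.array(self.rotations_rad + self.translations_vox, dtype=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotations_rad": list(self.rotations_rad),
                    "translations_vox": list(self.translations_vox),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["rotations_rad"]), tuple(d["translations_vox"]))


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def _resample(data: np.ndarray, params: np.ndarray, order: int = 1) -> np.ndarray:
    """Apply a forward rigid transform (rotate about the grid centre, then
    translate content by ``t`` voxels): output(x) = input(R^-1 (x - c - t) + c)."""
    rx, ry, rz, tx, ty, tz = params
    R = _rotation_matrix(rx, ry, rz)
    center = (np.array(data.shape) - 1) / 2.0
    matrix = R.T
    offset = center - matrix @ (center + np.array([tx, ty, tz]))
    return ndimage.affine_transform(
        data, matrix, offset=offset, order=order, mode="constant", cval=float(np.min(data))
    )


def _mirror_correlation(data: np.ndarray) -> float:
    """Pearson correlation between a volume and its sagittal mirror."""
    a = data.ravel()
    b = data[::-1, :, :].ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def align_midline(
    vol: VolumeGrid,
    max_translation_vox: float = 8.0,
    max_rotation_rad: float = 0.2,
) -> tuple[VolumeGrid, RigidTransform]:
    """Rigidly align a volume so its midsagittal symmetry plane sits on the
    grid midplane.

    Maximizes mirror-correlation over 6 rigid parameters (Powell search with
    a coarse translation pre-scan along the sagittal axis), resampling with
    trilinear interpolation.  If no parameter set beats the identity, a
    warning is emitted and the identity transform returned.
    """
    if vol.shape[0] < 2:
        raise ValueError("alignment needs at least 2 sagittal planes")
    data = np.asarray(vol.data, dtype=np.float64)

    # Only three rigid parameters break sagittal mirror symmetry: the
    # sagittal translation and the two rotations tilting the midplane.
    # The complementary parameters (in-plane translations, rotation about
    # the sagittal axis) commute with the mirror, are unidentifiable from
    # this objective, and are pinned to zero.
    def full_params(p3: np.ndarray) -> np.ndarray:
        ry, rz, tx = p3
        return np.array([0.0, ry, rz, tx, 0.0, 0.0])

    def neg_score(p3: np.ndarray) -> float:
        return -_mirror_correlation(_resample(data, full_params(p3)))

    base = -_mirror_correlation(data)
    # coarse integer pre-scan on sagittal translation (the dominant mode)
    best_t0 = 0.0
    best_v = base
    for t0 in np.arange(-max_translation_vox, max_translation_vox + 1):
        v = neg_score(np.array([0.0, 0.0, t0]))
        if v < best_v:
            best_v, best_t0 = v, float(t0)
    x0 = np.array([0.0, 0.0, best_t0])
    res = optimize.minimize(
        neg_score,
        x0,
        method="Powell",
        bounds=[(-max_rotation_rad, max_rotation_rad)] * 2
        + [(-max_translation_vox, max_translation_vox)],
        options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 60},
    )
    candidates = [(base, np.zeros(3)), (best_v, x0), (float(res.fun), np.asarray(res.x))]
    best_fun, best_p3 = min(candidates, key=lambda c: c[0])
    if best_fun >= base - 1e-12:
        if not np.allclose(best_p3, 0.0):
            warnings.warn(
                "midline alignment found no improvement over identity; "
                "returning identity",
                stacklevel=2,
            )
        return vol, RigidTransform()
    params = full_params(best_p3)
    transform = RigidTransform(
        tuple(float(p) for p in params[:3]), tuple(float(p) for p in params[3:])
    )
    aligned = vol.with_data(_resample(data, params))
    return aligned, transform


@dataclass
class HemispherePartition:
    """Left/right hemisphere region masks split at a midsagittal plane."""

    left_mask: VesselMask
    right_mask: VesselMask
    midline_plane_index: float
    convention: str = "radiological (sagittal index increases toward patient left)"


def split_hemispheres(
    vol_shape: tuple[int, int, int],
    midline_plane_index: float | None = None,
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625),
) -> HemispherePartition:
    """Partition voxels into hemispheres at a sagittal midline.

    Sagittal indices below the midline go to the right hemisphere, above it
    to the left.  An integer midline equal to half an even sagittal extent is
    read as the sheet boundary (effective half-index ``m - 0.5``), so an even
    extent splits cleanly in two; with an odd extent an integer midline names
    the single midplane sheet, which belongs to neither hemisphere.
    """
    S = int(vol_shape[0])
    if midline_plane_index is None:
        midline_plane_index = (S - 1) / 2.0
    m = float(midline_plane_index)
    if not (0 < m < S):
        raise ValueError(f"midline {m} outside sagittal extent {S}")
    eff = m - 0.5 if (m == int(m) and int(2 * m) == S) else m
    sag = np.arange(S)[:, None, None]
    ones = np.ones(vol_shape, dtype=bool)
    right = ones & (sag < eff)
    left = ones & (sag > eff)
    return HemispherePartition(
        left_mask=VesselMask(left, spacing_mm),
        right_mask=VesselMask(right, spacing_mm),
        midline_plane_index=m,
    )
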