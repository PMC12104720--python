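"""Synthetic CTA-like head phantoms with paired-hemisphere vascular trees.

Each phantom holds two tubular "vascular trees", one per hemisphere, inside
mirror-symmetric half-ellipsoid territory masks.  The healthy-side tree is a
random branching tube structure; the affected-side tree is its midsagittal
mirror image, rescaled (and trimmed voxel-by-voxel from the surface inward)
until the affected/healthy voxel-volume ratio hits a requested target.  That
construction makes the ground-truth volume ratio a controlled quantity, which
is the property the downstream collateral score needs — no attempt is made at
anatomically realistic Circle-of-Willis topology.

Intensities emulate contrast-enhanced CT: bright vessels (uniform draw from a
Hounsfield-unit interval) over a noisy parenchyma background, at the axial
slice spacing of a thin-slice CTA acquisition (0.625 mm).  All randomness is
driven by explicit integer seeds; two calls with the same spec are
bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import VesselMask, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "PhantomError",
    "generate_phantom",
    "generate_cohort",
    "slice_dataset",
    "territory_masks",
]

#: quaternary-grade qCS intervals on the ratio (not percent) scale, used for
#: stratified cohort sampling: (0, 0.05], (0.05, 0.49], (0.49, 0.95], (0.95, 1.2]
QUATERNARY_RATIO_INTERVALS: tuple[tuple[float, float], ...] = (
    (0.005, 0.05),
    (0.05, 0.49),
    (0.49, 0.95),
    (0.95, 1.2),
)


class PhantomError(RuntimeError):
    """Raised when a phantom cannot be generated under the given constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom case.

    ``true_ratio`` is the target affected/healthy vessel-volume ratio (1.0 =
    symmetric collaterals, 0 = no affected-side vessels).  ``tortuosity``
    bounds the per-step direction change of the centerline random walk
    (0 = straight tubes).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625)
    n_branches: int = 6
    radius_range_mm: tuple[float, float] = (0.6, 1.8)
    tortuosity: float = 0.35
    true_ratio: float = 1.0
    affected_side: str = "left"
    vessel_hu_range: tuple[float, float] = (150.0, 450.0)
    background_hu: float = 35.0
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes all >= 16, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.true_ratio < 0 or self.true_ratio > 1.5:
            raise ValueError(f"true_ratio must be in [0, 1.5], got {self.true_ratio}")
        if self.radius_range_mm[0] > self.radius_range_mm[1]:
            raise ValueError("radius_range_mm min must be <= max")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")


@dataclass
class PhantomCase:
    """A generated phantom: HU volume, ground-truth masks, achieved ratio."""

    volume: VolumeGrid
    gt_vessels: VesselMask
    territory_left: VesselMask
    territory_right: VesselMask
    realized_ratio: float
    spec: PhantomSpec
    case_id: str = "phantom"


# ---------------------------------------------------------------------------
# territory masks

def territory_masks(
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.625),
) -> tuple[VesselMask, VesselMask]:
    """Mirror-symmetric half-ellipsoid hemisphere territories.

    The ellipsoid is centred on the grid with semi-axes at 45% of each
    extent; sagittal indices below the midsagittal plane form the right
    territory, above it the left (radiological convention: axis 0 increases
    toward the patient's left).
    """
    shape = tuple(int(s) for s in grid_shape)
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    ellipsoid = r2 <= 1.0
    sag = np.arange(shape[0])[:, None, None]
    mid = centers[0]
    left = ellipsoid & (sag > mid)
    right = ellipsoid & (sag < mid)
    return (
        VesselMask(left, spacing_mm),
        VesselMask(right, spacing_mm),
    )


# ---------------------------------------------------------------------------
# tree synthesis

def _grow_centerlines(
    spec: PhantomSpec, territory: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random branching tube centerlines inside a territory.

    Returns (points, radii): an (N, 3) float array of voxel-space centerline
    samples and their radii in mm.  Branches start near the inferior-medial
    part of the territory (a crude stand-in for the proximal arteries) and
    walk outward with direction persistence; the per-step turn is bounded by
    ``tortuosity``.  Radii taper linearly from max to min along each branch.
    """
    shape = np.array(spec.grid_shape, dtype=float)
    spacing = np.array(spec.spacing_mm)
    idx = np.argwhere(territory)
    if idx.size == 0:
        raise PhantomError("territory mask is empty; grid too coarse")
    # root region: medial third (toward midline), inferior half of axial axis
    sag_mid = (shape[0] - 1) / 2.0
    medial = np.abs(idx[:, 0] - sag_mid)
    order = np.argsort(medial + 0.5 * idx[:, 2])
    root_pool = idx[order[: max(8, len(order) // 50)]]

    r_min, r_max = spec.radius_range_mm
    step_mm = max(spacing.min(), 0.5 * r_min)
    pts: list[np.ndarray] = []
    radii: list[float] = []
    # parent branches then child branches forked from random parent points
    branch_starts: list[tuple[np.ndarray, np.ndarray, float]] = []
    for b in range(spec.n_branches):
        if b == 0 or not pts:
            start = root_pool[rng.integers(len(root_pool))].astype(float)
            direction = rng.normal(size=3)
        else:
            j = int(rng.integers(len(pts)))
            start = pts[j].copy()
            direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction) + 1e-12
        n_steps = int(rng.integers(20, 45))
        r0 = rng.uniform(0.7 * r_max, r_max)
        p = start.copy()
        for s in range(n_steps):
            frac = s / max(n_steps - 1, 1)
            r = r0 + (r_min - r0) * frac
            pts.append(p.copy())
            radii.append(r)
            turn = rng.normal(scale=spec.tortuosity, size=3)
            direction = direction + turn
            direction /= np.linalg.norm(direction) + 1e-12
            step_vox = step_mm / spacing
            p_next = p + direction * step_vox
            pi = np.round(p_next).astype(int)
            inside = np.all(pi >= 0) and np.all(pi < shape) and territory[tuple(pi)]
            if not inside:
                # bounce back toward territory centroid
                centroid = idx.mean(axis=0)
                direction = centroid - p
                direction /= np.linalg.norm(direction) + 1e-12
                p_next = p + direction * step_vox
                pi = np.round(p_next).astype(int)
                if not (np.all(pi >= 0) and np.all(pi < shape) and territory[tuple(pi)]):
                    break
            p = p_next
    if not pts:
        raise PhantomError("no centerline points placed; territory too small")
    return np.array(pts), np.array(radii)


def _rasterize(
    points: np.ndarray,
    radii_mm: np.ndarray,
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    radius_scale: float,
) -> np.ndarray:
    """Union of spheres along the centerline, radius in mm scaled by ``radius_scale``."""
    mask = np.zeros(shape, dtype=bool)
    if radius_scale <= 0:
        return mask
    spacing = np.asarray(spacing_mm)
    for p, r in zip(points, radii_mm):
        r_eff = r * radius_scale
        half = np.ceil(r_eff / spacing).astype(int)
        lo = np.maximum(np.round(p).astype(int) - half, 0)
        hi = np.minimum(np.round(p).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        sub = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(sub, p, spacing))
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= r_eff**2
    return mask


def _mirror_sagittal(mask: np.ndarray) -> np.ndarray:
    return mask[::-1, :, :].copy()


def _trim_to_count(mask: np.ndarray, target: int) -> np.ndarray:
    """Remove surface voxels (shallowest first, deterministic order) until
    exactly ``target`` remain."""
    n = int(mask.sum())
    if n <= target:
        return mask
    depth = ndimage.distance_transform_edt(mask)
    flat = np.flatnonzero(mask.ravel())
    keys = depth.ravel()[flat]
    # remove smallest depth first; stable tie-break on flat index
    order = np.lexsort((flat, keys))
    kill = flat[order[: n - target]]
    out = mask.copy()
    out.ravel()[kill] = False
    return out


# ---------------------------------------------------------------------------
# main generators

def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; deterministic for a fixed spec.

    The healthy-hemisphere tree is drawn from the spec's random process.  The
    affected-hemisphere tree is the mirrored healthy tree with its radii
    rescaled (bisection on the scale factor, then exact surface trimming) so
    that the affected/healthy voxel count ratio equals ``true_ratio`` to
    within a voxel.  ``true_ratio == 1`` short-circuits to the exact mirror.
    """
    rng = np.random.default_rng(spec.seed)
    terr_left, terr_right = territory_masks(spec.grid_shape, spec.spacing_mm)
    healthy_terr = terr_right if spec.affected_side == "left" else terr_left
    affected_terr = terr_left if spec.affected_side == "left" else terr_right

    points, radii = _grow_centerlines(spec, healthy_terr.data, rng)
    healthy = _rasterize(points, radii, spec.grid_shape, spec.spacing_mm, 1.0)
    healthy &= healthy_terr.data
    n_healthy = int(healthy.sum())
    if n_healthy == 0:
        raise PhantomError(
            "healthy tree rasterized to zero voxels: grid resolution too coarse "
            f"for radius range {spec.radius_range_mm} at spacing {spec.spacing_mm}"
        )

    if spec.true_ratio == 1.0:
        affected = _mirror_sagittal(healthy) & affected_terr.data
        if int(affected.sum()) != n_healthy:
            # territories are mirror-symmetric so this cannot trigger, but guard it
            raise PhantomError("mirror symmetry violated by territory masks")
    elif spec.true_ratio == 0.0:
        affected = np.zeros(spec.grid_shape, dtype=bool)
    else:
        target = int(round(spec.true_ratio * n_healthy))
        if target == 0:
            raise PhantomError(
                f"true_ratio {spec.true_ratio} unattainable: target voxel count "
                f"rounds to zero at this resolution (healthy tree {n_healthy} voxels)"
            )
        m_points = points.copy()
        m_points[:, 0] = (spec.grid_shape[0] - 1) - m_points[:, 0]

        def count_at(scale: float) -> int:
            m = _rasterize(m_points, radii, spec.grid_shape, spec.spacing_mm, scale)
            m &= affected_terr.data
            return int(m.sum())

        lo, hi = 0.0, 1.0
        if target > n_healthy:  # ratio > 1: inflate radii
            while count_at(hi) < target and hi < 4.0:
                hi *= 1.3
            if count_at(hi) < target:
                raise PhantomError(
                    f"true_ratio {spec.true_ratio} unattainable: affected territory "
                    "saturates below the target volume"
                )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if count_at(mid) >= target:
                hi = mid
            else:
                lo = mid
        affected = _rasterize(m_points, radii, spec.grid_shape, spec.spacing_mm, hi)
        affected &= affected_terr.data
        affected = _trim_to_count(affected, target)

    realized = int(affected.sum()) / n_healthy
    gt = healthy | affected

    # CTA-like intensities: background noise field, vessels overwritten
    vol = rng.normal(spec.background_hu, spec.noise_sd_hu, size=spec.grid_shape)
    lo_hu, hi_hu = spec.vessel_hu_range
    vol[gt] = rng.uniform(lo_hu, hi_hu, size=int(gt.sum()))

    return PhantomCase(
        volume=VolumeGrid(vol, spec.spacing_mm, intensity_kind="hu"),
        gt_vessels=VesselMask(gt, spec.spacing_mm),
        territory_left=terr_left,
        territory_right=terr_right,
        realized_ratio=realized,
        spec=spec,
        case_id=f"phantom_seed{spec.seed}",
    )


def _case_seed(master_seed: int, i: int) -> int:
    """Stable per-case seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def generate_cohort(
    n_cases: int,
    base_spec: PhantomSpec,
    seed: int,
    ratio_sampler: str | tuple[float, float] = "stratified",
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate a cohort of phantoms with a reproducible manifest.

    ``ratio_sampler`` is either ``"stratified"`` (cycle through the four
    quaternary-grade ratio intervals, uniform within each) or a
    ``(low, high)`` tuple for uniform sampling.  If ``out_dir`` is given,
    volumes and masks are written as ``.nii.gz`` and the manifest as
    ``manifest.csv`` with file paths filled in.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if ratio_sampler == "stratified" and n_cases < len(QUATERNARY_RATIO_INTERVALS):
        raise ValueError(
            f"stratified sampling over {len(QUATERNARY_RATIO_INTERVALS)} grade "
            f"intervals needs at least that many cases, got {n_cases}"
        )
    master = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    rows = []
    for i in range(n_cases):
        if ratio_sampler == "stratified":
            lo, hi = QUATERNARY_RATIO_INTERVALS[i % len(QUATERNARY_RATIO_INTERVALS)]
        else:
            lo, hi = ratio_sampler
        ratio = float(master.uniform(lo, hi))
        side = "left" if master.uniform() < 0.5 else "right"
        cs = _case_seed(seed, i)
        spec = replace(base_spec, true_ratio=round(ratio, 4), affected_side=side, seed=cs)
        case = generate_phantom(spec)
        case.case_id = f"case{i:03d}"
        cases.append(case)
        row = {
            "case_id": case.case_id,
            "true_ratio": spec.true_ratio,
            "realized_ratio": case.realized_ratio,
            "affected_side": side,
            "volume_path": "",
            "mask_path": "",
            "territory_left_path": "",
            "territory_right_path": "",
            "seed": cs,
        }
        if out_dir is not None:
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            paths = {
                "volume_path": d / f"{case.case_id}_cta.nii.gz",
                "mask_path": d / f"{case.case_id}_vessels.nii.gz",
                "territory_left_path": d / f"{case.case_id}_territory_left.nii.gz",
                "territory_right_path": d / f"{case.case_id}_territory_right.nii.gz",
            }
            case.volume.save(paths["volume_path"])
            case.gt_vessels.save(paths["mask_path"])
            case.territory_left.save(paths["territory_left_path"])
            case.territory_right.save(paths["territory_right_path"])
            row.update({k: str(v) for k, v in paths.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return cases, manifest


def slice_dataset(
    cases: list[PhantomCase],
) -> list[dict]:
    """Axial image/mask slice pairs with case provenance.

    Emits every axial slice that intersects the union of territory masks,
    once, as ``{"case_id", "slice_index", "image", "mask"}`` with the image
    in raw HU.  Empty-vessel slices are kept (all-zero mask) so the training
    set sees negatives.  The case id is retained so cross-validation can
    split by case, never by slice.
    """
    if not cases:
        raise ValueError("cases must be non-empty")
    out = []
    for case in cases:
        terr = case.territory_left.data | case.territory_right.data
        for k in range(case.volume.shape[2]):
            if not terr[:, :, k].any():
                continue
            out.append(
                {
                    "case_id": case.case_id,
                    "slice_index": k,
                    "image": np.ascontiguousarray(case.volume.data[:, :, k]),
                    "mask": np.ascontiguousarray(case.gt_vessels.data[:, :, k]),
                }
            )
    return out
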