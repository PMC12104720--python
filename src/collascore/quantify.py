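"""Quantitative collateral score (qCS), grading, and threshold refinement.

The qCS is the vessel volume of the stroke-affected hemisphere's MCA
territory expressed as a percentage of the healthy side's:

    qCS(%) = 100 * V_affected / V_healthy,   qCS >= 0

The affected side is a clinical input, never inferred from the image.  The
score maps onto three grading schemes sharing cut points at 5, 49 and 95%:
binary (poor/good at 49), quaternary 0-3 (Tan-like), and six-class 0-5
(Menon-like, adding cuts at 25 and 75).  All interval upper ends are closed
("<=") so, e.g., qCS = 49.0 is still poor.

``sweep_thresholds`` reproduces the refinement procedure that produced those
cuts: around each nominal boundary it scores every candidate cutoff in a
+/-5-point window at 1-point steps against reference labels, ranking by
accuracy with a Youden-style (sensitivity+specificity) tie-break, then
proximity to the nominal value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import VesselMask

__all__ = [
    "GradeThresholds",
    "QCSResult",
    "CollateralGrade",
    "SweepResult",
    "DegenerateCaseError",
    "territory_volume",
    "compute_qcs",
    "classify",
    "quantify_case",
    "sweep_thresholds",
]


class DegenerateCaseError(ValueError):
    """Raised when the qCS is mathematically undefined (zero healthy volume)."""


@dataclass(frozen=True)
class GradeThresholds:
    """Cut points (percent) shared by the three grading schemes."""

    t_floor: float = 5.0
    t_binary: float = 49.0
    t_ceiling: float = 95.0
    six_class_cuts: tuple[float, ...] = (5.0, 25.0, 49.0, 75.0, 95.0)

    def __post_init__(self) -> None:
        cuts = (self.t_floor, self.t_binary, self.t_ceiling)
        if not all(0 <= c <= 100 for c in cuts):
            raise ValueError(f"thresholds must lie in [0, 100], got {cuts}")
        if not (self.t_floor < self.t_binary < self.t_ceiling):
            raise ValueError(f"thresholds must be strictly increasing, got {cuts}")
        if tuple(sorted(self.six_class_cuts)) != tuple(self.six_class_cuts):
            raise ValueError("six_class_cuts must be increasing")
        for c in cuts:
            if c not in self.six_class_cuts:
                raise ValueError(f"six_class_cuts must contain {c}")

    @property
    def quaternary_cuts(self) -> tuple[float, float, float]:
        return (self.t_floor, self.t_binary, self.t_ceiling)


@dataclass(frozen=True)
class QCSResult:
    v_affected_mm3: float
    v_healthy_mm3: float
    qcs_percent: float
    affected_side: str


@dataclass(frozen=True)
class CollateralGrade:
    binary: str  # "poor" | "good"
    quaternary: int  # 0..3
    six_class: int  # 0..5


@dataclass
class SweepResult:
    """Per-boundary candidate tables and chosen thresholds."""

    tables: dict[float, pd.DataFrame]
    chosen: dict[float, float]
    skipped: dict[float, str] = field(default_factory=dict)


def territory_volume(
    mask: VesselMask, territory: VesselMask, spacing_mm: Sequence[float] | None = None
) -> float:
    """Vessel volume (mm^3) inside a territory: voxel count times voxel volume."""
    if mask.shape != territory.shape:
        raise ValueError(f"mask shape {mask.shape} != territory shape {territory.shape}")
    spacing = tuple(spacing_mm) if spacing_mm is not None else mask.spacing_mm
    if spacing_mm is None and mask.spacing_mm != territory.spacing_mm:
        raise ValueError(
            f"mask spacing {mask.spacing_mm} != territory spacing {territory.spacing_mm}"
        )
    n = int((mask.data & territory.data).sum())
    return n * float(np.prod(spacing))


def compute_qcs(
    v_affected_mm3: float, v_healthy_mm3: float, affected_side: str = "left"
) -> QCSResult:
    """qCS(%) = 100 * V_affected / V_healthy; may exceed 100."""
    if v_affected_mm3 < 0 or v_healthy_mm3 < 0:
        raise ValueError("volumes must be non-negative")
    if v_healthy_mm3 == 0:
        raise DegenerateCaseError(
            "healthy-hemisphere vessel volume is zero; qCS undefined"
        )
    return QCSResult(
        v_affected_mm3=float(v_affected_mm3),
        v_healthy_mm3=float(v_healthy_mm3),
        qcs_percent=100.0 * v_affected_mm3 / v_healthy_mm3,
        affected_side=affected_side,
    )


def classify(
    qcs_percent: float, thresholds: GradeThresholds = GradeThresholds()
) -> CollateralGrade:
    """Grade a qCS on all three schemes; interval upper ends are closed."""
    q = float(qcs_percent)
    if q < 0:
        raise ValueError(f"qcs must be >= 0, got {q}")
    t = thresholds
    quaternary = int(np.searchsorted(np.asarray(t.quaternary_cuts), q, side="left"))
    six_class = int(np.searchsorted(np.asarray(t.six_class_cuts), q, side="left"))
    binary = "good" if q > t.t_binary else "poor"
    return CollateralGrade(binary=binary, quaternary=quaternary, six_class=six_class)


def quantify_case(
    mask: VesselMask,
    territory_affected: VesselMask,
    territory_healthy: VesselMask,
    affected_side: str,
    thresholds: GradeThresholds = GradeThresholds(),
    territory_source: str = "explicit",
    case_id: str | None = None,
) -> dict:
    """Full per-case quantification: volumes, qCS, grades, provenance.

    ``affected_side`` comes from the clinic; the caller passes the
    territory masks already ordered (affected, healthy).  If explicit MCA
    territories are unavailable, pass hemisphere-partition masks and set
    ``territory_source="hemisphere_partition"``.
    """
    if affected_side not in ("left", "right"):
        raise ValueError("affected_side must be 'left' or 'right'")
    v_aff = territory_volume(mask, territory_affected)
    v_heal = territory_volume(mask, territory_healthy)
    try:
        result = compute_qcs(v_aff, v_heal, affected_side)
    except DegenerateCaseError as e:
        raise DegenerateCaseError(f"case {case_id or '<unnamed>'}: {e}") from e
    grade = classify(result.qcs_percent, thresholds)
    return {
        "case_id": case_id,
        "v_affected_mm3": result.v_affected_mm3,
        "v_healthy_mm3": result.v_healthy_mm3,
        "qcs_percent": result.qcs_percent,
        "affected_side": affected_side,
        "binary": grade.binary,
        "quaternary": grade.quaternary,
        "six_class": grade.six_class,
        "territory_source": territory_source,
        "thresholds": thresholds.quaternary_cuts,
    }


def _score_candidate(qcs: np.ndarray, positive: np.ndarray, cand: float) -> dict:
    pred = qcs > cand
    tp = int((pred & positive).sum())
    tn = int((~pred & ~positive).sum())
    fp = int((pred & ~positive).sum())
    fn = int((~pred & positive).sum())
    n = len(qcs)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "candidate": cand,
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
    }


def sweep_thresholds(
    qcs_values: Sequence[float],
    reference_labels: Sequence,
    nominal: Sequence[float] = (0.0, 50.0, 100.0),
    half_window: float = 5.0,
    step: float = 1.0,
) -> SweepResult:
    """Refine nominal grade boundaries against reference labels.

    ``reference_labels`` are ordinal grades (ints) with one more level than
    there are nominal boundaries — boundary ``i`` dichotomizes grade <= i vs
    grade > i — or, with a single nominal boundary, any binary labels
    (0/1 or "poor"/"good").  For each nominal t the candidates are
    ``max(0, t - half_window) .. t + half_window`` in ``step`` increments; a
    case is predicted above the boundary when qcs > candidate.  Chosen
    candidate = argmax accuracy, ties broken by max sensitivity+specificity,
    then by proximity to the nominal, then by the smaller candidate.
    Boundaries whose reference dichotomy is single-class are skipped with a
    warning.
    """
    qcs = np.asarray(qcs_values, dtype=float)
    labels = list(reference_labels)
    if len(qcs) != len(labels):
        raise ValueError("qcs_values and reference_labels lengths differ")
    if set(labels) <= {"poor", "good"}:
        grades = np.array([0 if l == "poor" else 1 for l in labels])
    else:
        grades = np.asarray(labels, dtype=int)
    tables: dict[float, pd.DataFrame] = {}
    chosen: dict[float, float] = {}
    skipped: dict[float, str] = {}
    binary_labels = grades.max() <= 1
    for i, t in enumerate(nominal):
        positive = (grades >= 1) if binary_labels else (grades > i)
        if positive.all() or (~positive).all():
            msg = f"single-class reference at boundary {t}; skipped"
            warnings.warn(msg, stacklevel=2)
            skipped[float(t)] = msg
            continue
        lo = max(0.0, t - half_window)
        cands = np.arange(lo, t + half_window + step / 2, step)
        rows = [_score_candidate(qcs, positive, float(c)) for c in cands]
        table = pd.DataFrame(rows)

        def sort_key(j: int) -> tuple:
            r = table.iloc[j]
            youden = np.nan_to_num(r["sensitivity"]) + np.nan_to_num(r["specificity"])
            return (-r["accuracy"], -youden, abs(r["candidate"] - t), r["candidate"])

        best = min(range(len(table)), key=sort_key)
        tables[float(t)] = table
        chosen[float(t)] = float(table.iloc[best]["candidate"])
    return SweepResult(tables=tables, chosen=chosen, skipped=skipped)
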