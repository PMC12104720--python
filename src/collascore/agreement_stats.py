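"""Agreement and classification statistics for collateral scoring.

Covers the full evaluation vocabulary of the pipeline: Dice overlap between
masks, K-class confusion matrices with the derived binary metrics
(accuracy, F1, sensitivity, specificity, Matthews correlation), rank-based
ROC-AUC with a Hanley–McNeil confidence interval, Spearman rank correlation,
and the single-measure absolute-agreement intraclass correlation ICC(2,1)
from the two-way random-effects ANOVA decomposition.

Metrics with a zero denominator are reported as ``None`` together with a
reason string — never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "dice",
    "confusion",
    "binary_metrics",
    "multiclass_accuracy",
    "per_class_recall",
    "roc_auc",
    "spearman",
    "icc_2_1",
]


def dice(a, b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) between two binary masks.

    Two empty masks count as perfect agreement (1.0) — agreement on the
    absence of foreground; conventions differ, so this policy is explicit.
    """
    def as_bool(x):
        if not isinstance(x, np.ndarray) and hasattr(x, "data"):
            x = x.data  # VesselMask-like container
        return np.asarray(x).astype(bool)

    da, db = as_bool(a), as_bool(b)
    if da.shape != db.shape:
        raise ValueError(f"mask shapes differ: {da.shape} vs {db.shape}")
    na, nb = int(da.sum()), int(db.sum())
    if na + nb == 0:
        return 1.0
    inter = int((da & db).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are reference, columns are prediction."""

    counts: np.ndarray
    vocabulary: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key):
        return self.counts[key]


def confusion(reference: Sequence, predicted: Sequence, vocabulary: Sequence) -> ConfusionMatrix:
    """Count paired labels into a confusion matrix with a fixed class order.

    Classes in the vocabulary but absent from the data keep their zero
    row/column.
    """
    ref = list(reference)
    pred = list(predicted)
    if len(ref) != len(pred):
        raise ValueError(f"length mismatch: {len(ref)} reference vs {len(pred)} predicted")
    vocab = tuple(vocabulary)
    index = {v: i for i, v in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)), dtype=np.int64)
    for r, p in zip(ref, pred):
        if r not in index:
            raise ValueError(f"unknown reference label {r!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts, vocab)


def binary_metrics(cm: ConfusionMatrix, positive_index: int = 1) -> dict:
    """Accuracy, F1, sensitivity, specificity and MCC from a 2x2 matrix.

    The positive class defaults to index 1 of the vocabulary (by the
    pipeline's convention, "good collateral").  Any metric with a zero
    denominator comes back as ``None`` with its reason in ``undefined``.
    """
    if cm.counts.shape != (2, 2):
        raise ValueError(f"binary_metrics needs a 2x2 matrix, got {cm.counts.shape}")
    pos, neg = positive_index, 1 - positive_index
    tp = int(cm.counts[pos, pos])
    tn = int(cm.counts[neg, neg])
    fp = int(cm.counts[neg, pos])
    fn = int(cm.counts[pos, neg])
    total = tp + tn + fp + fn
    undefined: dict[str, str] = {}

    def ratio(num, den, name):
        if den == 0:
            undefined[name] = "zero denominator"
            return None
        return num / den

    accuracy = ratio(tp + tn, total, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined["mcc"] = "zero denominator"
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": accuracy,
        "f1": f1,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "mcc": mcc,
        "undefined": undefined,
    }


def multiclass_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_recall(cm: ConfusionMatrix, cls) -> float | None:
    i = cm.vocabulary.index(cls)
    row = int(cm.counts[i].sum())
    if row == 0:
        return None
    return float(cm.counts[i, i]) / row


def roc_auc(scores: Sequence[float], labels: Sequence[int], alpha: float = 0.05) -> dict:
    """Rank-based (Mann–Whitney) AUC of continuous scores against a binary
    reference; ties contribute 1/2.  95% CI by the Hanley–McNeil normal
    approximation, clipped to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "auc": float(auc),
        "ci_low": float(np.clip(auc - z * se, 0, 1)),
        "ci_high": float(np.clip(auc + z * se, 0, 1)),
        "n_positive": n1,
        "n_negative": n0,
    }


def spearman(x: Sequence[float], y: Sequence[float]) -> dict:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": None, "p": None, "undefined": "zero rank variance"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "undefined": None}


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n targets x k raters) complete matrix.  The point
    estimate is (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) from the
    two-way ANOVA mean squares (MSR rows/targets, MSC columns/raters, MSE
    residual); the 95% CI uses the F-distribution method with a
    Satterthwaite-approximated denominator df.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D targets x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires at least 2 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete (no NaN)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(ss_total, 0.0):
        return {
            "icc": None,
            "ci_low": None,
            "ci_high": None,
            "undefined": "zero between-target variance",
        }
    icc = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measure)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:
        ci_low, ci_high = icc, icc
    return {
        "icc": float(icc),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "undefined": None,
        "anova": {"msr": float(msr), "msc": float(msc), "mse": float(mse)},
        "n": n,
        "k": k,
    }


@dataclass
class MetricsReport:
    """Aggregate evaluation report for one comparison."""

    n: int
    dsc_mean: float | None = None
    accuracy: float | None = None
    f1: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    mcc: float | None = None
    auc: dict | None = None
    spearman_rho: dict | None = None
    icc: dict | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "dsc_mean": self.dsc_mean,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
            "spearman_rho": self.spearman_rho,
            "icc": self.icc,
            "notes": self.notes,
        }
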