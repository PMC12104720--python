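"""Development protocol: stratified case-level folds, augmentation,
early-stopped training, and grid search over (learning rate, batch size).

The protocol mirrors common segmentation practice: 5-fold cross-validation
stratified by collateral grade at the *case* level (slices from one case
never straddle the train/validation boundary), Adam with a small grid of
learning rates {1e-3, 1e-4, 1e-5} and batch sizes {8, 16, 32}, up to 500
epochs with early stopping once the best validation Dice has not improved
for 20 consecutive epochs, and selection of the winning grid cell by mean
best-validation-DSC across folds.  The final model is the winning cell's
single best fold (weights from that fold's best epoch), not a retrain on
all data; ``refit`` is available for the alternative.

Validation DSC is volume-wise: each validation case is segmented as a
volume and its Dice against the ground-truth mask contributes one number;
the epoch's validation score is the mean over cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .agreement_stats import dice
from .preproc import normalize_window
from .u2net_core import ModelConfig, U2Net, build_model, predict_mask
from . import _autograd as ag

__all__ = [
    "AugmentSpec",
    "TrainConfig",
    "CVReport",
    "EarlyStopper",
    "early_stop_epoch",
    "make_folds",
    "augment_pair",
    "train_one",
    "grid_search_cv",
    "DEFAULT_GRID",
]

#: the hyperparameter grid searched during development
DEFAULT_GRID: tuple[tuple[float, int], ...] = tuple(
    (lr, bs) for lr in (1e-3, 1e-4, 1e-5) for bs in (8, 16, 32)
)


@dataclass(frozen=True)
class AugmentSpec:
    """Slice-level augmentation parameters; every range contains identity."""

    flip_prob: float = 0.5
    brightness_delta: float = 0.2  # multiplicative: factor in [1-d, 1+d]
    contrast_range: tuple[float, float] = (0.8, 1.2)
    rotation_deg: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not (0 <= self.flip_prob <= 1):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.brightness_delta < 0 or self.rotation_deg < 0:
            raise ValueError("brightness_delta and rotation_deg must be >= 0")
        if not (self.contrast_range[0] <= 1.0 <= self.contrast_range[1]):
            raise ValueError("contrast_range must contain 1.0 (identity)")
        if not (self.zoom_range[0] <= 1.0 <= self.zoom_range[1]):
            raise ValueError("zoom_range must contain 1.0 (identity)")

    @property
    def is_identity(self) -> bool:
        return (
            self.flip_prob == 0
            and self.brightness_delta == 0
            and self.contrast_range == (1.0, 1.0)
            and self.rotation_deg == 0
            and self.zoom_range == (1.0, 1.0)
        )

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls(0.0, 0.0, (1.0, 1.0), 0.0, (1.0, 1.0))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 500
    patience_epochs: int = 20
    min_delta: float = 0.0
    n_folds: int = 5
    augmentation: AugmentSpec = field(default_factory=AugmentSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience_epochs >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


# ---------------------------------------------------------------------------
# folds

def make_folds(case_ids, labels, n_folds: int = 5, seed: int = 0) -> dict:
    """Case-level stratified fold assignment {case_id: fold}.

    Within each stratum, cases are shuffled (seeded) and dealt round-robin
    starting at the running global offset, which keeps per-fold stratum
    proportions within one case of the global proportions and overall fold
    sizes within one of each other.  A stratum smaller than ``n_folds``
    cannot appear in every fold; it is distributed round-robin with a
    warning.
    """
    case_ids = list(case_ids)
    labels = list(labels)
    if len(case_ids) != len(labels):
        raise ValueError("case_ids and labels lengths differ")
    if len(case_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    by_stratum: dict = {}
    for cid, lab in zip(case_ids, labels):
        by_stratum.setdefault(lab, []).append(cid)
    assignment: dict = {}
    offset = 0
    for lab in sorted(by_stratum, key=repr):
        ids = by_stratum[lab]
        if len(ids) < n_folds:
            warnings.warn(
                f"stratum {lab!r} has {len(ids)} case(s) < {n_folds} folds; "
                "distributed round-robin",
                stacklevel=2,
            )
        order = rng.permutation(len(ids))
        for j, k in enumerate(order):
            assignment[ids[k]] = (offset + j) % n_folds
        offset += len(ids)
    return assignment


# ---------------------------------------------------------------------------
# augmentation

def augment_pair(
    image: np.ndarray, mask: np.ndarray, spec: AugmentSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One augmented (image, mask) pair; same geometry for both.

    Geometric transforms (flips, rotation, zoom) hit image and mask alike —
    bilinear for the image, nearest-neighbour for the mask.  Photometric
    transforms (multiplicative brightness, then contrast scaling about the
    slice mean) touch only the image, which is re-clipped to [0, 1].  When
    the spec is the identity the inputs are returned bit-exact.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("augment_pair expects a normalized image in [0, 1]")
    msk = np.asarray(mask)
    if spec.is_identity:
        return img.copy(), msk.copy()
    rng = np.random.default_rng(seed)
    flip_h = rng.uniform() < spec.flip_prob
    flip_v = rng.uniform() < spec.flip_prob
    angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
    zoom = rng.uniform(*spec.zoom_range)
    brightness = rng.uniform(1 - spec.brightness_delta, 1 + spec.brightness_delta)
    contrast = rng.uniform(*spec.contrast_range)

    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if flip_v:
        img, msk = img[::-1, :], msk[::-1, :]
    if angle != 0.0 or zoom != 1.0:
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        matrix = rot / zoom
        center = (np.array(img.shape) - 1) / 2.0
        offset = center - matrix @ center
        img = ndimage.affine_transform(img, matrix, offset=offset, order=1, mode="nearest")
        msk = ndimage.affine_transform(
            msk.astype(np.float64), matrix, offset=offset, order=0, mode="constant"
        )
    if brightness != 1.0:
        img = img * brightness
    if contrast != 1.0:
        m = img.mean()
        img = m + (img - m) * contrast
    if brightness != 1.0 or contrast != 1.0:
        img = np.clip(img, 0.0, 1.0)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk > 0.5 if msk.dtype != bool else msk)


# ---------------------------------------------------------------------------
# early stopping

class EarlyStopper:
    """Stop when the best validation score has not improved for ``patience``
    consecutive epochs ("plateauing" = no strict improvement beyond
    ``min_delta``)."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, score: float) -> bool:
        """Record one epoch's score; returns True when training should stop."""
        if score > self.best + self.min_delta:
            self.best = score
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def early_stop_epoch(
    val_history: list[float], patience: int, min_delta: float = 0.0
) -> tuple[int, int]:
    """(stop_epoch, best_epoch), 1-based, for a given validation history."""
    stopper = EarlyStopper(patience, min_delta)
    for e, v in enumerate(val_history, start=1):
        if stopper.update(e, v):
            return e, stopper.best_epoch
    return len(val_history), stopper.best_epoch


# ---------------------------------------------------------------------------
# training

def _normalize_slice(img_hu: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(img_hu, dtype=np.float64) + 200.0) / 600.0, 0.0, 1.0)


def _val_dsc(model: U2Net, val_cases) -> float:
    scores = []
    for case in val_cases:
        vol = normalize_window(case.volume)
        pred = predict_mask(model, vol)
        scores.append(dice(pred, case.gt_vessels))
    return float(np.mean(scores))


def train_one(
    model: U2Net,
    train_slices: list[dict],
    val_cases,
    cfg: TrainConfig,
) -> tuple[U2Net, pd.DataFrame]:
    """Train with Adam + deep supervision; return best-epoch weights.

    ``train_slices`` are ``{"case_id", "image" (HU), "mask"}`` dicts;
    ``val_cases`` expose ``.volume`` (HU) and ``.gt_vessels``.  Training and
    validation case sets must be disjoint (the caller's fold assignment
    guarantees it; we re-check).  The returned history has one row per
    epoch: epoch, train_loss, val_dsc.
    """
    if not val_cases:
        raise ValueError("validation set is empty; early stopping undefined")
    train_ids = {s["case_id"] for s in train_slices}
    val_ids = {c.case_id for c in val_cases}
    leaked = train_ids & val_ids
    if leaked:
        raise ValueError(f"case leakage between train and validation: {sorted(leaked)}")

    images = [_normalize_slice(s["image"]) for s in train_slices]
    masks = [np.asarray(s["mask"], dtype=bool) for s in train_slices]
    params = model.parameters()
    opt = ag.Adam(params, lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience_epochs, cfg.min_delta)
    rng = np.random.default_rng(cfg.seed)
    best_state = model.state_dict()
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        model.set_training(True)
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_img, batch_msk = [], []
            for j in idx:
                aug_seed = int(rng.integers(0, 2**31 - 1))
                im, mk = augment_pair(images[j], masks[j], cfg.augmentation, aug_seed)
                batch_img.append(im)
                batch_msk.append(mk)
            x = np.stack(batch_img)[:, None].astype(np.float32)
            t = np.stack(batch_msk)[:, None].astype(np.float32)
            fused, sides = model.forward_tensors(x)
            loss = ag.bce_with_logits_mean(fused, t)
            for s in sides:
                loss = loss + ag.bce_with_logits_mean(s, t)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        vdsc = _val_dsc(model, val_cases)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dsc": vdsc})
        improved = vdsc > stopper.best + stopper.min_delta
        stop = stopper.update(epoch, vdsc)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = stopper.best_epoch
    history.attrs["best_val_dsc"] = float(stopper.best)
    return model, history


# ---------------------------------------------------------------------------
# grid search

@dataclass
class CVReport:
    """Grid-search outcome: per-(cell, fold) best validation DSC, the
    winning cell, the selected fold, and full training histories."""

    table: pd.DataFrame  # columns: lr, batch_size, fold, best_val_dsc, n_epochs
    winning_cell: tuple[float, int]
    winning_mean_dsc: float
    selected_fold: int
    histories: dict = field(default_factory=dict)


def grid_search_cv(
    cases,
    model_cfg: ModelConfig,
    base_cfg: TrainConfig,
    grid=DEFAULT_GRID,
    labels=None,
) -> tuple[U2Net, CVReport]:
    """Cross-validated grid search; returns the final model and the report.

    The winning cell has the highest mean best-validation-DSC over folds
    (ties: smaller learning rate, then smaller batch size); the final model
    is the winning cell's highest-DSC fold, with that fold's best-epoch
    weights.  Cells where any fold fails to train are excluded with a
    warning.
    """
    from .phantom_forge import slice_dataset
    from .quantify import classify

    if not grid:
        raise ValueError("grid must be non-empty")
    cases = list(cases)
    if labels is None:
        labels = [classify(100.0 * c.realized_ratio).quaternary for c in cases]
    folds = make_folds([c.case_id for c in cases], labels, base_cfg.n_folds, base_cfg.seed)
    rows, histories, models = [], {}, {}
    for lr, bs in grid:
        cfg = replace(base_cfg, learning_rate=lr, batch_size=bs)
        failed = False
        for fold in range(base_cfg.n_folds):
            train_cases = [c for c in cases if folds[c.case_id] != fold]
            val_cases = [c for c in cases if folds[c.case_id] == fold]
            if not train_cases or not val_cases:
                warnings.warn(f"fold {fold} empty; cell (lr={lr}, bs={bs}) excluded", stacklevel=2)
                failed = True
                break
            try:
                model = build_model(model_cfg, seed=base_cfg.seed + fold)
                model, hist = train_one(model, slice_dataset(train_cases), val_cases, cfg)
            except Exception as e:  # noqa: BLE001 - cell-level containment is the contract
                warnings.warn(
                    f"cell (lr={lr}, bs={bs}) fold {fold} failed: {e}", stacklevel=2
                )
                failed = True
                break
            best = float(hist.attrs["best_val_dsc"])
            rows.append(
                {"lr": lr, "batch_size": bs, "fold": fold, "best_val_dsc": best,
                 "n_epochs": len(hist), "failed": False}
            )
            histories[(lr, bs, fold)] = hist
            models[(lr, bs, fold)] = model.state_dict()
        if failed:
            rows = [r for r in rows if not (r["lr"] == lr and r["batch_size"] == bs)]
            rows.append({"lr": lr, "batch_size": bs, "fold": -1, "best_val_dsc": np.nan,
                         "n_epochs": 0, "failed": True})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("every grid cell failed to train")
    means = ok.groupby(["lr", "batch_size"])["best_val_dsc"].mean()
    best_mean = means.max()
    tied = sorted(
        [cell for cell, m in means.items() if m == best_mean],
        key=lambda c: (c[0], c[1]),
    )
    win_lr, win_bs = tied[0]
    cell_rows = ok[(ok["lr"] == win_lr) & (ok["batch_size"] == win_bs)]
    sel = cell_rows.sort_values(["best_val_dsc", "fold"], ascending=[False, True]).iloc[0]
    selected_fold = int(sel["fold"])
    final = build_model(model_cfg, seed=base_cfg.seed + selected_fold)
    final.load_state_dict(models[(win_lr, win_bs, selected_fold)])
    report = CVReport(
        table=table,
        winning_cell=(float(win_lr), int(win_bs)),
        winning_mean_dsc=float(best_mean),
        selected_fold=selected_fold,
        histories=histories,
    )
    return final, report
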