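"""End-to-end workflow: generate → preprocess → train → segment → quantify
→ evaluate, with one config object, seeded determinism, and file outputs.

Every stage is a pure function of (inputs, config, seed) in deterministic
mode, so re-running a config reproduces byte-identical result tables.  The
per-case output CSV carries the quantification of each held-out case from
*predicted* masks next to its ground-truth value; the aggregate metrics
report compares predicted and ground-truth scores and grades with the full
agreement-statistics suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement_stats as stats
from .grids import VolumeGrid, load_mask, load_volume
from .phantom_forge import PhantomCase, PhantomSpec, generate_cohort, slice_dataset
from .preproc import align_midline, normalize_window
from .quantify import DegenerateCaseError, GradeThresholds, classify, quantify_case
from .train_harness import AugmentSpec, TrainConfig, grid_search_cv
from .u2net_core import ModelConfig, U2Net, build_model, predict_mask

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_cohort"]

log = logging.getLogger("collascore")


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    out_dir: str = "collascore_run"
    n_cases: int = 12
    n_test: int = 4
    seed: int = 0
    align: bool = False
    prob_threshold: float = 0.5
    log_level: str = "INFO"
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(grid_shape=(48, 48, 24)))
    model: ModelConfig = field(default_factory=ModelConfig.scaled)
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=1e-2, batch_size=8, max_epochs=15, patience_epochs=5, n_folds=2
        )
    )
    grid: tuple[tuple[float, int], ...] = ((1e-2, 8),)
    thresholds: GradeThresholds = field(default_factory=GradeThresholds)

    def __post_init__(self) -> None:
        if self.n_test >= self.n_cases:
            raise ValueError("n_test must be < n_cases")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = self.model.to_dict()
        d["grid"] = [list(g) for g in self.grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            p = dict(d["phantom"])
            for k in ("grid_shape", "spacing_mm", "radius_range_mm", "vessel_hu_range"):
                if k in p:
                    p[k] = tuple(p[k])
            d["phantom"] = PhantomSpec(**p)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "augmentation" in t and isinstance(t["augmentation"], dict):
                a = dict(t["augmentation"])
                for k in ("contrast_range", "zoom_range"):
                    if k in a:
                        a[k] = tuple(a[k])
                t["augmentation"] = AugmentSpec(**a)
            d["train"] = TrainConfig(**t)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            t = dict(d["thresholds"])
            if "six_class_cuts" in t:
                t["six_class_cuts"] = tuple(t["six_class_cuts"])
            d["thresholds"] = GradeThresholds(**t)
        if "grid" in d:
            d["grid"] = tuple((float(lr), int(bs)) for lr, bs in d["grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _split_cases(cases: list[PhantomCase], n_test: int) -> tuple[list, list]:
    """Deterministic stratified-ish holdout: every 'stride'-th case goes to
    test until n_test is reached (cohort generation cycles grade strata, so
    a stride sample covers them)."""
    n = len(cases)
    stride = max(n // n_test, 1)
    test_idx = set()
    i = stride - 1
    while len(test_idx) < n_test:
        test_idx.add(i % n)
        i += stride
    test = [c for j, c in enumerate(cases) if j in test_idx]
    train = [c for j, c in enumerate(cases) if j not in test_idx]
    return train, test


def evaluate_cohort(results: pd.DataFrame, thresholds: GradeThresholds) -> stats.MetricsReport:
    """Aggregate agreement between predicted and ground-truth collateral
    scores over a cohort results table (columns qcs_percent, qcs_gt,
    dsc_vs_gt)."""
    n = len(results)
    gt_grades = [classify(q, thresholds) for q in results["qcs_gt"]]
    pr_grades = [classify(q, thresholds) for q in results["qcs_percent"]]
    gt_bin = [g.binary for g in gt_grades]
    pr_bin = [g.binary for g in pr_grades]
    report = stats.MetricsReport(n=n)
    report.dsc_mean = float(results["dsc_vs_gt"].mean())
    quat_cm = stats.confusion(
        [g.quaternary for g in gt_grades], [g.quaternary for g in pr_grades], (0, 1, 2, 3)
    )
    report.notes["quaternary_accuracy"] = stats.multiclass_accuracy(quat_cm)
    report.notes["quaternary_confusion"] = quat_cm.counts.tolist()
    bin_cm = stats.confusion(gt_bin, pr_bin, ("poor", "good"))
    bm = stats.binary_metrics(bin_cm, positive_index=1)
    report.accuracy = bm["accuracy"]
    report.f1 = bm["f1"]
    report.sensitivity = bm["sensitivity"]
    report.specificity = bm["specificity"]
    report.mcc = bm["mcc"]
    y = [1 if b == "good" else 0 for b in gt_bin]
    if 0 < sum(y) < n:
        report.auc = stats.roc_auc(results["qcs_percent"].tolist(), y)
    if n >= 3:
        report.spearman_rho = stats.spearman(
            results["qcs_percent"].tolist(), results["qcs_gt"].tolist()
        )
    if n >= 2:
        ratings = np.column_stack([results["qcs_gt"], results["qcs_percent"]])
        report.icc = stats.icc_2_1(ratings)
    return report


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the selected stages (default: all); returns paths and summaries.

    Stage order: generate, preprocess, train, segment, quantify, evaluate.
    Later stages read earlier stages' in-memory outputs; all artifacts are
    also written under ``cfg.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stages = stages or ("generate", "preprocess", "train", "segment", "quantify", "evaluate")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    summary: dict = {"out_dir": str(out)}

    log.info("generate: %d phantoms, seed %d", cfg.n_cases, cfg.seed)
    cases, manifest = generate_cohort(
        cfg.n_cases, cfg.phantom, cfg.seed, out_dir=out / "data"
    )
    summary["manifest"] = str(out / "data" / "manifest.csv")

    if "preprocess" in stages and cfg.align:
        for case in cases:
            aligned, tfm = align_midline(case.volume)
            case.volume = aligned

    train_cases, test_cases = _split_cases(cases, cfg.n_test)
    summary["train_cases"] = [c.case_id for c in train_cases]
    summary["test_cases"] = [c.case_id for c in test_cases]

    model: U2Net | None = None
    model_path = out / "model.npz"
    if "train" in stages:
        log.info("train: %d cases, grid %s, seed %d", len(train_cases), cfg.grid, cfg.seed)
        model, report = grid_search_cv(train_cases, cfg.model, cfg.train, grid=cfg.grid)
        model.save(model_path)
        report.table.to_csv(out / "cv_report.csv", index=False)
        for key, hist in report.histories.items():
            lr, bs, fold = key
            hist.to_csv(out / f"history_lr{lr}_bs{bs}_fold{fold}.csv", index=False)
        summary["winning_cell"] = report.winning_cell
        summary["selected_fold"] = report.selected_fold
        summary["winning_mean_dsc"] = report.winning_mean_dsc
    elif model_path.exists():
        model = U2Net.load(model_path)

    rows = []
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    use_gt = "segment" not in stages or model is None
    for case in test_cases:
        if use_gt:
            pred = case.gt_vessels
        else:
            vol = normalize_window(case.volume)
            pred = predict_mask(model, vol, cfg.prob_threshold)
            pred.save(pred_dir / f"{case.case_id}_pred.nii.gz")
        terr_aff = case.territory_left if case.spec.affected_side == "left" else case.territory_right
        terr_heal = case.territory_right if case.spec.affected_side == "left" else case.territory_left
        try:
            q = quantify_case(
                pred, terr_aff, terr_heal, case.spec.affected_side,
                cfg.thresholds, territory_source="explicit", case_id=case.case_id,
            )
        except DegenerateCaseError:
            raise
        q["qcs_gt"] = 100.0 * case.realized_ratio
        q["dsc_vs_gt"] = stats.dice(pred, case.gt_vessels)
        q["thresholds"] = list(q["thresholds"])
        rows.append(q)
    results = pd.DataFrame(rows)
    results.to_csv(out / "results.csv", index=False)
    summary["results"] = str(out / "results.csv")

    if "evaluate" in stages and len(results) >= 2:
        report = evaluate_cohort(results, cfg.thresholds)
        (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
        summary["metrics"] = report.to_dict()
    return summary
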