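# collascore

Automated quantification of cerebral collateral circulation from CTA-like
volumes.

In acute ischemic stroke, the quality of leptomeningeal collateral
circulation — the secondary vascular routes that keep tissue alive distal to
an occlusion — is a key factor in treatment decisions. Visual collateral
scores (Tan, Menon, rLMC) are rated by radiologists on CTA and suffer
substantial inter-observer variability. `collascore` implements an
automated alternative: segment the arterial vasculature, compare the two
hemispheres volumetrically, and grade the result on fixed cut points.

## The score

Given a binary vessel segmentation and a middle-cerebral-artery (MCA)
territory mask per hemisphere, the quantitative collateral score is

```
qCS(%) = 100 · V_affected / V_healthy ,   qCS ≥ 0
```

where `V_affected` and `V_healthy` are the vessel volumes (mm³) inside the
stroke-side and contralateral territories, and the affected side is a
clinical input. The score maps onto three grading schemes sharing cut
points at 5, 49 and 95% (all interval upper ends closed):

| scheme     | classes | cuts (%)          |
|------------|---------|-------------------|
| binary     | poor / good | 49            |
| quaternary | 0–3     | 5, 49, 95         |
| six-class  | 0–5     | 5, 25, 49, 75, 95 |

Segmentation uses a two-level nested U-shaped network: each stage of the
outer encoder–decoder is a residual U-block, with deep supervision on every
stage's side output and a fused output driving inference. The network is
implemented in pure NumPy (including reverse-mode autodiff) and is fully
size-configurable; a small 4-stage / 8-channel preset trains in minutes on
one CPU. A seeded phantom generator produces CTA-like head volumes with
paired-hemisphere vascular trees whose affected/healthy volume ratio is
controlled exactly, so every stage of the pipeline is testable end to end
without clinical data.

The package also ships the complete evaluation suite used for collateral
agreement studies: Dice, confusion-matrix metrics (accuracy, F1,
sensitivity, specificity, MCC), rank-based ROC-AUC with confidence
interval, Spearman rank correlation, and ICC(2,1) absolute agreement with
F-based confidence intervals.

## Worked example

```python
import collascore as cs

spec = cs.PhantomSpec(grid_shape=(48, 48, 24), seed=7, true_ratio=0.5)
case = cs.generate_phantom(spec)
result = cs.quantify_case(
    case.gt_vessels, case.territory_left, case.territory_right,
    affected_side="left", case_id=case.case_id,
)
print(result)
```

prints (reformatted):

```json
{
  "case_id": "phantom_seed7",
  "v_affected_mm3": 126.5625,
  "v_healthy_mm3": 253.125,
  "qcs_percent": 50.0,
  "affected_side": "left",
  "binary": "good",
  "quaternary": 2,
  "six_class": 3,
  "territory_source": "explicit",
  "thresholds": [5.0, 49.0, 95.0]
}
```

The phantom was asked for an affected/healthy volume ratio of 0.5 and
realizes it exactly (126.5625 / 253.125 mm³), so the score is 50.0%: above
the 49% binary cut (good collaterals, just), quaternary grade 2, six-class
grade 3.

The same operations are available from the shell:

```
collascore generate --n 12 --out cohort/ --seed 1
collascore run --out run/ --seed 1          # full pipeline on phantoms
collascore quantify --mask m.nii.gz --territory-left l.nii.gz \
    --territory-right r.nii.gz --affected left --out qcs.json
```

`collascore run` generates a phantom cohort, trains the scaled network on
the training split, segments the held-out cases, quantifies them, and
writes `results.csv` (per-case volumes, qCS, grades, Dice against ground
truth) plus `metrics.json` (aggregate agreement statistics). Runs are
deterministic: the same config and seed reproduce byte-identical outputs.

## Layout

- `src/collascore/phantom_forge.py` — synthetic cohort generator
- `src/collascore/preproc.py` — HU windowing, midline alignment, hemisphere split
- `src/collascore/u2net_core.py` — nested-U segmentation network
- `src/collascore/_autograd.py` — minimal NumPy reverse-mode autodiff
- `src/collascore/train_harness.py` — folds, augmentation, early stopping, grid search
- `src/collascore/quantify.py` — qCS, grading, threshold sweep
- `src/collascore/agreement_stats.py` — evaluation statistics
- `src/collascore/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — models, parameters, design decisions, limitations
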