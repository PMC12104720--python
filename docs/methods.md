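# Methods

## Problem and model

The pipeline quantifies cerebral collateral circulation on CTA by comparing
vascular volume between hemispheres. Its stages: (1) intensity
normalization to the vascular display window; (2) optional rigid
midline alignment; (3) slice-wise binary vessel segmentation with a nested
residual-U network; (4) per-territory vessel volumes and the quantitative
collateral score qCS(%) = 100·V_affected/V_healthy, with the affected side
supplied clinically; (5) threshold-based grading; (6) agreement statistics.

The score is a ratio, so it is insensitive to global over- or
under-segmentation as long as both hemispheres are affected alike — which
is why a modestly sized network already yields accurate scores on phantoms
even when its voxel-level Dice is imperfect. qCS has no upper bound
(affected vasculature can exceed the healthy side's); the only hard
constraint is qCS ≥ 0, and a zero healthy-hemisphere volume is an explicit
degenerate-case error, never infinity or a silent zero.

## Synthetic phantoms

`phantom_forge` stands in for a clinical cohort. Each phantom is a 3D grid
(default 64×64×32 voxels at 0.5×0.5×0.625 mm; tests and the scaled pipeline
use 48×48×24) containing:

- **Territories** — mirror-symmetric half-ellipsoids (semi-axes 45% of each
  extent) split at the midsagittal plane; sagittal index increases toward
  the patient's left (radiological convention).
- **Healthy tree** — random branching tubes: seeded random-walk centerlines
  with direction persistence (per-step turn SD = `tortuosity`, default
  0.35), radii tapering linearly within 0.6–1.8 mm, rasterized as spheres
  and clipped to the territory. Default 6 branches of 20–45 steps.
- **Affected tree** — the healthy tree mirrored about the midsagittal
  plane, its radii rescaled by bisection and then trimmed voxel-by-voxel
  from the surface inward (distance-transform order, deterministic
  tie-break) until the affected/healthy voxel count equals the target
  ratio to within one voxel. `true_ratio = 1` short-circuits to the exact
  mirror, so the realized ratio is exactly 1; `true_ratio = 0` yields an
  empty affected tree. Because voxel sets grow monotonically with the
  radius scale, bisection is well-posed and the realized ratio is monotone
  in the target.
- **Intensities** — vessels uniform in 150–450 HU over a Gaussian
  parenchyma background (mean 35 HU, SD 10 HU). These straddle the
  annotation display window (level 100, width 600 HU) and satisfy
  mean(vessel) ≥ background + 3·SD, so vessels are separable by contrast.

All randomness flows from explicit integer seeds (per-case seeds derived
from a master seed by hashing), and generation is bit-reproducible.

What the phantoms do **not** emulate: skull and bone, venous structures,
contrast-bolus timing, anatomically realistic Circle-of-Willis topology,
pathological vessel texture, or partial-volume effects at real scanner
resolution. Consequently, passing tests demonstrate the correctness of the
quantification machinery and the trainability of the network on
high-contrast tubular foreground — not clinical segmentation performance.

## Preprocessing

- **Windowing** — linear map of [−200, 400] HU (level 100, width 600) onto
  [0, 1], clipped. This is the window under which vascular annotation is
  performed, so training targets and inputs share it.
- **Midline alignment** — rigid, template-free: maximize the Pearson
  correlation between the volume and its sagittal mirror image. Only three
  rigid parameters break mirror symmetry (sagittal translation and the two
  midplane tilts); the complementary three (in-plane translations, rotation
  about the sagittal axis) commute with the mirror, are unidentifiable from
  this objective, and are pinned to zero. The search is a coarse integer
  pre-scan of the sagittal translation followed by bounded Powell
  refinement (±8 voxels, ±0.2 rad); images are resampled trilinearly,
  masks nearest-neighbour. If nothing beats the identity, the identity is
  returned with a warning.
- **Hemisphere split** — voxels strictly below the midline plane are right,
  strictly above are left. An integer midline equal to half an even extent
  denotes the sheet boundary (clean split); with an odd extent it names the
  midplane sheet, which belongs to neither hemisphere.

## Segmentation network

A two-level nested U: the outer encoder–decoder's stages are residual
U-blocks (RSU). An RSU of depth L applies an input convolution (the
residual source), an internal encoder with L−1 conv–BN–ReLU units and L−2
poolings, a dilated bottom convolution, and a symmetric decoder; its output
is input-conv + decoder-output. The deepest stage(s) use a pooling-free
variant whose dilation doubles with depth (two such stages when there are
≥ 5 stages, one otherwise). Each decoder stage and the deepest encoder
stage emit a 1-channel side logit, upsampled (nearest-neighbour) to input
size; a 1×1 convolution over the concatenated side logits produces the
fused map. All channel widths and depths live in `ModelConfig`:

- full preset: 6 stages, RSU depths (7,6,5,4,4,4), base 64 channels;
- scaled preset: 4 stages, depths (4,3,2,2), base 8 channels
  (~116k parameters) — trains on one CPU in minutes.

The implementation is pure NumPy with an in-repo reverse-mode autodiff
(`_autograd.py`): im2col convolutions, batch normalization, 2×2 max
pooling, nearest upsampling, and a numerically stable logit-space binary
cross-entropy. Float32 throughout; single-threaded deterministic execution,
so identical seeds give bit-identical training runs.

Training loss is the sum over all maps (sides + fused) of per-pixel-mean
BCE with equal weights. Inference is 2D axial slice-wise (annotation and
training units are axial slices); slices indivisible by the config's
power-of-two are reflect-padded and cropped back. A voxel is vessel iff
fused probability > 0.5 (strict; the threshold is exposed).

Numerical notes: He-normal initialization from the model seed; max-pool
gradients split equally among tied maxima; BN uses batch statistics in
training and running statistics (momentum 0.1) at inference.

## Development protocol

- **Folds** — case-level, stratified by collateral grade: within each
  stratum cases are shuffled (seeded) and dealt round-robin starting at the
  running global offset, keeping per-fold stratum counts within one of the
  global proportions and fold sizes within one of each other. Strata
  smaller than the fold count are distributed round-robin with a warning.
  Slices inherit their case's fold; no case ever straddles train and
  validation.
- **Augmentation** — horizontal/vertical flips (p = 0.5 each),
  rotation ±10°, zoom 0.9–1.1 (shared geometry, bilinear for images,
  nearest for masks), then multiplicative brightness ±20% and contrast
  scaling about the slice mean 0.8–1.2 (image only, re-clipped to [0, 1]).
  Brightness-as-multiplicative and contrast-about-the-mean are this
  package's operator choices; both are configurable. When all drawn
  parameters equal the identity the input passes through bit-exact.
- **Early stopping** — "plateauing" is read as no strict improvement of the
  best validation DSC for `patience` (default 20) consecutive epochs, with
  an optional minimum delta (default 0). The returned weights are from the
  best epoch, never the last. Validation DSC is volume-wise: each
  validation case is segmented as a volume, and the per-case Dice values
  are averaged (slice-wise averaging would overweight vessel-free slices).
- **Grid search** — default grid: learning rates {1e-3, 1e-4, 1e-5} ×
  batch sizes {8, 16, 32}, Adam, up to 500 epochs. The winning cell has the
  highest mean best-validation DSC across folds; ties break to the smaller
  learning rate, then the smaller batch. The final model is the winning
  cell's highest-DSC fold (that fold's best-epoch weights) rather than a
  retrain on all data; the full per-cell/per-fold table and histories are
  persisted so the selection is recomputable.

The scaled pipeline preset departs from the full protocol in size only:
12-case cohorts at 48×48×24, a one-cell grid at learning rate 1e-2 with
batch 8, 15 epochs with patience 5, and 2 folds. The larger learning rate
reflects the much smaller parameterization of the scaled network, whose
loss landscape tolerates (and needs) bigger steps than the full-size
configuration.

## Quantification and thresholds

Territory volume is a voxel count times the voxel volume — no smoothing or
partial-volume weighting — so quantifying a phantom's ground-truth mask
reproduces 100×realized_ratio to machine precision (this is asserted over
cohorts in the tests). Explicit MCA-territory masks take precedence; if
unavailable, the hemisphere partition serves as fallback and the choice is
recorded in the output.

Grading boundaries are closed above exactly as printed (qCS = 49.0 is
poor); the three schemes are mutually consistent at the shared 49% cut by
construction, and grading is monotone in qCS.

The threshold-refinement sweep scans each nominal boundary ±5 percentage
points in 1-point steps (clipped at 0 below; candidates above 100 are
allowed since qCS can exceed 100), dichotomizes cases at each candidate
(strict >), and scores accuracy, sensitivity and specificity against the
reference dichotomy. The published procedure evaluates all three without
stating how they combine; this implementation ranks by accuracy, breaks
ties by sensitivity+specificity (Youden-style), then proximity to the
nominal value, then the smaller candidate — and always emits the full
candidate table so a user can re-decide. Boundaries with a single-class
reference are skipped with a warning.

## Agreement statistics

Implementations are definitional; each is verified in the tests against an
independent brute-force oracle (pair enumeration for AUC, explicit ANOVA
sums for ICC, formula evaluation for MCC/F1) and cross-checked against
scikit-learn (MCC, F1, AUC) and pingouin (ICC) where those overlap.

- **Dice** — 2|A∩B|/(|A|+|B|); two empty masks are defined as 1.0
  (agreement on absence), a convention flagged because it differs between
  packages.
- **Binary metrics** — from a 2×2 confusion matrix with "good collateral"
  as the positive class. Zero-denominator metrics are reported as explicit
  nulls with reasons, never coerced to 0.
- **AUC** — rank-based (Mann–Whitney), ties contributing ½, using the
  continuous qCS as the score against the binary reference; 95% CI by the
  Hanley–McNeil normal approximation, clipped to [0, 1].
- **Spearman** — mid-rank correlation via scipy; zero rank variance is an
  explicit undefined flag.
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure: (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) from the ANOVA
  mean squares; 95% CI by the F-distribution method with a Satterthwaite
  denominator df. A constant ratings matrix is flagged undefined.

## Known limitations

- Phantom realism is deliberately minimal (see above); reported Dice and
  accuracy on phantoms do not transfer to clinical CTA.
- The nested-U implementation is CPU-oriented NumPy; the full-size preset
  is provided for completeness but is not practical to train here.
- Midline alignment assumes approximate head symmetry; gross pathology
  breaking that symmetry would bias the recovered midplane.
- MCA-territory delimitation is taken from supplied masks (or the
  hemisphere fallback); no vascular-territory atlas is included.
- Affected-side detection is out of scope by design: it is a clinical
  input.
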