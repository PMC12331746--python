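# Methods

## Problem and scope

`iecad` implements a multi-task framework for resting transthoracic
echocardiographic video: from a 20-frame clip of one cardiac cycle in each
of the three standard apical views (A4C, A3C, A2C) it classifies the view,
segments the left myocardium and left-ventricular cavity, regresses the
per-frame global longitudinal strain (GLS) and ejection-fraction (LVEF)
curves, the global work efficiency (GWE), and the Gensini coronary-severity
score, and classifies significant coronary artery disease (CAD).  Because
no clinical videos ship with the package, a synthetic beating-heart
generator reproduces the statistical structure such a model learns from,
and all validation runs against its analytically known labels.

## Clinical definitions

* **Significant CAD** — any left-main stenosis >= 50% or any other
  coronary stenosis >= 70%.
* **Gensini score** — per lesion, severity points from the stenosis bin
  (<=25% -> 1, <=50% -> 2, <=75% -> 4, <=90% -> 8, <=99% -> 16,
  100% -> 32; right-closed) times a segment multiplier (left main x5,
  proximal LAD and proximal LCx x2.5, mid LAD x1.5, second diagonal and
  posterolateral branch x0.5, all remaining segments x1), summed over
  lesions.  The point and multiplier tables follow the classic Gensini
  system and are overridable through `GensiniConfig`.  A collateralised
  total or near-total (>=99%) occlusion is demoted to the 90% bin; this
  "collateral adjustment" has no universally standard form, so it is an
  explicit, documented default that can be switched off.
* **Severe CAD** — Gensini score >= 15 points.
* **Detection assignments** — 1: significant; 2: severe; 3: significant
  XOR severe; 4: significant AND severe.  The continuous score behind each
  ROC curve is: max per-view significant-class probability (1), the final
  max-over-views Gensini score (2), and the max/min of those two
  constituents for 3/4, with the severity score passed through a logistic
  centred at the 15-point cutoff so both constituents live on [0, 1].
  The choice of continuous statistic is a design decision of this package.

## Preprocessing

A raw cycle with annotated end-diastole (ED) and end-systole (ES) indices
is resampled to 10 frames uniformly spanning the half-open phase interval
[ED, ES) and 10 spanning [ES, next ED), each phase mapped to the nearest
source frame from below (no temporal blending, preserving speckle
statistics).  Frames are resized isotropically and zero-padded to a square
raster (256 x 256 by default), intensities rescaled to [0, 1] only when
they fall outside it, and pixels outside the transducer sector polygon are
zeroed.  Masks follow the identical frame-index list with
nearest-neighbour spatial resizing.  Half-open sampling yields 20 unique
phases without duplicating ES; frame 0 is ED and frame 10 is ES everywhere
in the package (systole for work computations is frames 0–10).

## Network

A 3-D DeepLabV3+-style encoder on a 3D-ResNet50 trunk processes the
(1, 20, S, S) clip with *spatial-only* strides so the 20-frame axis
survives every stage (output stride 16).  The stem is a 3x7x7 stride-(1,2,2)
convolution; the four bottleneck stages have 3/4/6/3 blocks with 3x3x3
middle convolutions, the last stage dilated instead of strided.  An atrous
spatial pyramid (1x1 branch, three dilated 3x3x3 branches, image pooling)
projects to 256 channels at 20 x 16 x 16.  The pyramid's dilation rates
default to (6, 12, 18) at the 256-px raster and scale linearly with the
raster so receptive fields stay proportional to the feature map in
reduced-scale runs.

Decoders (reference widths; all scale with the `width` multiplier):

* **View**: low-level features (48 ch after pointwise reduction of the
  first-stage output, downsampled 64 -> 16) globally pooled, FC 48 -> 3,
  softmax.
* **Segmentation**: backbone features upsampled to 64 x 64, concatenated
  with the pre-downsampling low-level features (256 + 48 = 304 ch),
  3x3x3 conv to 256, pointwise to 3 classes, upsampled to 256 x 256,
  voxel softmax.
* **GLS / LVEF**: backbone plus the task's low-rank sparse features,
  spatially pooled to a 20 x 256 sequence, bidirectional LSTM (256 per
  direction), per-step FC 512 -> 1.
* **GWE**: backbone + sparse features globally pooled, FC 256 -> 1.
* **Gensini / CAD**: a 1,072-channel fusion — (backbone + Gensini-sparse)
  ++ GLS-sparse ++ LVEF-sparse ++ GWE-sparse ++ low-level
  (4 x 256 + 48) — through 3x3x3 conv to 512, 8-head temporal
  self-attention at width 512 over the pooled 20-token sequence, temporal
  mean, then 512 -> 256 -> 1 (GELU; score) and 512 -> 256 -> 2 + softmax
  (ReLU; CAD).  Adding the Gensini-sparse features element-wise into the
  backbone slot keeps the fused width at 1,072.

Task-sparse features come from low-rank convolution blocks: the 3x3x3
stage is factorised through a rank-4 channel bottleneck (full-kernel conv
to r channels, pointwise r -> 256), followed by a rank-4 1x1x1 stage, each
with batch normalisation and rectification — sparse complementary features
for multi-task fusion at ~1/60 of the dense parameter count.

Regression heads emit scaled units — strain/EF/GWE as fractions and the
Gensini score per 100 points — and predictions are converted back to
clinical units at the output.  This keeps every task loss O(1) without
per-task loss weights (which default to 1).

### Numerical engine

The model runs on a compact reverse-mode autodiff engine over NumPy
(`iecad.nn`): float32 tensors, a recorded operation graph, and the
operations the architecture needs.  Convolutions lower to either a single
im2col matmul (with numba-compiled gather/scatter kernels; small problems)
or a kernel-offset loop of BLAS matmuls (large problems, bounding memory
at one padded input copy).  Batch normalisation is a fused primitive with
the closed-form backward.  Every primitive's gradient is verified against
central finite differences (in float64) in the test suite.  Interior
gradients are freed during the backward sweep so memory is reused within a
pass.

## Training

Three sequential phases with per-phase optimizers:

1. view (cross-entropy) + segmentation (cross-entropy + Dice loss, where
   Dice loss = 1 − mean over classes of 2Σpq/(Σp²+Σq²+ε) on softmax
   probabilities), 30 epochs;
2. GLS/LVEF/GWE mean-squared-error regression, 30 epochs (the encoder
   remains trainable);
3. Gensini MSE + CAD cross-entropy, 90 epochs, with the encoder, the conv
   block, and all phase-1/2 heads frozen *exactly*: their parameters are
   excluded from the optimizer and their normalisation layers held in
   evaluation mode, so neither weights nor running statistics move; the
   frozen trunk additionally runs gradient-free.

Adam (lr 2e-4, weight decay 1e-5), batch 16 with parameter updates after
every 3 gradient accumulations (accumulated losses are mean-scaled so the
update equals the large-batch gradient), and a cosine-annealed learning
rate re-warmed at each phase start (linear warmup over the first 5% of the
phase — the warmup length is this package's choice).  No early stopping:
the last epoch is canonical.  All randomness is seeded; identical seeds
give identical runs on CPU.  A config flag (`joint_losses`) optionally
keeps earlier phases' losses active in later phases; the default is
phase-exclusive.

Cohorts are split at the subject level (never the clip level), stratified
on the (significant, severe) label pair; each stratum contributes
floor(stratum x 0.2) subjects to the test side and the proportions are
screened with a chi-squared test (p > 0.1) with a bounded number of
redraws.

## Inference

The three views of a study are tested separately in evaluation mode.  The
final Gensini score is the maximum over views, the study is significant if
any view is, and severe iff the final score reaches 15 points —
aggregation chosen for sensitivity, since regional wall-motion signatures
may be visible in only one plane.

## Synthetic cohort generator

One subject is an elliptical LV cavity (semi-axes a0 ~ U(70, 90),
b0 ~ U(42, 55) px on the 256-px raster) inside a myocardial annulus
(thickness h0 ~ U(11, 15) px), contracting radially by a fraction
alpha ~ U(0.18, 0.30) scaled by the local territory contractility, over
the triangular 20-frame phase (ED at 0, ES at 10).  The three views are
distinct in-plane rotations (0/-22/+22 degrees plus per-subject jitter)
with view-specific territory weightings (A4C cuts LAD/LCx walls, A2C
LAD/RCA, A3C LAD against a posterior LCx+RCA blend).  The view identity is
carried by the same cues that distinguish real apical windows:
view-specific neighbouring anatomy rendered into the video only (A4C a
contracting right-ventricular crescent on the septal side, A3C the aortic
outflow right of the base, A2C the left atrium left of the base), a
per-view acquisition gain (0.86/1.0/1.14), and a per-view transducer
sector width (half-angles 38/32/46 degrees) — the latter two mimic the
different probe and depth settings of each window and make the view
signal robust to heart-size variation.  Frames carry a smooth tissue
template multiplied by spatially correlated Rayleigh speckle and are
cropped to the sector; masks are rasterised from the same geometry and
are pixel-exact.

Coronary lesions couple to motion through their territory: the summed
territory Gensini contribution G lowers contractility as
c = 0.3 + 0.7 exp(-G/25) (floor 0.3), and relative contractility deficits
add a contraction delay (up to 2 frames) and an early-to-late systolic
passive stretch (post-systolic-shortening pattern, amplitude 0.18 x
deficit) — so diseased subjects have systematically smaller |GLS|, lower
LVEF and lower GWE, and a hypokinetic wall lags visibly in the video.

Reference labels are computed analytically from the generating geometry:
strain from the midline-annulus perimeter averaged over the three views;
EF from biplane Simpson volumes built from A4C/A2C chord widths of the
analytic boundary; GWE by aggregating constructive and wasted work (step
shortening/lengthening x midpoint pressure, over systole) across six wall
segments per view under a schematic LV pressure curve (8 -> 120 mmHg),
mirroring how work efficiency is derived from segmental pressure-strain
loops; a motionless heart is assigned GWE = 100 (nothing is wasted).
Significant cohorts draw a culprit-territory lesion cluster (one >=70%
lesion plus 1–3 more at 40–100%), non-significant subjects 0–3
sub-threshold lesions; `round(prevalence x n)` subjects are significant,
with the default prevalence 122/290 matching the reference cohort
composition.

**What the generator does not emulate:** real speckle decorrelation and
through-plane motion, valves and atria, probe/depth variation, foreshortening,
image-quality heterogeneity, and label noise from human annotation.
Passing tests therefore demonstrate that the architecture, losses,
schedule and scoring are implemented correctly and can extract
disease-relevant motion features — not that clinical-grade accuracy would
transfer to hospital data.

## Reduced-scale study sizes

The checked-in training study runs 60 subjects at 64-px frames with width
multiplier 1/8, epochs 5/5/10, batch 6 without accumulation, and per-phase
peak learning rates (1e-2, 3e-3, 1e-3): with ~100 optimizer updates per
phase, total parameter displacement scales with (updates x rate), so the
from-scratch phase needs a much larger rate than the full 150-epoch recipe
to converge at all, while the later phases — which fine-tune on top of
phase-1 features — want progressively smaller ones.  Both effects are
visible directly in the phase loss curves.
These sizes are the package's reduced-scale reference configuration; the
full-width 256-px architecture is exercised by a forward-pass conformance
check, and mask-metric recovery runs at the full 256-px raster.

## Numerical choices and degenerate inputs

* Dice loss epsilon 1e-6; batch-norm epsilon 1e-5, momentum 0.1.
* `gwe_from_loop` raises on zero total work (efficiency undefined).
* `metrics_from_masks` raises naming the first frame whose cavity or
  myocardium class is empty; disk extraction uses the principal axis of
  the cavity pixel cloud with 20 slabs.
* Empty-both-masks Dice is defined as 1; undefined confusion-matrix ratios
  are reported as NaN, never silently 0.
* Bootstrap CIs are subject-level percentile bootstrap (B = 1000 default);
  degenerate resamples are skipped and counted.  The CI method is this
  package's choice.
* Classifier decisions at exact thresholds are inclusive (>= 50, >= 70,
  >= 15).

## Known limitations

* CPU-only: the engine favours clarity and testability over throughput;
  full-width training at 256 px is impractical on one core (the
  reduced-scale configuration exists for exactly this reason).
* The synthetic generator's disease couplings are stylised; effect sizes
  were chosen to mirror the direction and rough magnitude of published
  group differences, not fitted to data.
* Bi-LSTM and attention layers assume the fixed 20-frame grid.
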