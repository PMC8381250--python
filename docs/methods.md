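# Methods note

This package implements a liver-tumor segmentation pipeline for axial
CT slices and exercises it at desk scale on synthetic phantoms. This
note records the modeling choices, default parameters and their
rationale, and the known limits of the synthetic setting.

## Problem setting and conventions

- Volumes are 3D arrays in Hounsfield units (HU); the third array axis
  is the axial (through-plane) direction. Default voxel spacing is
  (1.0, 1.0, 2.5) mm.
- Labels follow the LiTS convention: 0 background, 1 liver, 2 tumor.
  The liver mask is `label >= 1`, so tumor ⊆ liver by construction.
- Segmentation is slice-wise 2D: each axial slice is processed
  independently and predictions are restacked into a volume.

## Phantom generator

Each case is a body ellipse (~40 HU) on an air background (−1000 HU)
containing a liver ellipse (mean 60 HU, SD 10) over a central run of
slices with sinusoidal tapering. One to three hypodense tumor blobs
(disk plus small satellite bumps, radius 3–8 px) are placed inside the
liver across one to three consecutive slices; their mean HU sits
`contrast_gap` below the liver mean (default 30 HU). Global Gaussian
noise (SD 5 HU) is added last. Cohorts pin each case's tumor radius on
an even grid over the radius range so small- and large-tumor strata are
both populated. All sampling is driven by per-case seeds derived from
a master seed by counter, so cohorts are order-independent and
reproducible.

The phantoms are deliberately simple: elliptical anatomy, no
respiratory or partial-volume effects, spatially white noise. They are
sufficient to exercise every pipeline stage and to make learning
nontrivial (noise SD 5 vs contrast 30), but results on them say nothing
quantitative about clinical CT.

## Preprocessing

- **HU window** (−45, 105): the standard soft-tissue window (width 150,
  level 30) brackets liver (~60 HU) and hypodense tumors; values are
  clipped and mapped linearly to [0, 1].
- **Point-to-point flip**: the windowed image is rendered to 8-bit and
  each liver pixel p is replaced by 255 − p; everything outside the
  liver is forced to black. Hypodense tumors thereby become the
  brightest structures and all non-liver context is removed. The flip
  is applied identically at training and inference time, which is why
  inference requires a liver mask and why predictions are intersected
  with the liver.
- **Grayscale float** (train only): one multiplicative factor
  u ~ U(0.8, 1.2) and one offset v ~ U(−0.2, 0.2) per image, clipped to
  [0, 1].
- **Geometric augmentation** (train only): mirror, rotation ≤ 5°,
  translation ≤ 2 px, shear ≤ 0.02, applied jointly to image (linear
  interpolation) and masks (nearest). The defaults are deliberately
  gentle and sized for 64-px slices: with small training sets and small
  targets, stronger settings (10°/4 px) moved too much probability mass
  off the thin tumor blobs and prevented convergence. Right-angle
  rotations and integer shifts are exact grid maps.
- **Contrast filter** (train only): a tumor-bearing slice is dropped
  when |mean HU(tumor) − mean HU(liver∖tumor)| falls below a critical
  threshold (default 10 HU); tumor-free slices always pass. Rationale:
  slices where the tumor is radiologically invisible contribute labels
  without learnable signal. The statistic is a package choice; other
  contrast measures would serve equally.

## Network

A U-shaped encoder–decoder ("S-Net"). Encoder blocks are
(conv 3×3 → batch norm → ReLU) × 2 with channel doubling per level and
2×2 max pooling between levels; defaults depth 4, base 32 channels
(encoder sequence 32, 64, 128, 256). The bottleneck output passes
through a channel+spatial attention block (CBAM-style): spatially
avg/max-pooled descriptors through a shared two-layer perceptron give
per-channel weights; channel-pooled avg/max maps through a 1×1
convolution give a per-position map. Normalization is softmax by
default (weights are probability distributions; an optional rescale by
the element count keeps feature magnitudes unchanged, so uniform
attention is the identity); sigmoid is available since softmax maps
scale as 1/(H·W). The decoder mirrors the encoder with nearest-neighbor
upsampling and concatenative long-hop connections; the head is a 1×1
convolution + sigmoid giving per-pixel tumor probability. Masks are
thresholded at p ≥ 0.5.

**Head bias initialization** (−4.0): tumors occupy a tiny fraction of
each slice. With a symmetric initialization the network starts at
p = 0.5 everywhere and the soft-Dice denominator Σp dominates the
gradient, which stalls training for many epochs. Initializing the head
bias at the approximate prior log-odds of the foreground starts
predictions near zero and gives the Dice loss usable gradients from the
first steps; this was the single most important convergence fix at
desk scale.

The network runs on a small reverse-mode autodiff engine (`snetseg.nn`)
written on NumPy: im2col+GEMM convolutions, fused batch norm, 2×2 max
pooling, nearest upsampling, softmax, concatenation, and SGD with
classical momentum. No deep-learning framework is required; all layer
gradients are covered by numerical gradient checks in the test suite.

## Training protocol

Soft Dice loss (per sample, then batch mean; smoothing ε = 1e-6), SGD
with momentum 0.9, initial learning rate 0.01. After each epoch the
validation loss is fed to a reduce-on-plateau scheduler (factor 0.1
after 3 consecutive non-improving epochs). Validation Dice is computed
**per case** — each validation case's slices are restacked and scored
as one volume, then averaged over cases — matching the evaluation
metric instead of a per-slice mean, which is dominated by trivially
empty slices. The weights of the epoch with the best validation Dice
are checkpointed. An optional `stop_dice` ends training early once the
validation Dice reaches a target; the desk-scale study uses 0.6 with a
30-epoch cap. Non-finite losses abort with an error rather than
continuing silently.

## Post-processing and evaluation

Predicted masks are closed morphologically (default: radius-1 disk,
slice-wise). Closing pads by the structuring-element radius before
dilation/erosion so border objects are treated by the definition rather
than clipped. Metrics: Dice per case (DC, unweighted mean over cases),
Dice global (DG, pooled voxels), VOE = 1 − Jaccard, and ASSD/RMSD over
pooled symmetric boundary distances (face-connectivity boundaries,
Euclidean distances with anisotropic spacing, KD-tree nearest
neighbors). Conventions: Dice of two empty masks is 1.0, of one empty
mask 0.0; VOE of two empty masks is 0; surface distances are undefined
(error / NaN in cohort reports) when either mask is empty. Cases are
stratified into small/large at `threshold × max cohort tumor count`
(default 0.2, count at the cutoff is "large"); an absolute voxel-count
cutoff is also available, since the fraction-vs-absolute reading of
such thresholds is ambiguous in common usage.

## Desk-scale study sizes

The end-to-end study (in `scripts/acceptance.py` and the smoke test)
uses 30 phantom cases at 64×64×10, a 70/15/15 case-level split, at most
200 training slices, and a depth-3/base-16 network — sizes chosen so
the full pipeline trains in minutes on one CPU while remaining
nontrivial (the untrained network scores Dice ≈ 0). Across seeds the
held-out Dice per case lands around 0.7–0.8. These sizes are package
choices for a tractable demonstration, not tuned quantities.
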