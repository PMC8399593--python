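# Methods

`neoseg` implements a complete, reproducible pipeline for detecting and
localizing retinal neovascularization — the growth of fine, fragile new
blood vessels that marks proliferative diabetic retinopathy (PDR) — by
per-pixel semantic segmentation of color fundus photographs. Because
clinical fundus datasets with pixel-level neovascularization labels are
rarely shareable, the package pairs the method with a synthetic phantom
generator that produces fundus-like images with exact ground truth, so
every stage is testable end to end.

## The segmentation model

Each pixel of a (preprocessed, single-channel) fundus patch is assigned
one of two classes, *Neo* (neovascularization) or *NotNeo*, by a
42-layer fully convolutional encoder–decoder:

* **Stem.** A 7×7 convolution (32 filters, stride 1, same padding) with
  batch normalization and ReLU. The wide first kernel reflects the high
  resolution of the source images: more context enters the first feature
  map than a 3×3 kernel would admit.
* **Encoder.** A 2×2 max-pool (stride 2), then two residual blocks (64
  and 128 filters) that downsample ×2 each. A block's main path is
  3×3 conv (stride 2) → BN → ReLU → 3×3 conv → BN; because the main path
  halves the resolution, the skip path carries a 1×1 convolution with
  stride 2 (plus BN) so both meet at the element-wise addition with
  identical shapes; a ReLU follows the addition. The 1×1 skip kernel
  downsamples with minimal filtering, preserving the identity-like
  character of the shortcut. After three ×2 reductions the feature maps
  sit at 1/8 resolution, where a 1×1 bottleneck convolution (128
  filters) operates — at that scale few pixels remain for larger
  kernels.
* **Decoder.** Three transposed convolutions (4×4 kernels, stride 2,
  symmetric crop; 64, 64, 32 filters) restore full resolution; the first
  two carry BN + ReLU. The kernel size is a standard choice for ×2
  upsampling that avoids checkerboard artifacts; the study design fixes
  the stride but not the kernel.
* **Skip by concatenation.** The final upsampled maps (32 channels) are
  depth-concatenated with the stem activation (32 channels, equal
  spatial size) to give 64 channels of mixed coarse context and fine
  detail. Concatenation — rather than the U-Net strategy of raising
  feature-map resolution — keeps feature-map sizes fixed and memory flat.
* **Head.** Two 3×3 conv + BN + ReLU trios that keep the 64-channel
  width delivered by the concatenation, a 1×1 convolution to 2
  channels, and a per-pixel softmax.

Counting every layer from the input through the softmax — and not the
classification loss — gives 42 layers. The plan is declarative
(`neoseg.nn.spec.NetworkSpec`): shape inference, parameter counting,
serialization and the executable graph all derive from the same layer
list, so the architecture asserted in tests is the architecture that
runs.

The head's filter counts are a free choice; keeping the post-concat
width (64) preserves the mixed fine/coarse feature space through the
full-resolution decision layers, at quadratic compute cost in width.

## Numerics

The network runs on hand-written numpy kernels (im2col convolution via
BLAS matrix products, batch normalization, max-pooling, transposed
convolution, softmax) with analytically derived backward passes; the
full backward graph is verified against central finite differences in
the test suite. Arithmetic is single precision. Batch normalization
uses eps = 1e-5 and running-statistics momentum 0.1; inference
normalizes with the running estimates. Max-pool gradient ties (exactly
equal values in one window) route the gradient to every maximum — with
continuous activations such ties have measure zero. An exact softmax
tie (p = 0.5) at segmentation time is assigned NotNeo, the conservative
majority class.

**Weight initialization.** Convolution weights are zero-mean Gaussians
at a fraction of the He magnitude (gain 0.05 on std = sqrt(2/fan_in)
for every convolution except the final 1×1 classifier, which keeps the
full He scale), with a recorded seed. For the batch-normalized layers
the forward pass is invariant to weight magnitude while the effective
step size of gradient descent scales as lr/‖w‖², so a sub-He gain is
what makes the architecture trainable at the small fixed learning rate
of the training regime (5e-4) within a practical iteration budget; at
full He gain the same optimizer crawls.

## Training regime

Stochastic gradient descent with momentum: v ← µv − η∇, w ← w + v, with
mini-batch size 7, momentum µ = 0.9, initial learning rate η = 5e-4
held constant, and at most 10 epochs — the tuned operating point of the
study design. The loss is the mean per-pixel cross-entropy,
−w_c·log p(true class), probabilities clamped at 1e-12; per-class
weights default to (1, 1) and a weighted mode is available for the
phantom experiments, where Neo pixels are ~1% of the raster and the
unweighted optimum is degenerate over short runs.  The weighting used
in those experiments is inverse frequency on the background class with
the Neo weight capped at 4: uncapped inverse frequency (~50 on
phantoms) makes false positives nearly free in the loss and saturates
recall at the expense of precision.

After every mini-batch iteration the full validation loss is evaluated
(`validation_frequency` widens this for large runs). A cumulative
patience counter increments every time the validation loss fails to
beat the running minimum and never resets; training stops when it
reaches `validation_patience` (default 4) or when the epoch budget
ends. The returned parameters are those of the iteration with the
minimum validation loss, the standard best-weights contract. Data
order is reshuffled once per epoch under the run seed; the final short
mini-batch of an epoch is kept.

## Preprocessing

The enhancement chain is fixed: green-channel extraction (vessels carry
the strongest contrast there), CLAHE, background crop, non-overlapping
patching, per-patch min–max normalization to [0, 255]. Ground-truth
masks undergo only the geometric steps (crop, patch, flip); contrast
operations never touch labels. CLAHE runs on the full image before
patching, with normalized clip limit 0.01 on an 8×8 tile grid —
conventional defaults, exposed in configuration since the study design
does not record them. Crop offsets default to centered along the wide
axis (symmetric background removal). Training sets are tripled by
horizontal and vertical flips (the doubly flipped copy is excluded;
only that convention turns 100 patches into 300). Random
train/validation/test splits use fractions (0.5, 0.25, 0.25) with
largest-remainder rounding, which is deterministic and reproduces the
200 → 100/50/50 partition.

## Evaluation

Pixel-level confusion counts (Neo positive) feed six metrics: accuracy,
sensitivity, specificity, precision, Jaccard and Dice. A metric whose
denominator is zero is *undefined* — rendered as "-" and excluded from
averages, never coerced to 0 or 1. With tp = 0 but fp + fn > 0 the
overlap metrics are a defined 0. These conventions are forced by the
reference per-image table shipped with the package: its average row is
reproducible only under defined-only averaging, and its one
all-negative image with false positives prints 0.0000 for precision,
Jaccard and Dice while leaving sensitivity dashed. Per-image averages
are arithmetic means over images where the metric is defined (the
pooled-pixel alternative does not reproduce the printed row).

The patch-classification view tiles each segmented test patch into
fixed rectangles (200×296 at full study scale; scaled proportionally
for phantoms) and calls a tile positive iff it contains at least one
Neo pixel, identically for prediction and truth. Tile-level counts are
pooled over the whole testing set before metrics are computed,
matching the "N of the 400 image patches correctly classified" reading;
reports round half-up to 4 decimals.

## Synthetic phantoms

A phantom is a dark canvas with a circular retina (radial shading), one
bright elliptical optic disk, a recursive binary vessel tree (child
width = 0.72 × parent, floor 1 px; segments are gently curved random
walks), and `n_lesions` neovascular lesions: tangles of ≥
`lesion_vessel_count` thin (1–2 px), highly tortuous strokes radiating
from a lesion center and confined to a disk whose radius is drawn from
`lesion_radius_range`. Because every stroke passes through the center,
each lesion is one connected mask component. Vessels and lesions share
one palette whose contrast against the retinal background is largest in
the green channel, as in real fundus photographs. The mask marks
exactly the lesion stroke pixels. Lesions reject overlap with each
other and with the optic disk (disk neovascularization is a separate
clinical entity that the segmentation targets do not cover). Gaussian
noise (sd 3 by default) is added and clipped to [0, 255].

The default phantom is 400 × 592 — a 1/5-scale stand-in for the
2000 × 2368 cropped clinical image, chosen so that the 8-fold
downsampling path and a 5 × 2 patch grid (80 × 296 patches, the scaled
analogue of 400 × 1184) both apply exactly. A master seed expands to
per-image seeds by unit increments, so any single file regenerates in
isolation.

What the phantoms do *not* model: exudates, hemorrhages,
microaneurysms, illumination gradients, camera vignetting or
photorealistic texture. Passing on phantoms therefore demonstrates
that the pipeline's mechanics (geometry, losses, metrics, determinism)
and the network's capacity to learn thin-structure discrimination are
sound — not clinical performance. Notably, phantom lesion strokes and
the thinnest normal-vessel branches are locally similar by
construction; separating them requires the network to use tangle
density and curvature context, which is the intended difficulty.

## Problem sizes in the shipped runs

Tests and the acceptance script run scaled-down configurations chosen
as sensible desk-scale defaults: pipeline smoke runs use 4–6 phantoms
(160×160 or 400×592) and a few training epochs; the learning-sanity
check trains on 4 lesion-bearing 80 × 296 phantom patches for at most
200 iterations at the study hyperparameters. The full-scale geometry
(2000 × 3008 sources, 400 × 1184 patches) appears in the patch-
arithmetic checks, which are pure geometry and run in milliseconds.

## Known limitations

* The layer plan is a committed reconstruction honoring every stated
  architectural constraint (kernel-size policy, one concatenation with
  the stem, modified residual downsampling, BN+ReLU placement, the
  42-layer count); exact per-layer filter counts of the original design
  are not published, so other reconstructions are possible.
* Batch normalization is assumed present on the residual skip path.
* Training at the full study scale (200 patches of 400 × 1184) is
  possible but slow on the numpy backend; the package is tuned for
  desk-scale phantom work.
* The phantom generator's lesion statistics (size, count) are design
  choices; no published statistics exist to calibrate them against.
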