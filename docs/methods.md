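# Methods

## The model

`roigan` synthesizes *paired* medical images and region-of-interest (ROI)
masks with a cycle-consistent adversarial model whose input domain carries
a-priori regional features.  Given a paired sample — an intensity image
`x_img` in [0,1] and its binary ROI mask `y` — the *region image* is the
elementwise product `x_img * y` (tumor intensities only).  A small
convolutional network, the regional feature extraction block (RFB), maps the
region image to feature maps that are channel-concatenated with the image;
this fused grid is the domain-X input.  The ROI mask is the domain-Y input.
Two generators translate between the domains (G: X→Y, F: Y→X) and two
discriminators (D_y on ROI-like images, D_x on medical images) score realness.

Training minimizes, for the generators,

    L = L_GAN(G, D_y) + L_GAN(F, D_x) + λ · L_cyc

where `L_GAN(G, D_y) = E[log D_y(y)] + E[log(1 − D_y(G(x)))]` (discriminators
perform gradient ascent on the same quantity) and

    L_cyc = mean|F(G(x)) − x_img| + mean|G(F(y)) − y|

with per-pixel means so the loss magnitude is resolution independent.  The
x-side cycle reconstructs the *image channel* (the medical image), the only
part of the fused input the model is asked to reproduce.  In the y-side
cycle the fused input to G is rebuilt from F(y): the region image is
`F(y) * y` (the seed mask supplies the region support), so the RFB receives
gradients through both directions and is trained jointly with the generators;
no separate pretraining exists.

Synthesis is seeded by a real pair: (i) image synthesis runs
x → G(x) → F(G(x)); (ii) ROI synthesis runs y → F(y) → G(F(y)) and binarizes
the soft output at a threshold (default 0.5).  There is no noise input, so
unconditional sampling is out of scope by construction; every synthetic image
is emitted with the synthetic ROI from the same cycle.

## Architectures

All specs are declarative (`NetworkSpec`) with hard shape contracts, and are
executed by a small NumPy engine (`roigan.nn`) with hand-written backward
passes (im2col convolutions, transposed convolutions as the conv adjoint,
instance normalization, reflection padding); correctness is guarded by
finite-difference gradient checks in the test suite.

* **Generator** (size S divisible by 4): 3-pixel mirror pad (S → S+6), four
  conv layers — 7×7/stride 1/32ch, 3×3/s2/64ch, 3×3/s2/128ch, 3×3/s1/128ch —
  each followed by instance norm + ReLU; two transposed convs (3×3, s2)
  back to S with two concat-fusion skip layers (encoder features
  concatenated, merged by a 1×1 conv) at the S/2 and S resolutions to
  preserve low-level image information; final 7×7 conv + sigmoid keeps the
  output in [0,1] (the data are max-normalized to [0,1], so a tanh output
  would need re-ranging).  At S=256 this plan reproduces the published shape
  anchors exactly: 262×262 after padding and a 128-channel 64×64 bottleneck
  after the third conv.  The four "convolutional layers" of the published
  description are the encoder/bottleneck convs; the output projection is an
  additional 7×7 conv.
* **RFB**: two mirror-pad layers, three convs (16/32/64 channels, strides
  1/2/1, instance norm + ReLU) and one transposed conv restoring the input
  size with `feature_channels` (default 8) output maps.  Kernel sizes and
  channel counts are this package's choices; only the layer-kind census and
  the size-restoring contract are externally fixed.
* **Discriminator**: four 4×4/stride-2 convs (64/128/256/512, leaky-ReLU
  slope 0.2, the DCGAN convention), flatten, dense to one unit, sigmoid — a
  single realness score in (0,1).

Whether fusion means concatenation or addition was an open design point;
concatenation was chosen because it preserves the identity of channel 0
(the unmodified image), which is directly testable.  Instance norm uses
eps=1e-5 and no learnable affine; weights are initialized N(0, 0.02) from a
seeded generator (cycleGAN convention).

## Training procedure

Batch size 1 (instance normalization makes per-sample statistics the only
ones used; train/eval forwards are identical).  Per step: update D_x and D_y
by ascent on the adversarial objective with detached fakes, then one joint
Adam step for G, F and the RFB.  The generators minimize the adversarial
term exactly as written (the saturating form); `non_saturating=True` enables
the standard −log D(G(x)) variant.  Discriminator outputs are clamped to
[1e-7, 1−1e-7] inside the logs.  λ defaults to 10, the published cycleGAN
default, since the combined objective's weighting is otherwise unspecified.
A NaN in any loss term aborts with the step and term named.  Runs are
bit-reproducible under a fixed seed on a fixed machine.

Two configuration profiles:

| parameter | full scale (default) | desk scale (`TrainConfig.desk_scale`) |
|---|---|---|
| epochs / steps | 300 epochs | 300 optimizer steps |
| learning rate | 2e-4 | 2e-3 |
| Adam β1, β2 | 0.9, 0.999 | 0.5, 0.999 |
| λ (cycle) | 10 | 10 |

The full-scale defaults mirror the published recipe (Adam with default
parameters, lr 2e-4, 300 epochs).  The desk profile is this package's choice
for CPU-sized runs: it executes roughly 150× fewer optimizer steps than a
full training, compensated by a 10× learning rate and the β1=0.5 that short
adversarial schedules conventionally use.

## Synthetic phantoms

The phantom generator produces what the method structurally assumes: a
tissue background, a compact high-contrast tumor with an exactly aligned
binary mask, intensities in [0,1].  Tumors are random ellipses (radii
sampled from `tumor_radius_range`, random rotation, optional sinusoidal
boundary wobble), placed with a margin so each mask is one connected
component strictly inside the frame.  The background is a constant level
plus, optionally, a smoothed Gaussian random field (correlation length
`texture_scale`, amplitude 0.05 by default) — pure-constant backgrounds make
SSIM degenerate (zero variance) — plus i.i.d. Gaussian noise; the image is
clipped to [0,1] after noise, preserving the normalization invariant.
Defaults: 64×64, background 0.3, contrast 0.4, radii 6–14 px.

Desk-scale training and the acceptance run use *noise-free, texture-free*
phantoms (background 0.3, contrast 0.4): there the image is an exact
two-level function of the mask, so cycle reconstruction quality is cleanly
measurable against the contrast.  What passing these tests shows is that the
mechanism works — losses descend, the cycle reproduces held-out phantoms,
synthesized ROIs overlap the true masks; it does not show that the model
synthesizes realistic mammograms or brain MRI.  The phantoms have no imaging
physics, no multi-sequence structure, and far less appearance variability
than the real datasets the method targets.

## Metrics

PSNR and SSIM are computed from global statistics over the evaluated region,
exactly as the defining formulas print them: PSNR uses the squared maximum
pixel value of the two images over the region MSE (identical inputs give an
infinite PSNR, reported as a sentinel and excluded from mean±SD aggregates
with a count); SSIM uses region means/variances/covariance with
c1=(0.01·L)², c2=(0.03·L)², L=1 (a sliding-window Gaussian mode is available
behind a flag for cross-tool comparison with scikit-image).  MS-SSIM follows
the standard construction — contrast-structure terms at each dyadic scale
(2×2 average pooling), luminance at the coarsest, standard five-scale
weights renormalized when fewer scales fit — and reduces exactly to SSIM at
one scale; negative components are clamped at zero before exponentiation.
The tumor-region restriction evaluates PSNR/SSIM statistics over
mask-foreground pixels only (the restriction rule itself was unspecified and
is this package's documented choice); for tumor-region MS-SSIM the mask is
average-pooled alongside the images and used as per-scale pixel weights,
since multi-scale statistics on an irregular pixel subset are otherwise
undefined.  Dice of two empty masks is defined as 1 (perfect agreement, with
a warning); Hausdorff distance on any empty mask is an error, as the
distance to an empty set is undefined.  Histograms use 256 equal-width bins
over [0,1] by default and are compared by total-variation distance.  Paired
comparisons use two-sided paired-samples t-tests at α=0.05.

## Downstream classification

Feature extraction is pluggable (any callable image → vector); the built-in
deterministic fallback extractor (downsampled intensities, 128-bin
histogram, super-threshold area fractions, marginal profiles, gradient
statistics — 522 values, first 500 kept in extractor order) lets the whole
pipeline run without pretrained weights.  RFE drops the lowest-ranked 10% of
remaining features per iteration (at least one) until 30 remain, ranking by
per-fold linear-SVM |coefficients| averaged over five stratified folds;
whether the internal ranking model should be the kernel SVM itself was open,
and a linear model was chosen as the standard, stable criterion.
Classification uses an RBF-kernel SVM (C=1, bandwidth by the median
heuristic `gamma='scale'`, standardized features); Acc/Sen/Spe come from the
confusion counts with the HGG-analogue as positive class, AUC from
trapezoidal ROC integration (verified against the Mann–Whitney concordance
identity).  The experiment driver structurally rejects any synthetic sample
in a test set.

## Numerical choices and limitations

* float32 forward/backward in training; float64 in metrics and tests.
* Conv shape arithmetic floors; backward passes zero-extend accordingly.
  Generator sizes must divide by 4, discriminator sizes by 16.
* Crop windows center on the mask bounding-box center, clamped in bounds;
  oversized lesions are cropped to their bounding box and resized (bilinear
  image, nearest-neighbor mask, preserving binarity).  The train/test split
  is a seeded uniform permutation with nearest-integer train count
  (107 pairs at 0.7 → 75/32).
* PNG pairs are written as 16-bit grayscale; round-trip error ≤ 0.5/65535.
* Checkpoints are single-file `.npz` archives embedding the JSON network
  specs, so a saved model is auditable without code execution.
* The feature extractor interface accepts learned extractors, but none is
  bundled; all shipped results use the non-learned fallback.
* Desk-scale problem sizes used throughout the tests and the acceptance
  script: 16 training phantoms and 8 held-out phantoms at 64×64, 300
  optimizer steps, 100×500 feature tables.
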