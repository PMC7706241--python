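# Methods

`chdseg` re-implements, end to end and at desk scale, a GAN-augmented
segmentation pipeline for short-axis cine CMR of pediatric hearts with
complex congenital disease: preprocessing, exact geometric augmentation, a
skip-architecture FCN with a U-Net baseline, a two-channel DCGAN that
synthesizes paired image+mask samples, quality filters for those samples,
and the geometric / volumetric / statistical evaluation suite.  Every stage
is exercised on a built-in cardiac phantom, so the whole pipeline is
testable without downloading data or training at GPU scale.

## The phantom and what it does (not) emulate

`phantom_data` renders studies that structurally match a pediatric
short-axis acquisition: 12–15 slices per phase (default 13) at 512×512,
in-plane spacing 1.7 mm, slice thickness 8 mm; per slice one
simply-connected bright LV blood pool (disk) inside a darker myocardial
ring and one crescent-shaped RV (a half-annulus hugging the septum);
end-systolic radii are the end-diastolic radii scaled by
`es_shrink_factor = 0.6` (so ES/ED areas are 0.36 and EF ≈ 64%, in the
physiological range); radii taper linearly base→apex (apical fraction
0.55), and by default the last slice is empty to exercise empty-slice
handling.  Masks are rasterized analytically *before* Gaussian intensity
noise (σ = 0.05) is added, so the ground truth is exact and chamber volumes
have a closed-form reference.

Two deliberate non-realisms:

* **Geometry scale.** The LV basal radius is drawn from 36–44 px so that
  after preprocessing the mask-area fraction of the 128×128 frame is
  centred (~0.010) inside the nearest-neighbour quality window
  (0.005–0.025) used downstream — the same relationship the real training
  data must have to its filter window for the filter to be useful.  At the
  fixed 1.7 mm spacing this makes absolute phantom volumes larger than a
  pediatric cohort's; the pipeline only ever uses identities (SV = EDV−ESV,
  EF = 100·SV/EDV) and relative comparisons, so mask-fraction coherence was
  prioritized over absolute-volume realism.
* **Appearance.** No bSSFP contrast physics, trabeculation, papillary
  muscles or through-plane motion.  Passing tests therefore demonstrate
  correctness of the machinery (shapes, counts, losses, metrics,
  statistics), not clinical-grade accuracy on real CMR.

## Preprocessing

Order is fixed: center-crop to 445 px (the odd 67-px remainder puts the
extra pixel on the top/left margin — any fixed rule works; this one is
documented and tested) → down-sample to the network size (default 128) by
nearest-neighbour (pixel-center index rule) or bicubic → z-normalize.
Masks are always resampled nearest-neighbour and re-thresholded, since
fractional mask values are meaningless downstream; constant images
normalize to zeros rather than dividing by zero.  Pairs whose mask is empty
after resampling are excluded.  `ImageMaskPair` carries the *effective*
pixel spacing (source spacing × crop/target) so that millimetre metrics
computed on the resampled grids are physically correct.  Splitting is at
subject level (round(0.8·n) train), so no subject leaks across the
partition.

## Augmentation

Only rotation and flips — transformations that deform chamber shape are
excluded.  Three exact schemes: `classic40` (angles 0…180 step 20 × flips
{none, h, v, both}), `gan76` (step 10 × same flips), `synth7` {identity,
h-flip, v-flip, rot 45/90/135/180}.  The identity is counted and duplicates
are kept: the multiplicities 40/76/7 require it.  Images rotate bilinearly,
masks nearest-neighbour with re-binarization, zero fill outside the canvas;
multiples of 90° use the exact index permutation.  Mask area is conserved
exactly under flips and within ~3% under interpolated rotation for
chamber-like blobs.

## Segmentation networks and training

The FCN has 19 convolutional layers for 128×128 inputs: five encoder
stages of paired 3×3 convolutions with ReLU, four max-pools of size 3
(stride = size; 128 is not divisible by 3⁴, so pooling pads with −inf to
the ceiling multiple — spatial ladder 128→43→15→5→2 — and each upsampled
map is center-cropped back to its encoder partner), four kernel-4
transposed convolutions for the decoder, four 1×1 skip projections summed
into the decoder at matched resolutions, and a final 1×1 convolution with
sigmoid.  Encoder widths default to doubling 16→256 but are a config list,
since only the total design (19 layers, 4 pools of 3, kernel-4 upsampling)
is fixed; dropout 0.5 at the bottleneck and L2 1e−4 are likewise exposed
config.  The U-Net baseline is the standard contracting/expanding
architecture with pool size 2 and concatenation skips.

Training: Glorot-uniform init, SGD with Nesterov momentum (lr 0.002,
momentum 0.9), batch size 5, 450 epochs, minimizing the negative soft Dice
−(2Σpt+ε)/(Σp+Σt+ε) with ε = 1 (the smoothing matters exactly where Dice
denominators are small, i.e. near-apex end-systolic masks).  The model with
the best validation loss is retained.  One deviation from pure
by-the-recipe initialization: the final layer's bias starts at −3 so the
initial heatmap is near-background.  With the sigmoid starting at 0.5 on
masks occupying ~1% of the frame, Dice training otherwise sits on a long
plateau whose escape time varies strongly with the random seed;
prior-probability bias initialization is the standard remedy for sparse
dense-prediction targets and makes convergence seed-robust.

The whole network stack (convolutions, transposed convolutions, pooling,
batch-norm, the two optimizers) is implemented in NumPy inside `chdseg.nn`
with hand-written backpropagation; every layer and both full models are
verified against central-difference numerical gradients in the test suite.

## DCGAN

Generator: z ∈ R¹⁰⁰ ~ N(0, I) through six kernel-4 transposed convolutions
(stride 1 then five of stride 2; padding 1 on stride-2 layers, 0 on the
edge layers, yielding exactly 1→4→8→16→32→64→128), ReLU between stages,
Tanh last, two output channels (image, soft mask).  Discriminator mirrors
it: six kernel-4 convolutions (stride 2 except the last), LeakyReLU 0.2,
sigmoid scalar.  BatchNorm is on by default (standard for DCGAN, exposed as
a flag).  Each iteration performs exactly two steps — discriminator on a
real batch labelled 1 then a generated batch labelled 0; generator through
the frozen discriminator on a generated batch labelled 1 — with BCE loss
and Adam (lr 2e−4, betas 0.5/0.999, exposed config) for both networks, for
a fixed iteration budget (40,000 at full scale) with periodic mask-area-
spread diagnostics as a mode-collapse check rather than an automatic
equilibrium stop.

Numerical choices worth noting:

* **Weight init** is N(0, 0.02²).  Reading the quoted "variance 0.02"
  literally (std ≈ 0.14) saturates the discriminator's sigmoid before any
  training (outputs spanning 0.006–0.998 at init) and reliably produces
  the gradient-vanishing failure the init is meant to avoid; 0.02 is the
  DCGAN-conventional standard deviation.
* **Tanh-range mapping.** Real masks map {0,1}→{−1,1}; z-normalized images
  are squashed clip(z,−3,3)/3 since unbounded z-scores cannot match a Tanh
  output, and both maps are inverted on sampling (soft mask back to [0,1]).
* **Sampling** uses batch statistics in BatchNorm by default: with the
  training batch size of 5 the running moments are noisy and eval-mode
  samples degrade; sampling is deterministic per seed either way.

## Synthetic-sample filtering

quantize (≥0.5 → 1) → area window → component rule, in that order.  Windows
are 0.005–0.025 (nearest-neighbour data) and 0.02–0.05 (bicubic), bounds
inclusive; with more than one connected component (8-connectivity default)
the pair is removed when largest/second-largest < 20.  Note the exact pixel
boundaries at 128²: 0.005·16384 = 81.92 and 0.025·16384 = 409.6, so 82 and
409 px are the innermost passing counts.  `--take N` keeps the first N
accepted, or a seeded random N with `sample_seed` (both readings of "2,500
out of 6,000" are supported).  Every input gets a verdict row; the pipeline
is idempotent on its accepted set and monotone in both thresholds.

## Evaluation

Overlap: Dice, Jaccard, sensitivity, specificity, PPV, NPV as percentages;
both-empty masks score Dice = Jaccard = 100, ratios with zero denominators
are reported missing rather than 0.  Contours are mask pixels with a
4-neighbour outside; HD is the exact symmetric Hausdorff (not a
percentile), MCD the mean of nearest-contour distances over both directed
point sets, both in mm via the effective pixel spacing; either contour
empty → metrics missing and the exclusion is counted.  Volumes use slice
summation (Σ pixels × spacing² × thickness), which, like any slice-based
method, underestimates chambers extending into unsegmented slices.
Agreement per index (EDV/ESV/SV/EF × chamber): two-sided paired t-test
(pass ⇔ p > 0.05; zero-variance differences give p = 1, flagged), Fisher's
intraclass correlation ICC = (1/n)Σ(xᵢ−m)(yᵢ−m)/s² with pooled mean and
population variance over all 2n values, interpreted with the Koo–Li bins;
Bland–Altman bias ± 1.96·sd (sample sd); R²vol as squared Pearson
correlation by default with a regression-against-identity variant
(`method="identity"`), since the defining convention is not fixed by name
alone.

## Problem sizes used in tests and the acceptance script

Scaled-down experiments keep every structural element of the full recipe
while remaining CPU-friendly: the overfit sanity check trains an all-8-
filter FCN on 8 LV phantom pairs at 32×32 for 300 epochs; the GAN sanity
check trains a 32×32 DCGAN (generator widths 64/32/16) for 1,500
alternating iterations on ×76-augmented pairs from 4 subjects and filters
500 samples; metric oracles run on 500 random 8×8 mask pairs; statistical
recovery uses n = 10,000 simulated pairs at intraclass ρ = 0.8.  The
full-scale defaults (128×128, 40,000 GAN iterations, 450 epochs, 6,000
samples → 2,500 accepted → 17,500) are the package defaults and run through
the identical code paths.

## Known limitations

No FID scoring (requires pretrained external embedding weights); no
epicardial or myocardial-mass analysis (the design has endocardial masks
only); single-ventricle anatomies are out of scope; the NumPy engine is
CPU-bound and meant for correctness and desk-scale experiments, not
GPU-scale training on real cohorts; phantom realism is limited as described
above, so quantitative results on real CMR require training on real data.
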