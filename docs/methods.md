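# Methods

## Problem and protocol

Polyp segmentation models are trained on small datasets (hundreds to a
thousand frames), so augmentation choices materially change test IoU. The
package implements a one-factor-at-a-time ablation: a baseline model is
finetuned with no augmentation, every transformation/range combination is
finetuned under otherwise identical conditions, each experiment is repeated
(default ten times) to average over the randomness of the draws, and pooled
per-image test IoUs are compared against the baseline with a permutation
test. Augmentation is applied on the fly: parameters are re-drawn for every
sample every time it is served, never by pre-expanding the dataset.

## Augmentation operators

**Image-based** transforms act jointly on the image, the polyp mask and the
void mask with one shared coordinate mapping. Conventions (the operators are
bit-reproducible, so these matter):

* Resampling: bilinear for images, nearest-neighbour for masks (then a 0.5
  threshold wherever interpolation could occur), so masks stay binary.
* Fill: edge replication for regions exposed by the transform, matching the
  long-standing default of mainstream augmentation tooling.
* Shifts are rounded to whole pixels (no interpolation on masks); a shift
  fraction is relative to width/height and symmetric ranges draw uniformly
  from [−r, +r].
* Zoom uses a single shared factor for both axes per draw; factor < 1
  magnifies content ("zoom in": the analysed intervals lie below 1, e.g.
  [0.5, 1]), factor > 1 shrinks it.
* Shear is an affine map with tan(angle) about the center; |angle| = 90° is
  rejected (tan undefined).
* Elastic deformation follows the classic recipe: per-pixel uniform(−1, 1)
  displacement fields smoothed by a Gaussian of width σ (fixed at 40 in the
  analysed grid) and scaled by α (250–6000); the same realized field warps
  image and masks.
* Flips in the ablation grid are applied with probability 0.5 per draw.

**Pixel-based** transforms touch only the image. Brightness adds a signed
offset drawn uniformly in [−r, +r] (grid r: 25–175), contrast multiplies by a
factor drawn in [1−x, 1+x] (x up to 1.0; factors are clamped strictly
positive) — pure multiplication about zero, no recentering. Channels share
one draw or get independent draws. Rounding throughout is
half-away-from-zero followed by clipping to [0, 255].

**Application-based** transforms emulate endoscopy artifacts. Specular
highlights are ellipses rendered at 255 in all channels; blur is a mean
filter with edge replication, odd windows 3–15 (even-width mean filters have
no center pixel and are therefore excluded from the grid).

## Specular-highlight model

The shipped `SpecularModel` carries the moments measured on the manually
segmented specular-light class of CVC-EndoSceneStill: major axis 7.77 ± 10.36
px (max 259.81), minor axis 3.82 ± 4.29 px (max 137.39), count per image
18.20 ± 16.97. Both the count and the axes have coefficient of variation
near or above 1, which rules out (truncated) normal families — a
lower-truncated normal cannot exceed cv = 1. A **moment-matched gamma**
(shape (m/s)², scale s²/m) is therefore used for the count (rounded to an
integer) and for each axis (clipped to the observed maximum; the minor axis
is additionally capped by the major so the ellipse ordering invariant holds).
Axis statistics are full axis lengths; rasterization uses semi-axes of half
those values. Centers are uniform over the valid (non-void) area, since
reflections arise on tissue.

## Network and loss

The segmentation network is a U-Net: `levels` encoder blocks of two 3×3
convolutions (each with batch normalization and ReLU), 2×2 max-pooling
between blocks, channel widths doubling from `base_width`; the decoder
mirrors this with 2×2 nearest up-sampling, a 3×3 convolution, concatenation
of the matching encoder feature map and two further convolutions; a final
1×1 convolution plus sigmoid yields the probability map. The default
configuration (256×256×3 input, 5 levels, base width 64, dropout 0.5 on the
two deepest encoder blocks, batch norm on) reaches a 16×16×1024 bottleneck.
The implementation is plain numpy with hand-written backpropagation
(im2col convolutions, exact max-pool and batch-norm gradients), which keeps
training bit-reproducible under a seed and dependency-free.

The loss combines mean binary cross-entropy with the negative log of the
**soft Jaccard** Σ(y·ŷ) / (Σy + Σŷ − Σ(y·ŷ)), which keeps the IoU term
differentiable; probabilities are clamped to [ε, 1−ε], ε = 10⁻⁷, for the
cross-entropy. Batch normalization tracks running statistics with momentum
0.99 during training; because exponential averages can lag badly after short
trainings, `train_model` finishes with a precise-calibration pass that
replaces them with the exact average batch statistics over the training set
(dropout disabled), so eval-mode behavior matches what the network learned.
Evaluation-time IoU uses masks binarized at 0.5 (ties → 1)
and the set-based Jaccard, with the convention IoU = 1 when ground truth and
prediction are both empty (correctly predicting "no polyp" is a perfect
answer). Optimization is Adam (β₁ 0.9, β₂ 0.999, amsgrad off) under the
cyclic schedule rate(e) = base · 0.5^(e mod 5).

### Scaled-down training protocol

The full-scale protocol (256×256, 5 levels, base 64, base rate 10⁻⁴,
pretrained initialization) is GPU-scale. For CPU-scale work the package uses
a tiny configuration — 3 levels, base width 8, 64×64 inputs, dropout 0, 100
synthetic frames (80 train / 20 test), 15 epochs, batch 4 — and a base rate
of 10⁻³ with the same schedule shape. The larger base rate is the
appropriate choice when training this small network from random
initialization rather than finetuning a pretrained checkpoint; at 10⁻⁴ the
15-epoch budget is spent still descending. Pretrained weights can be
supplied by constructing the network and loading parameters before
`train_model`.

## Synthetic data generator

Each frame is a smoothly textured reddish field (Gaussian-filtered noise with
length scale `texture_scale` and sd `contrast_level`) inside a centered disc
whose radius is solved by bisection to hit the requested void fraction within
±0.01; the polyp is one ellipse (aspect ratio up to 2, near-circular when
very large) placed fully inside the valid area via a distance transform, its
semi-axes rescaled iteratively until the pixel count is within 5 % of the
requested fraction of the valid area; the blob is rendered paler and slightly
yellower with a smoothed boundary. After compositing, intensities are
rescaled so the mean HSV value channel hits `brightness_level`. Dataset
generation jitters per-sample parameters uniformly within configured ranges;
the `KVASIR_LIKE` and `ENDOSCENE_LIKE` presets center those ranges on the
two public datasets' published statistics (void ≈ 15 %/24 %, polyp ≈
17 %/12 % of valid area, brightness 0.622/0.560).

What the generator does **not** emulate: real mucosal texture, vasculature
and lumen geometry; specular highlights (added only by the augmentation);
multiple polyps; flat or sessile morphologies; camera noise and compression
artifacts. Passing tests therefore demonstrate that the pipeline is
correct and that the protocol can detect augmentation effects — not that any
particular transformation helps on clinical data.

## Statistics

The permutation test pools the baseline and group values, re-partitions them
into the original group sizes (default 10 000 times) and reports
p = #(|permuted mean difference| ≥ |observed|) / N. The absolute difference
makes the test two-sided, so both significant improvements and significant
decrements are starred, and the ≥ rule makes identical constant groups yield
p = 1 rather than 0. No small-sample +1 correction is applied. The unit of
analysis is the pooled per-image test IoU across repetitions — per-image
dispersion is what the benchmark's ± 8–9 sd magnitudes reflect; repetition
means can be aggregated by the caller when a coarser unit is wanted.

Summary tables report mean ± sd (×100, two decimals), deltas to baseline in
percentage points, and the best range per family (exact ties go to the
first-listed range of the canonical grid, making the selection stable under
row reordering). Combination strategies: (a) best (family, range) per
category; (b) best range of every image-based family whose best mean beats
the baseline, with zoom-in/zoom-out merged into one zoom family; (c) the two
distinct families with the highest best-range means. On the shipped
benchmark tables these rules reproduce the published picks in most but not
all cases — the published member lists for (b) and (c) deviate from their own
stated selection rules in a few places (e.g. improving rotation/shear/elastic
ranges omitted from the CVC list); this package follows the stated rules.

## Numerical conventions and degenerate inputs

* 8-bit images everywhere; rounding half-away-from-zero before clipping.
* Void detection without a void mask: all channels ≤ 8 (robust to
  compression noise).
* Histogram metrics use the HSV value channel with 256 bins; flatness is
  GM/AM of bin counts (0 as soon as a bin is empty), spread is the
  interquartile distance of the cumulative histogram over 255.
* `run_ablation` derives one seed per (experiment, repetition) via CRC32;
  weight initialization is shared across experiments within a repetition
  (the analogue of a shared pretrained checkpoint), so a zero-epoch run
  yields identical IoU vectors for every experiment and queuing extra
  experiments never perturbs the baseline's records.
* Degenerate cases: empty valid area, empty training set, missing baseline,
  fractions not summing to one, out-of-grid blur windows, |shear| = 90°, and
  non-positive contrast factors all raise `ValueError`; combination strategy
  (b) with nothing improving returns an empty, flagged spec instead of
  raising.

## Known limitations

* The numpy network is CPU-bound; the full-scale 256×256 configuration is
  usable for inference but impractically slow to train — the package targets
  protocol correctness at desk scale, not leaderboard IoU.
* The generator's uniform per-sample jitter reproduces dataset-level means,
  not the full shape of the published per-image distributions (e.g. the
  heavy right tail of polyp sizes).
* Only one transformation draw order is implemented for combinations:
  image-based, then pixel-based, then application-based.
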