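# Methods

## Pipeline

A whole-slide image is decomposed into a non-overlapping grid of
512 × 512 tiles at the scan magnification (level 0); `n_cols = ⌈W/512⌉`,
`n_rows = ⌈H/512⌉`, so edge tiles are smaller and every pixel belongs to
exactly one tile. Background tiles are discarded before inference by a
thumbnail-level tissue filter; the kept tiles are segmented independently
and their class maps placed back into a whole-slide label mask (no
blending — tiles partition the slide, and seam artifacts at tile borders
are accepted). Edge tiles are reflect-padded (symmetric mode, so 1-px
strips are handled) up to 512 before inference and the prediction is
cropped back to the true extent. Discarded tiles contribute label 0 and
are never scored; the per-slide report records total/kept/inferred tile
counts so a cohort run reproduces a tiles-per-slide histogram.

## Background filter

Papanicolaou staining puts colored material on bright glass, so tissue
detection operates on the HSV saturation of a ×32 thumbnail: a pixel is
tissue iff its saturation exceeds a threshold *and* its luminance
(`rgb2gray`) is below 250/255. The threshold is Otsu's on the saturation
histogram by default, clamped from below at 20/255: on a slide with no
stained material Otsu would split sensor noise into two classes and call
half the glass "tissue", and the clamp (with a warning) prevents that; a
constant-saturation thumbnail falls back to the same floor. Luminance
rather than HSV value is used for the brightness guard because fully
saturated stain can still have value 1.0 (e.g. magenta), while luminance
separates glass (≈1.0) from any stained pixel. A tile is kept when ≥5%
of its thumbnail footprint is tissue; the threshold, downsample, and
floor are all `FilterConfig` fields. The filter touches only the
thumbnail — for pyramidal slides the coarsest adequate level — never
level-0 tiles, which is the entire speed claim of the screening design.
Raising the tissue threshold can only shrink the kept set, and
kept + discarded always equals the grid size.

## Network

FCN-32s over VGG16, implemented in numpy (activations `(C, H, W)`
float32, batch = one tile). The layer arithmetic is: pad 100 per side;
first 3×3 convolution valid, all later 3×3 convolutions pad-1; 2×2
stride-2 max pooling with ceiling division on odd sizes; `conv6` 7×7
valid and `conv7`/`conv8` 1×1; one transposed convolution kernel 64 /
stride 32 mapping `h → 32·(h−1) + 64`; final crop back to the input
frame. For input 512 this reproduces the feature chain
712/710/355/178/89/45/23/17/576/512. The 576-px deconvolution output is
cropped with a symmetric offset of 32 per side (the classical FCN
offset-19 variant is available via `crop_offset`); symmetric alignment
matches the symmetric 100-px pad. Ties in the argmax resolve to the
lowest class index, i.e. toward background.

`width_multiplier` scales every channel width (`⌈c·m⌉`, minimum 1,
scoring layers fixed at `n_classes = 3`); spatial sizes are unaffected,
so the full-width architecture table is verified at full width while
training tests run at 1/64 width.

Convolutions are im2col + GEMM with explicit col2im backward; the
transposed convolution forward/backward are exact adjoints of the strided
convolution, computed by scatter/gather over kernel offsets; max-pool
backward routes gradients through stored argmax indices. Layer gradients
are finite-difference checked in the test suite.

## Training

Pixel-wise softmax cross-entropy (label 255 = ignore; an all-ignored tile
contributes zero loss and zero gradient), reduced by summation by default:
the published learning rate of 1×10⁻¹⁰ is only sensible against a
per-image summed loss of ~10⁵ pixels, the original FCN convention. Mean
reduction with a correspondingly larger rate is what the desk-scale tests
use. The optimizer is SGD with momentum (default 0.99, the
heavy-momentum convention paired with a tiny rate; unstated in the
source recipe) and coupled L2 weight decay: `v ← µv + (g + λw)`,
`w ← w − ηv`, so with a zero data gradient one step scales weights by
`(1 − ηλ)`. Batch size is one tile; sample order is reshuffled each epoch
from the config seed, dropout noise comes from a second seeded stream,
and two runs with identical seed and data produce bitwise-equal traces.

Inputs are mapped to optical density, `x = 1 − rgb/255`: stained (dark)
material becomes positive signal, bright glass approaches zero, and the
network's 100-px zero padding reads as glass rather than as maximally
dark tissue. This matters doubly for width-scaled models: the early
layers have one or two channels, and with ReLU + max pooling a channel
that responds *negatively* to stain has its evidence erased by the
bright background before the scoring layers.

Initialization: `pretrained_backbone` copies published VGG16 weights into
conv1–conv7 where shapes permit, zeroes `conv8`, and sets the deconv to
the exact separable bilinear kernel (for kernel 64: triangular profile of
half-width 32 centered at 31.5). When no weight file is available the
backbone falls back to randomly initialized convolutions with a warning;
`conv8` stays zero — initial logits are then identically zero, a stable
start. Random convolutions are He-normal with two standard adjustments
for very narrow stacks: each output channel is sign-oriented so its
coefficient sum is non-negative (a measure-preserving choice that keeps
stain evidence alive through the ReLU/max-pool chain), and the layers
are then rescaled layer-sequentially to unit output standard deviation
on a fixed synthetic probe (the LSUV scheme), which prevents the
orders-of-magnitude activation growth that otherwise destroys early
training. Both steps are deterministic per seed; layers loaded from
published weights are never rescaled.

Even so, a very narrow network occasionally draws an initialization whose
pooled features are blind to the stain layout; training then sits on the
class-prior plateau. `train_with_restarts` implements the standard
remedy: a short probe run, and a rebuild with a fresh seed if the loss
has not moved (at most 3 restarts, all deterministic from the config
seed). The desk-scale tests and the reproduction script train through
this protocol.

## Synthetic slides

The generator emulates the screening contract of papanicolaou-stained
cytology — colored cell clusters on bright glass — not its morphology:
non-overlapping random ellipses (two classes: pale-blue benign
`(170,200,230)`, dark-violet PTC `(110,50,140)`) with Gaussian interior
texture (sd 8) on a near-white background (245 with sd-3 noise). Colors
were chosen so HSV saturation separates both classes from glass by
construction, making filter behavior deterministic. Truth labels are
recorded at paint time; cluster placement retries 200 times before
failing. Slides are written as 3-level pyramidal tiled TIFFs so the same
code path serves gigapixel scans. PTC/benign assignment is exact
(`round(n·ptc_fraction)`), and training-tile crops anchor on clusters
round-robin, so tile class balance tracks `ptc_fraction`. What passing
these tests does *not* show: performance on real nuclear morphology,
stain variability, pen marks, or out-of-focus regions — none of which
the generator models.

A hand-weighted "color-rule" network (`ptcscreen.nn.reference`) encodes
`relu(B−R)` / `relu(R−G)` stain evidence in conv1, carries it through
the pooling chain, thresholds at conv6 and scores at conv8. It makes the
network's segmentation behavior known by construction and exercises the
full pipeline without training; because decisions pass five max-poolings,
boundaries dilate by up to one 32-px block, bounding achievable IoU on
small clusters (the paired fixtures use large ones).

## Problem sizes in tests and the acceptance script

Desk-scale choices, made once: fixtures are ≤1536² px (3×3 tile grids);
the architecture table is confirmed by one instantiated full-width
forward pass on a 512-px input; the training smoke runs a 1/64-width
network on eight 512-px synthetic tiles with mean-reduced loss, learning
rate 0.01, momentum 0.9, 40 epochs through the restart protocol (the
published 1e-10/sum recipe is the default config but is not informative
at eight tiles), and is scored by foreground IoU against generator truth
on those tiles. The screening demonstration uses
the color-rule model, which decouples pipeline correctness from training
stochasticity.

## Known limitations

- Whole-slide masks are held densely in memory during stitching; a
  91k × 44k slide needs ~4 GB. Streamed stitching to tiled TIFF would
  remove this but is not needed at fixture scale.
- The tissue filter is a standard saturation detector; it makes no claim
  of equivalence to any particular production filter beyond its contract
  (background tiles are skipped, stained tiles are kept).
- No data augmentation, learning-rate schedules, or class rebalancing;
  the training loop is deliberately the plain recipe.
- Single-level (non-pyramidal) TIFFs force the thumbnail to be computed
  from level 0, which weakens the filter's speed contract for such files.
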