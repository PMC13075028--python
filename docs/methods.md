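# Methods

## Model

The network is a four-stage hierarchical transformer encoder with an all-MLP
decoder, following the SegFormer design: overlapping patch embeddings
(7×7 stride 4, then 3×3 stride 2), efficient self-attention with spatial
reduction of the key/value tokens, and Mix-FFN blocks whose 3×3 depthwise
convolution supplies positional information, so no positional encoding is
needed and input resolution is free (any square side divisible by 32). Stage
outputs C1..C4 sit at strides 4/8/16/32 with strictly increasing channel
counts. Three sizes are configured:

| variant | stage channels | depths | decoder width | role |
|---|---|---|---|---|
| `b2` | 64/128/320/512 | 3/4/6/3 | 768 | base configuration |
| `tiny` | 32/64/128/256 | 2/2/2/2 | 256 | mid-size CPU profile |
| `micro` | 16/32/64/128 | 1/1/1/1 | 64 | test/ablation profile |

Weight compatibility with published SegFormer checkpoints is not a goal; the
encoder honours the pyramid contract and is trained from random
initialisation (truncated normal ±2 sd for projections, Kaiming-scaled for
convolutions, unit-γ/zero-β for norms), all drawn from a single seeded
generator so a model is a pure function of its seed.

### Efficient channel attention

ECA recalibrates the channels of the shallow stages (default {1, 2};
any subset of the four stages can be activated for placement ablations).
Global average pooling gives the channel descriptor; a **bias-free** 1-D
convolution across the channel axis with zero padding (k−1)/2 models local
cross-channel interaction; a sigmoid produces weights in (0,1) that rescale
each channel. The kernel size follows k = odd(log₂(C)/γ + b) with γ=2, b=1:
nearest odd integer, exact ties resolved upward, floored at 3 so a
degenerate single-tap kernel cannot occur (64 → 5, 128 → 5, 32 → 3). The
bias-free choice keeps the module at k parameters per recalibrated stage —
10 in total for the base configuration — and is exposed as a config flag.
Recalibrated features replace the stage output, so deeper stages, the
decoder and the boundary branch all consume the same enhanced tensors and
gradients from both loss terms reach the ECA kernels.

### Boundary branch and losses

The branch fuses C1′ with C2′ (bilinear ×2 upsample, channel concat),
applies a 3×3 convolution **without bias** (absorbed by the following batch
norm) to 64 channels, BN, ReLU, then a biased 1×1 convolution to one
channel, and bilinearly upsamples the logits to input resolution. Under
these bias conventions the branch holds 3·3·192·64 + 2·64 + (64+1) = 110,785
parameters in the base configuration.

Supervision targets are the morphological gradient of the binary mask:
dilation minus erosion with a 3×3 square structuring element, out-of-image
pixels treated as background, so border-touching objects produce contour
pixels at the border. The target is binary (no distance weighting), matched
with plain mean binary cross-entropy in logit space; an optional
positive-class weight exists but is off by default. The segmentation loss is
mean pixel-wise two-class cross-entropy on the decoder logits upsampled from
the stride-4 grid to input resolution. The total objective is
L_total = L_seg + λ·L_bnd with λ = 0.5 by default; λ = 0 removes the
boundary term from the graph exactly (the boundary loss is still logged).

All bilinear resampling in the project uses the half-pixel-center
(`align_corners=False`) convention, implemented as a separable pair of 1-D
interpolation matrices so forward and adjoint are exact transposes.

## Metrics

Region metrics come from pooled confusion counts; binary mIoU averages
foreground IoU tp/(tp+fp+fn) and background IoU. A class absent from both
prediction and ground truth contributes IoU = 1, so all-water tiles are not
penalised (configurable). F1 is the harmonic mean of foreground precision
and recall with 0/0 → 0.

Boundary metrics operate on contour pixel sets extracted with the same
morphological gradient as the supervision labels (keeping training target
and evaluation definition consistent). BF-score matches a contour pixel if
any opposite-set pixel lies within Euclidean distance δ (inclusive; δ = 3 px
default); both-empty contours score 1 (vacuously perfect) and a one-sided
empty contour scores 0. The Hausdorff distance is the plain sup-inf form
(100th percentile, not HD95); it is 0 when both contours are empty and
undefined (NaN) when exactly one is, in which case the image is excluded
from — and counted next to — the dataset mean. Dataset aggregation pools
confusion counts for region metrics (a per-image-mean switch exists) and
averages BF-score and HD per image. Nearest-neighbour queries use a k-d
tree; the test-suite checks exact agreement with O(|B_p|·|B_g|) pairwise
oracles on hundreds of random masks.

## Preprocessing and augmentation

Scenes are multiband rasters (read via `tifffile`; geo tags are passed
through opaquely, and no atmospheric correction, reprojection or
vector-annotation handling is attempted). Band roles are a required config
input (`NIR=B4, G=B2, B=B1` by default — the channels-4/2/1 composite);
they are never inferred from wavelengths. Each selected band is clipped to
its per-scene 2nd–98th percentiles (linear-interpolation percentiles),
mapped to [0, 255] with round-half-up and quantised to 8 bits; a constant
band maps to zeros. The stretch is per scene, before tiling, so tile
statistics do not depend on the tiling grid. Tiling pads the bottom/right
with zeros and enumerates windows row-major; non-overlapping 512-px windows
by default, with an optional minimum-foreground filter plus a
background-keep probability replacing ocean-vector tile filtering.

Augmentation is train-only (requesting it for val/test raises): independent
horizontal/vertical flips at p = 0.5; one rotation drawn from
{90°, 180°, 270°} with probability 0.5; a crop/scale perturbation (factor
uniform in [0.75, 1.25], then random crop or zero-pad back) with
probability 0.5; multiplicative brightness and mean-anchored contrast
jitter, each a factor uniform in [0.9, 1.1], applied to the image only with
8-bit clamping. No saturation jitter, to preserve the relative spectral
relationship between algae and water. Geometric draws hit image and mask
identically; masks stay strictly binary. Rotation and crop/scale
probabilities and ranges are choices of this package (the recipe fixes only
the flip probability and the ±10% photometric range) and are configurable.

## Synthetic scenes

The generator emulates what matters statistically in coastal-zone imagery
of floating algae: water that is dark in NIR (mean reflectance 0.02) with a
smooth ripple field and additive Gaussian sensor noise; algae at elevated
NIR reflectance (mean 0.18, per-pixel gain jitter ±15%) shaped as curved
random-walk filaments of varying thickness and as small random ellipses;
weaker correlated algal signal in green/blue; and a turbidity-like blotch
field injected into the red band — the reason the red band is excluded from
the composite, so the band-selection logic is genuinely exercised. Shapes
are rendered without anti-aliasing, making the mask exactly the set of
rendered pixels. A `contrast` multiplier scales the algae–water NIR
separation; presets span `easy` (contrast 1.5, noise sd 0.004), `default`
(1.0, 0.010) and `hard` (0.35, 0.030, many small fragments), plus a 64-px
`smoke` preset for fast tests. On generated scenes the NIR step across the
mask boundary is verifiably smaller on `hard` than on `easy`.

Scene seeds are spawned from one master seed via `numpy.random.SeedSequence`,
so a dataset is a pure function of (parameters, master seed). Splits are
assigned per scene by largest-remainder apportionment — never per tile — so
tiles of one scene cannot leak across train/val/test.

What the generator does **not** model: radiative transfer, sun glint,
clouds, land, geolocation realism, inter-scene radiometric drift, or the
spatial autocorrelation of real bloom drift. Passing the directional
experiments on synthetic scenes therefore shows the architecture and
training loop behave as designed (boundary supervision measurably improves
contour metrics when boundaries are learnable), not that real-data accuracy
levels are reproduced.

## Training

AdamW with the published recipe values (base lr 6e-5, weight decay 0.01,
batch 8, 40,000 iterations at 512 px) as defaults; learning rate follows a
linear warmup (default 1,500 iterations from lr/10 — both values are this
package's choice, logged and configurable) into polynomial decay with
power 1. Validation runs every 10% of the iteration budget and the
best-mIoU state is retained. Divergence (non-finite loss) aborts with a
diagnostic. Mixed precision is off; compute is float32 end to end, and runs
are bit-reproducible for a fixed seed on one device.

The reduced CPU profile used by the tests and ablation helpers trains the
`micro` variant on 64-px tiles (batch 4, 200 iterations, lr 1e-3 with a
20-iteration warmup). The larger rate compensates for the short schedule at
this model size; it is part of the reduced profile, not of the reference
recipe. Study conditions for the directional experiment: eight easy-preset
128-px scenes split 4/2/2 by scene into train/val/test (16/8/8 tiles of
64 px), three repeats with seeds {0, 101, 202} shared across arms, the λ
grid {0, 0.1, 0.3, 0.5, 0.7, 1.0}. Under these conditions the full model
(ECA on stages {1,2} + boundary branch, λ = 0.5) beats the plain
no-ECA/no-boundary baseline on mean BF-score and mean Hausdorff distance,
and mean BF-score at every λ > 0 is at least the λ = 0 value.

Checkpoints are single `.npz` archives embedding the model config as JSON,
so evaluation rebuilds the exact graph; save → load → evaluate is
bit-for-bit reproducible.

## Numerical and design notes

- Nearest-odd rounding with ties upward and the floor at 3 are stated
  explicitly because the kernel rule is otherwise ambiguous at exact ties.
- Binarisation of predictions is argmax over the two segmentation channels;
  no threshold tuning.
- Coordinates are 0-based (row, col); tensors are described H×W×C at the
  API surface regardless of the internal NCHW layout.
- The ECA 1-D convolution slides over channels with zero padding, so edge
  channels see a truncated neighbourhood; this matches the minimal-parameter
  description and keeps output length C.
- `aggregate` excludes images with undefined HD rather than imputing, and
  reports how many were excluded.
- Known limitations: single-device training only; two classes only; no
  GFLOPs accounting; the pure-NumPy engine favours clarity and testability
  over speed, so GPU-scale (512-px, 40k-iteration) runs are out of its
  intended range.
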