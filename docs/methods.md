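# Methods

## The architecture family

All eight networks are symmetric encoder–decoder ("U-shaped") convolutional
networks for binary semantic segmentation. A *block* is a 3×3 same-padding
convolution, optionally followed by batch normalization, then ReLU. Each
contracting stage applies two blocks and a 2×2 max-pool; the bottleneck
applies two blocks; each expanding stage applies a 2×2 stride-2 transposed
convolution to the mirrored channel count, concatenates the matching encoder
feature map along channels (same-padding makes the resolutions line up with
no cropping), and applies two blocks. The head is a 1×1 convolution with a
sigmoid, so outputs are per-pixel foreground probabilities in (0, 1). An
input of height/width divisible by 2^levels maps to an output of identical
spatial size; anything else raises a geometry error rather than silently
cropping.

The family members:

| name     | encoder levels | width mode | filters          | layer count |
|----------|----------------|------------|------------------|-------------|
| U-Net7   | 3              | doubling   | 64→128→256 (b 512) | 7         |
| U-Net9   | 4              | doubling   | 32→…→256 (b 512) | 9           |
| U-Net11  | 5              | doubling   | 16→…→256 (b 512) | 11          |
| U-Net13  | 6              | doubling   | 8→…→256 (b 512)  | 13          |
| U-Net16/32/64/128 | 4     | fixed      | 16/32/64/128 everywhere | 9    |

"Layer count" is the stage convention `2·levels + 1` (encoder stages +
bottleneck + decoder stages).

### Reference configuration choices

- **Batch normalization off by default.** The reference per-variant
  parameter totals for U-Net7/16/32/64/128 are reproduced *exactly* by
  BN-free blocks; BN is an opt-in flag (`use_batchnorm`, ε default 1e-5).
  When enabled, the audit counts γ, β and the running mean/variance —
  4 scalars per normalized channel.
- **Depth-variant initial filters 64/32/16/8.** The alternative assignment
  128/64/32/16 is inconsistent with the reference totals (and with the
  9-layer model starting at 32 filters); shifting the column by one
  reproduces the U-Net7 total exactly, so the count-consistent assignment
  is used.
- **Grayscale in, single sigmoid channel out** (binary task trained with
  binary cross-entropy), 2×2 transposed convolutions with bias, skip merging
  by concatenation — all confirmed by the parameter-count arithmetic.
- **Initialization**: He-uniform for all convolution weights, zeros for
  biases, from a seeded `numpy.random.Generator`; building twice with one
  seed gives identical weights.

Three reported totals (the 9/11/13-layer variants: 7,778,017 / 7,781,761 /
7,945,457) are *not* reproduced by this reconstruction — the natural layout
that matches the other five exactly differs here (e.g. by 18,496 for the
9-layer net), and no described structure accounts for the difference. Those
three numbers are flagged and excluded from the audit suite.

### Parameter audit

Two independent routes must agree for every spec: (1) the built network's
count — the summed sizes of all weight/bias arrays (plus BN buffers); and
(2) a closed-form arithmetic sum of `c_in·c_out·k² + c_out` over the stage
layout. `build_unet` asserts their equality at construction time, and the
test suite checks it across randomly sampled specs (levels 1–4, both width
modes, filters 1–16, BN on/off).

## Numerical core

No deep-learning framework is used: convolutions are im2col + BLAS matmul in
float32, the transposed convolution exploits stride = kernel (no output
overlap) and reduces to an einsum, max-pooling backpropagates through the
argmax, and batch normalization uses the standard batch-statistics backward
pass. Binary cross-entropy is computed from logits in the stable
`max(z,0) − z·y + log(1+e^−|z|)` form; Adam uses β₁ 0.9, β₂ 0.999, ε 1e-8.
Backpropagation is validated against central finite differences on a tiny
network; in float32 with ReLU kinks the comparison has a noisy tail, so the
test constrains the median and 90th-percentile relative error rather than
the maximum.

## Preprocessing

Order is resize → Gaussian denoise → intensity normalization; masks are
resized nearest-neighbor and re-binarized (threshold 0.5 of the value range)
so they stay strictly {0, 1}.

- **Resize**: bilinear for images, nearest for masks.
- **Gaussian denoise**: explicit discretized kernel
  `exp(−(i²+j²)/(2σ²))`, sum-normalized, default 3×3 with σ = 0.5; borders
  by edge replication. A constant image is a fixed point; σ → 0 approaches
  the identity.
- **Normalization**: histogram equalization via the exact empirical CDF
  (each pixel maps to the fraction of pixels at or below its value),
  followed by min-max scaling to [0, 1]. The exact-CDF form is chosen over
  256-bin interpolated equalization because it is provably idempotent —
  applying it twice is a no-op — and coincides with the binned form on
  8-bit input, which is what the PNG datasets contain. CLAHE is available
  behind a function but is not the default. Constant images pass through as
  zeros with a logged warning.

## Metrics

IoU = TP/(TP+FN+FP), Dice = 2TP/((TP+FN)+(TP+FP)), computed from exact
pixel tallies. Dice = 2·IoU/(1+IoU) identically, hence Dice ≥ IoU with
equality only at 0 and 1 — any table violating this row-wise has swapped
columns, which is why reports here label metrics by formula. When both
masks are empty the 0/0 case is defined as 1.0 (agreement on absence) with
a warning. Sigmoid outputs are thresholded at 0.5 before scoring. Dataset
aggregation is reported both micro (pool counts, then apply the formula)
and macro (mean of per-image values), since either convention is defensible
and they differ on heterogeneous images.

## Synthetic phantoms

Each phantom is a bright background (default intensity 0.80) with two
darker (contrast 0.45), vertically elongated (eccentricity 1.8) elliptical
lung fields whose horizontal semi-axes are drawn uniformly from 10–16 % of
image width, plus optional sinusoidal rib stripes (6 periods, amplitude
0.04) and additive Gaussian noise (σ 0.04), clipped to [0, 1]. The mask is
the exact ellipse-union indicator. With these defaults the foreground
fraction stays within [0.05, 0.6] by construction (checked empirically over
1,000 seeds in the tests). Centers are jittered but constrained so the two
fields are always disjoint and inside the frame; parameter choices that
cannot satisfy that raise an error. Per-item seeds are derived from the
master seed and the item index (`SeedSequence(master, spawn_key=(i,))`), so
item *i* is identical regardless of dataset size, and the generator never
touches global random state.

What the phantoms do *not* emulate: real anatomical shape variation,
pathology (consolidations, effusions), scanner characteristics, or
inter-annotator mask noise. Passing the phantom suite shows the pipeline is
wired correctly and the architectures can learn an easy figure/ground task;
it says nothing about clinical segmentation accuracy.

## Experiment harness

The full-scale protocol is the reference setup: 256×256 inputs, 10 epochs,
batch size 20, Adam at 1e-4, binary cross-entropy, 80/20 split. The split
takes `floor(0.8·n)` training items from a seeded shuffle — 3,886 items
split 3,108/778 — stratified by class by default (the floor rule applied
inside each class), with disjointness asserted in every report. There is no
validation split or early stopping: the protocol trains a fixed number of
epochs.

The **easy suite** used by the automated quality gate scales this to desk
size: 200 noise-free, rib-free, high-contrast phantoms at 64×64, 5 epochs,
seed 0, Adam at 1e-3 with batch size 10, training the two cheapest width
variants (16 and 32 filters). The raised learning rate and smaller batch
are part of the small-scale protocol by design: ~100 optimizer steps at the
full-scale 1e-4 cannot move a freshly initialized network appreciably,
whereas 1e-3 is the textbook Adam rate for small models. Under this
protocol both variants reach test micro-Dice ≥ 0.99 (gate at ≥ 0.90).

Wall-clock training time is recorded in the parameter table but marked
informational; it is hardware-dependent and never compared against
anything.

## Known limitations

- Published headline Dice/IoU on the radiograph dataset are out of reach at
  desk scale (external data, GPU-length training) and are not claimed; the
  phantom suite substitutes a property-based gate.
- The numpy training loop is single-threaded BLAS-bound; it is meant for
  correctness and small benchmarks, not production training speed.
- Only binary (single-channel) heads; no attention/residual/nested
  variants; no DICOM ingestion, lung-field cropping or bone suppression.
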