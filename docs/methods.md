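# Methods

## Problem and model

The package segments retinal blood vessels in fundus photographs: every
pixel inside the camera's circular field of view (FOV) is classified as
vessel or background. The segmenter is a four-stage encoder–decoder
convolutional network with three specific mechanisms:

**Gated skip-connections.** A plain U-Net skip copies the encoder
feature `E_t` into the decoder unchanged, noise included. Here the skip
is modulated by an attention map computed from both sides of the
bridge:

    alpha_t = sigmoid( Conv1x1( concat(E_t, D_t) ) )
    Y_t     = concat( E_t ⊙ alpha_t + E_t , D_t )

where `D_t` is the upsampled decoder feature at the same resolution,
`⊙` is the elementwise product, and the Conv1x1 emits one gate channel
per encoder channel. The additive `+ E_t` term is a residual
skip-connection around the gate: the gate can only *emphasize* encoder
content (the effective per-channel factor is `1 + alpha_t ∈ (1, 2)`),
and gradient flow to the encoder never vanishes even where the gate
saturates. Every entry of `alpha_t` lies strictly in (0, 1).

**Adaptive (sub-pixel) upsampling.** Each decoder stage doubles the
spatial size by a learned channel expansion followed by a
parameter-free periodic rearrangement: a bias-free 3x3 convolution
emits `r² · C_out` channels, and each group of `r²` channels is
rearranged into an `r x r` subwindow of the output,

    out[c, y, x] = mid[c·r² + (y mod r)·r + (x mod r), y div r, x div r]

(row-major depth-to-space layout). The rearrangement is exactly
invertible and adds zero parameters; all learning lives in the
preceding convolution. With one upsampling per decoder stage, `r = 2`
throughout; the rearrangement supports any `r` for single-shot
upsampling experiments.

**Multiscale inputs.** The input image is bilinearly downscaled to
1/2, 1/4 and 1/8 resolution, embedded by a 3x3 convolution
(`base_width` channels), and concatenated into the matching encoder
stage before that stage's convolution block, so every scale of the
image is seen directly rather than only through strided convolutions.

Each convolution block is two 3x3 convolutions, each followed by batch
normalization, with a single ReLU closing the block
(conv–norm–conv–norm–relu; the conventional conv–norm–relu pairing is
available via `norm_order="each"`). Downsampling uses a stride-2 3x3
convolution instead of pooling. The head is a 1x1 convolution to one
channel plus a sigmoid, trained with pixelwise binary cross-entropy —
so predictions are per-pixel vessel probabilities.

### Ablation variants

The upsampling mechanism and the gate are both switchable, giving six
variants (3 upsampling modes x gated/plain skip):

* `bilinear`: corner-aligned x2 bilinear resize + 1x1 convolution —
  the data-independent baseline and the smallest model;
* `adaptive`: the sub-pixel mechanism above (bias-free 3x3 expansion);
* `deconv`: a 6x6 stride-2 padding-2 transposed convolution with bias.

The deconv kernel size is chosen so the learned footprint matches the
adaptive stage exactly (both apply 3x3-per-output-pixel taps: 36
`C_in·C_out` weights per stage); deconv then carries one extra bias
vector per stage. Consequently the parameter totals order as
`bilinear < adaptive ≤ deconv` at fixed widths — the comparison
isolates the upsampling *mechanism* rather than capacity.

### Reading of the gate equation

The gated-skip output is stated in the literature as a sum of the
gated product, the encoder feature, and a concatenation with the
decoder feature, which is shape-inconsistent if the sum ranges over
the concatenation. The only shape-consistent composition that keeps
both the "skip-connection" (add `E_t`) and the "channelwise
concatenation" (join `D_t`) is `concat(E⊙alpha + E, D)`, which is what
this package implements. Similarly, the gate's 1x1 convolution emits
`channels(E)` gate channels (a per-channel gate) because a 1-channel
broadcast gate would need a broadcast rule the operator definition
never states.

### Bias placement

Convolutions feeding directly into batch normalization are bias-free:
BN subtracts the per-channel mean, so such a bias receives an exactly
zero gradient and can never train. This was confirmed with float64
finite-difference checks and is the standard conv+BN convention.
Stride-2 downsampling convolutions, gate convolutions, the multiscale
embeddings and the head keep their biases.

## Training protocol

Training samples random 48x48 patches from the training images —
centers uniform over positions whose patch fits the image, restricted
to the FOV — with the benchmark-scale default of 10,480 patches per
image. Optimization is Adam (beta1 = 0.9, beta2 at its conventional
0.999) with L2 weight decay 5e-4, initial learning rate 1e-3, and a
step-decay schedule multiplying the rate by (1 − 0.01) each epoch (the
interval is configurable; the decay coefficient 0.01 is interpreted as
the per-step multiplicative drop since "step decay" fixes only the
shape of the schedule, not its interval). The loss is pixel-averaged
binary cross-entropy with predictions clipped to [1e-7, 1 − 1e-7]. The
benchmark-scale profile (200 epochs, batch 256) ships in
`configs/benchmark.yaml`; the desk-scale profile used by the tests and the
reproduction script is in `configs/desk.yaml`.

Full images are segmented by overlapping 48x48 tiles (stride 24,
reflect padding) whose probabilities are averaged per pixel by overlap
count. The tiling procedure is this package's addition: a patch-trained
fully-convolutional net defines no canonical full-image procedure, and
overlap averaging suppresses tile-border artifacts.

## Evaluation

Confusion counts (TP/FP/TN/FN) are tallied over FOV pixels only, with
the probability map binarized at 0.5. Accuracy, sensitivity,
specificity, precision and F-measure follow the standard confusion
formulas; any ratio with a zero denominator is reported as NaN and
flagged, never silently zeroed. ROC and precision–recall curves sweep
all score thresholds with trapezoidal areas; the ROC area is checked in
the tests against the exact all-pairs rank statistic (probability a
random vessel pixel outscores a random background pixel, ties counted
half). FOV restriction is the default (and the convention for these
benchmarks); `--no-fov-restrict` disables it. Multi-image results are
unweighted means over images, which is also the leave-one-out
averaging rule.

## Synthetic phantoms

Real fundus datasets cannot be redistributed, and benchmark-scale
training is a GPU-days workload, so the package ships a procedural
phantom generator used by the tests and the reproduction script. Each
phantom is: vessel trees drawn as branching, tapering, tortuous random
walks radiating from an off-center root (emulating the optic disc),
rendered dark on a brighter background (fundus green-channel
appearance); a smooth illumination field (tilted plane plus
low-frequency blobs); additive Gaussian noise; and a circular FOV
with a dark exterior. Default geometry is 565x584 (the 40-image
benchmark's size), with ~5–11% of FOV pixels being vessel — matching
the vessel density of real annotated fundus images. Branch widths start
at 3–6 px and taper to 1 px, so thin-vessel cases are always present.

What the phantoms do *not* model: pathology (lesions, exudates,
hemorrhages), the optic disc and macula as intensity structures,
texture of the retinal surface, vessel central reflex, and
inter-annotator ambiguity. Passing the desk-scale checks therefore
shows that the implementation learns and segments curvilinear
dark-on-bright structure end to end — it does not certify benchmark
accuracy on real fundus images.

## Desk-scale problem sizes

The tests and `scripts/acceptance.py` exercise the pipeline at sizes a
single CPU handles in minutes, chosen once as the smallest
configuration where training visibly converges and evaluation is
stable:

* learning check: `base_width` 16, 10 training phantoms of 128x128,
  200 patches each, 2 epochs at batch 32, 3 held-out phantoms;
* variant comparison (gated/adaptive vs ungated/bilinear): 5 seeds of
  a shortened run — 6 training phantoms, 100 patches each, 2 epochs at
  batch 16 — scored by mean F-measure on 3 held-out phantoms. Two
  epochs is the shortest run at this scale whose probability maps are
  properly calibrated (one epoch leaves the batch-norm running
  statistics so far from the final weights that the fixed 0.5
  threshold misreads otherwise good rankings); it also keeps the
  comparison in the partially-converged regime where the mechanisms
  actually differ, rather than letting both variants saturate on an
  easy synthetic task.

## Numerical choices

* Engine precision is float32; `vesselseg.nn.core.set_dtype` switches
  to float64, which the gradient-check tests use.
* Bilinear resampling is corner-aligned (first/last samples map to
  first/last); every output pixel is a convex combination of its four
  nearest source pixels. The same convention is used for multiscale
  encoder inputs and the bilinear decoder stage.
* Weight init is He-normal scaled by fan-in, seeded per network from
  `NetworkConfig.seed`; BN starts at gamma = 1, beta = 0 with running
  stats (0, 1) and momentum 0.1.
* Labels are binarized at the 8-bit midpoint (127.5) when read from
  disk, tolerating lossy-format artifacts in manual annotations.
* Datasets without FOV masks get a luminance-threshold estimate
  (threshold 0.08, largest connected component, holes filled), and the
  record is flagged `fov_estimated`.
* Single-seed runs are bit-reproducible on one machine: all randomness
  flows through seeded NumPy generators, and per-item seeds are derived
  arithmetically (no global state).

## Known limitations

* CPU-only: the engine is vectorized NumPy + BLAS; benchmark-scale
  training (200 epochs x 10,480 patches x 20 images) is out of reach —
  desk-scale runs are the supported regime.
* No augmentation beyond random patch location, matching the training
  protocol it implements.
* The exact per-stage channel widths of the original ablation models
  are not public; parameter-count comparisons are meaningful as an
  ordering, not as absolute sizes.
* `eval`-mode batch statistics come from training-set running averages;
  very short runs can leave them noisy, which slightly blurs the
  probability maps near saturated activations.
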