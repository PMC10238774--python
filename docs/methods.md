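# Methods

`qcsanet` implements a quaternion channel-spatial attention network (QCSA)
for binary classification of chest-X-ray-like images, together with the
quaternion algebra, layers, data pipeline and evaluation harness it rests
on. This note documents the model, the numerical choices, the synthetic
data world, and the experiment designs the package ships.

## Quaternion representation and layers

A quaternion `Q = r + xi + yj + zk` is stored as four reals in the fixed
order `(r, x, y, z)`; feature maps are real NCHW arrays whose channel axis
is grouped in contiguous quadruples, so a map with `C_q` quaternion
channels has `4 C_q` real channels. Images enter the quaternion domain as
pure quaternions: an RGB pixel becomes `(0, R, G, B)`; a grayscale pixel
`g` becomes `(0, g, g, g)`.

The workhorse layer is the Hamilton-product convolution. Each kernel tap
is one quaternion weight `w`, and the tap's contribution is the Hamilton
product `w ⊗ q` with the input quaternion. Because the product couples all
four components of `w` with all four components of `q`, the layer is
exactly an ordinary real convolution whose per-pair 4×4 block is

```
[[ r, -x, -y, -z],
 [ x,  r, -z,  y],
 [ y,  z,  r, -x],
 [ z, -y,  x,  r]]
```

i.e. 4 free parameters standing in for the 16 of an unconstrained real
block — the 4× parameter sharing that motivates quaternion networks. The
implementation expands the quaternion weight into this structured real
kernel and runs an im2col + GEMM convolution; the expansion is part of the
autodiff tape, so gradients flow back to the four components with the
correct signs. A brute-force per-window Hamilton-sum oracle (double
precision) verifies the layer to < 1e-5 across random shapes in the test
suite.

A second convolution variant performs scaling/rotation per tap: with the
weight in polar form `w = s (cos(θ/2) + μ sin(θ/2))`, the tap computes the
scaled sandwich product `(1/s) w q w̄`, which rotates the pure part of `q`
and rescales it by `s`. Pure inputs stay pure and per-tap norms scale by
exactly `s`. This variant is provided as a verified forward operation (its
index conventions and the interaction of the `1/s` factor with learning
are under-determined), while the trainable model uses the Hamilton
variant throughout.

Nonlinearities and normalisation are *split* (component-wise): ReLU acts
elementwise and batch normalisation normalises each real channel
independently. These are the simplest choices that respect the layer
algebra; whitening-based quaternion normalisation is out of scope.

Weight initialization offers two seeded schemes. `quaternion-polar` draws
a magnitude from a Rayleigh law with `σ² = 1/(2 fan_in)` (real fan-in), a
phase uniform in `(-π, π]` and an axis uniform on the unit sphere, giving
closed-form component variances `σ²` (real part) and `σ²/3` (imaginary
parts); `component-glorot` draws each component Glorot-uniform on the real
fans. The sampled variances are verified against these closed forms at
10⁵ draws.

## Attention

Each residual block ends in a channel-then-spatial gating pair.

*Channel attention* average-pools and max-pools the map over space to two
per-channel descriptors, passes both through one shared two-layer
bottleneck MLP (reduction ratio `r`, no biases), sums and applies a
sigmoid. *Spatial attention* mean- and max-pools along the channel axis,
stacks the two H×W maps and convolves them with a single k×k filter
(2→1 channels) before the sigmoid.

Default granularity is per-quaternion-channel: the four components of a
quaternion channel always share one gate, so gating never splits a
quaternion. Defaults are `r = 8` and `k = 7` (the miniature preset uses
`r = 2` so the ratio divides its narrow widths).

Both modules also exist in a parameter-free variant — standardised
descriptors summed under the sigmoid for the channel gate, a fixed uniform
positive kernel for the spatial gate — which adds exactly zero parameters
(trainable or otherwise). Both variants are first-class because the
original description is ambiguous on whether its attention carried
parameters (it reports identical parameter counts with and without
attention while also describing a convolution inside the spatial gate).

A generic soft-attention primitive (`softmax_attention`) computes
`α_i = exp(h_i·v)/Σ_j exp(h_j·v)` with max-subtraction and the context
`O = Σ α_i h_i`.

## Architecture

The classifier is a stem Hamilton convolution followed by four residual
blocks (conv–BN–ReLU–conv–BN → attention → skip-add → ReLU, with a 1×1
quaternion projection on the skip when widths or strides change), global
average pooling, and a real sigmoid head. Blocks 2–4 downsample 2× by
stride. Residual-block convolutions carry no bias: batch-norm's mean
subtraction would cancel a bias exactly, leaving dead parameters.

Block widths are configurable; the published architecture's exact widths,
downsampling schedule and head are not recoverable from its description
(its printed 569,345/560,769 parameter counts are explicitly not a
target). The package default is (8, 16, 32, 64) quaternion channels; the
`miniature` preset (2, 4, 4, 8) at 50×50 input is the configuration used
by the shipped experiments, sized so training is comfortable on one CPU
core. The head default flattens the pooled quaternion features into real
features; a `quaternion-norm` head (per-quaternion magnitudes) is
available.

Binary head and loss: one sigmoid unit with binary cross-entropy,
threshold 0.5. Positive class is pneumonia (label 1).

## Training

Defaults follow the stated hyper-parameters: Adam, learning rate 0.001,
decay 1e-6 (read classically as the per-step schedule
`lr_t = lr/(1 + decay·t)`), batch size 16, 40 epochs, stride (1,1),
50×50 input. Mini-batches are reshuffled each epoch from the seed; the
best-validation-loss parameter snapshot is restored after the final epoch.
Optional class weights `w_l = N/(2 N_l)` implement cost-sensitive
balancing; seeded minority oversampling is the alternative.

Everything is differentiated by a small reverse-mode autodiff engine
written for this package (NumPy arrays, tape of closures, im2col
convolution with analytic backward). Every backward rule is checked
against central finite differences; the end-to-end network gradient is
checked at 1e-3 relative tolerance on an 8×8 configuration, layers at
1e-4. Layers run in single precision; the algebra core and all test
oracles run in double precision.

## Synthetic data world

The generator emulates the directory convention of the public pneumonia
CXR collection (`<root>/{train,val,test}/{NORMAL,PNEUMONIA}/*.png`) and
its radiological cue: NORMAL images are a dark field (0.12) with two
brighter elliptical lung regions (≈0.35, ±10% per-image brightness
jitter) plus Gaussian pixel noise (sd 0.05); PNEUMONIA images add 2–6
bright Gaussian blobs (peak ≈0.5 above background, σ between 2% and 5% of
the image side) centred inside the lung fields. Classes differ only by
the blobs. The defaults make the task winnable but not trivial: a
max-intensity threshold alone separates a default set at ≥95%, which the
suite asserts, and the learning experiments must still localise blobs
under noise.

What the generator does *not* emulate: anatomical variability, ribs and
mediastinum, scanner artefacts, label noise, and the long-tailed opacity
morphology of real pneumonia. Passing the learning criteria therefore
shows that the architecture, gradients and training loop work and that
attention helps on a localisation-flavoured task at desk scale — it says
nothing about clinical performance, and the published real-data accuracies
are explicitly out of scope.

Splitting is stratified by label at fractions (0.75, 0.05, 0.20) with
overall sizes `round`, `floor`, remainder — 5856 images yield exactly
4392/292/1172 — with per-class rounding slack reconciled so totals are
exact (per-class counts can differ by ±1 from independent rounding).

## Shipped experiments

Two canonical experiments live in `qcsanet.experiments` and are run by
both the acceptance script and the test suite:

* **Learning experiment** — miniature QCSA, 200 training and 50 test
  images per class at 50×50, 10 epochs, 10% validation holdout
  (~1.5 min on one CPU core). Expectation: ≥90% test accuracy.
* **Attention comparison** — ten seeded repetitions; each draws fresh
  data, trains the attention network and its attention-free twin from the
  same seed and hyper-parameters, and compares test F1 (ties count for
  attention, an undefined F1 from a positive-free prediction ranks as 0).
  Repetitions run at 32×32 with 150 training / 40 test images per class
  and 10 epochs — the same blob and noise conditions, sized so ten full
  repetitions (~7 min) remain affordable; a smaller design (60 per class,
  3 epochs) was rejected because neither architecture converges there.

## Numerical and degenerate-input conventions

* Polar form of a real quaternion: θ = 0 (π for negative reals) and axis
  `i` by convention; the zero quaternion has no polar form or inverse
  (errors, never NaN).
* `rotate_vector` rejects non-unit axes; `normalize_axis` is the explicit
  helper.
* Metric ratios with zero denominators are NaN with a warning, never
  silently 0; AUC is the Mann–Whitney rank statistic with ties counted
  half; kappa is `(p_o − p_e)/(1 − p_e)` from the confusion counts.
* Tie-break in channel max-pooling gradients: first arg-max.
* The capacity check (memorising 16 images in ≤200 steps) runs at 16×16
  input with narrow widths; it is a sanity check of optimisation, not an
  experiment.

## Known limitations

The rotation/scaling convolution is inference-only. Batch normalisation
uses per-component statistics rather than quaternion whitening. The
attention comparison is a desk-scale echo of the published 4-point
accuracy rise, not a reproduction of it. Training is CPU-bound NumPy;
wall-clock scales roughly linearly in pixels × channels × batch.
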