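# Methods

## The decorrelation statistic

The penalty is the squared **distance correlation** between a bias
variable `B` (n × d_b) and tapped network features `F` (n × d_f), computed
as the biased V-statistic: pairwise Euclidean distance matrices are
double-centered (`A_jk = d_jk − rowmean_j − colmean_k + grandmean`) and

    V²(B, F) = (1/n²) Σ_jk A_jk A'_jk,
    DC²(B, F) = V²(B, F) / sqrt(V²(B,B) · V²(F,F))

with a zero branch when the denominator product falls below `eps = 1e-12`
(this covers constant arguments exactly) and clamping to [0, 1] against
float drift.  The unbiased U-statistic estimator is deliberately not used:
the zero branch and the [0, 1] normalization are properties of the
V-statistic form.

**Sample weights.**  The weighted variant replaces every empirical mean in
the centering and the summation by a `w`-weighted mean — i.e. it is the
V-statistic of the weighted empirical distribution.  This is the unique
choice for which an integer weight is exactly equivalent to duplicating a
sample, and uniform weights reduce exactly to the unweighted statistic.
It implements the per-scanner control weighting of the scanner objective.

**Differentiability.**  `dcor_penalty` expresses the same computation on
autodiff tensors.  Gradients flow through `F` only; `B` is a constant
input and never trained.  Two numerical choices:

* the sqrt in the feature distance matrix uses the exact forward value but
  clamps its derivative at `0.5/1e-3` — after random oversampling a batch
  routinely contains duplicated rows whose pairwise distance is 0, where
  the true derivative is unbounded;
* the penalty requires at least 8 samples (`PENALTY_MIN_BATCH`); smaller
  batches make the V-statistic useless as a training signal, so the
  objectives set the term to 0 and flag the skip in the loss breakdown.

The analysis API and the penalty agree to ~1e-12, so the logged DC² per
iteration equals the statistic recomputed offline on the same batch.

## Objectives

* Class bias: `L_WCE + λ·DC²(B, F) + c‖θ‖²`.  `L_WCE` is the mean of
  `−w_{y_i}·log p_i(y_i)` with probabilities clipped at 1e-7.
* Scanner bias: `λ₁·L_CE + λ₂·DC²_control(B, F) + c‖θ‖²`, the penalty on
  control samples only, weighted by inverse scanner frequency among
  training controls (normalized to mean 1) so both scanners are
  decorrelated equally despite the control imbalance.
* `‖θ‖²` sums squared convolution and dense weights; bias vectors and
  normalization parameters are excluded (standard practice).
* With `λ = 0` (or `λ₂ = 0`, or a constant bias variable) the penalty
  branch contributes nothing and training is bitwise identical to the
  unpenalised baseline — asserted in the tests.

## Bias variables

* **Dummy class code** — each sample draws an integer uniform on
  `{0..width−1}` with `width = 10` for the majority class and `2` for the
  minority (the published account states only that the majority support is
  wider; the widths are config knobs).  The draw's variance depends on the
  class, so it carries exactly the class-prior signal the penalty removes.
  Redrawn every epoch from a derived seed.  On oversampled data the class
  counts are tied, so the original majority class must be named explicitly.
* **Voxel size** — (slice thickness, pixel spacing x, y) in mm from the
  manifest, standardized with training-split statistics (avoids the
  penalty being dominated by unit scale); constant on single-scanner data,
  where the zero branch then makes the penalty vanish.
* **Scanner-classifier (FE) features** — flattened last-conv-block
  activations of a scanner-classification model trained on controls,
  frozen.
* **Temporal standard deviation** — per-pixel population (1/T) std over
  the frame axis, average-pooled (default factor 4) to keep the distance
  computation cheap.

## Architectures

Five named variants (conv(3×3, same) → ReLU → batch-norm → max-pool(2×2)
blocks; two fully connected layers; softmax head), with the published
filter/neuron counts: class-bias model 32/64/128; scanner model 32/16/16
with FC 40/100; FE and FE-DcCNN 32/16/16/8/8 with FC 40/100 and dropout
0.2 on the first four blocks; ConvGRU model with a convolutional GRU front
end then 16/32/32 and FC 1000/500.  Kernel and pooling sizes are not
published; 3×3 / 2×2 stride-2 are the defaults and configurable.  The FC
widths of the class-bias variant are likewise unpublished; 64/32 is this
package's default.  Feature taps default to fc1/fc2/softmax (class-bias),
conv1/fc1/fc2 (scanner), conv5/fc1/fc2 (FE-DcCNN), conv2/fc1 (ConvGRU);
the softmax tap uses probabilities, and conv taps record the post-block
(pooled) activation.  The ConvGRU summarises the frame sequence into its
final hidden state before the conv stack (temporal processing first).
Input sizes generalize from the published 66×66 to any (H, W).

All layers run on a ~500-line numpy reverse-mode autodiff core written for
this package (conv2d via im2col, scatter-add col2im backward, argmax-mask
pooling backward, batch-norm composed from primitives).  Float64
throughout, so training is bitwise reproducible for a fixed seed.

**Precise-BN recalibration.**  Batch-norm running statistics collected as
an EMA lag the weights they were estimated under, which badly
miscalibrates inference on small training runs (we observed specificity
differences of 30+ points between batch-statistics and EMA inference).
Before each validation pass the running statistics are therefore
recomputed as a uniform average over training batches with the current
weights.

## Training protocol

RMSProp (or Adam), minibatches, an exponential-cyclical learning-rate
policy (triangular cycle with amplitude decaying by `gamma^iteration`) or
step decay; per-iteration logging of every loss term including the
evaluated DC²; checkpoint selection on a validation cohort; the
published uncertainty protocol of three seeded retrainings summarised as
mean ± t-based 95% interval (`t = 4.303` at n = 3).

Checkpoint metric: `TrainConfig` defaults to validation balanced accuracy.
The prebuilt suites select on validation **min(sensitivity, specificity)**
instead, applied to every method equally: at desk scale the best-BA
checkpoint frequently sits at a strongly unbalanced operating point
(e.g. 25% sensitivity / 92% specificity), which defeats the balance
analysis the suites exist to measure.

## Synthetic fixtures

The generator renders an elliptical brain phantom per subject with a
smooth random texture field (slices of one subject share it — the reason
splits are grouped by subject), an optional Gaussian-blob **class effect**
(amplitude and location configurable, off-switchable for null fixtures),
and a **scanner transform**: per-profile Gaussian smoothing, gain, sensor
noise, temporal per-frame noise, plus the profile's voxel metadata in the
manifest.  The two default profiles carry the acquisition geometry of the
emulated cohorts (3.2999/3.2941 mm vs 3.0/2.5 mm; temporal noise 0.05 vs
0.15).  Cohort layouts: single-scanner with 9:1 patient:control subject
imbalance, and two-scanner with patients on scanner A only and controls
1:9 between A and B (patients on both scanners require an explicit
override — the confounded layout is the design under study).

What the fixtures do **not** emulate: BOLD physiology, motion artifacts,
registration error, site effects beyond the scanner transform, and the
~10⁶-image scale of the real collections.  Passing suites therefore
demonstrate that the objectives remove the modelled biases under the
modelled acquisition differences, not clinical-grade performance.

## The desk-scale studies (`experiments.py`)

Both suites run at 32×32 with a narrowed conv stack (8/16/16; FC 32/16 or
40/16), three seeded retrainings per method, on one CPU core in minutes.

**Class-bias suite.**  Training cohort 135 patients / 15 controls
(~9:1), 5 slices each; separate class-balanced validation (30+30) and
held-out (50+50) cohorts; blob amplitude 0.16, texture 0.12, noise 0.12.
Methods: plain CNN, random oversampling, SMOTE on slice images,
stratified resampling, oversampling + weighted loss, and the fusion
pipeline (oversampling + weighted CE + decorrelation with λ = 1.0,
trained with the augmentation protocol — random rotation ±10°,
translation ±3 px, elastic deformation — and a longer 50-epoch anneal;
both are part of the proposed method's training recipe, while the
classical baselines are the existing techniques as-is at 18 epochs,
which longer training does not improve).  After oversampling the class counts are equal, so the
inverse-frequency weights are unity and "oversampling + weighted loss"
coincides with plain oversampling.  Metrics are subject-level via max-wins
voting (ties broken by mean positive probability).  λ = 1.0 was selected
on validation cohorts for this fixture/architecture, consistent with the
published guidance that the penalty weight must be tuned per model and
task.  The logged DC² trajectory rises from the finite-batch
independence floor (~0.05 at batch 256) as features organize, peaks, and
is then driven below the floor by the penalty as the learning rate
anneals — the decreasing trend visible over the bulk of training.

**Scanner-bias suite.**  Training cohort: 40 patients on scanner A, 4 + 36
controls on A/B; held-out cohorts class-balanced (patients still A-only —
the design's constraint); blob amplitude 0.16; λ₁ = 0.5, λ₂ = 7.5 (tuned
for this fixture; the published scanner model uses 5.0 at full scale),
voxel-size bias variable, taps fc1/fc2.  The audit is a logistic-regression
probe on frozen fc features of held-out controls with a subject-grouped
70/30 split — it measures scanner information in the features without
capacity confounds; per-scanner subject error rates and the scanner-null
control (identical profiles, probe at chance) complete the picture.

## Known limitations

* The numpy core is single-threaded; the published image and batch sizes
  (66×66, minibatch 4000, ~10⁶ slices) are config-reachable but not
  practical on one core.
* No early stopping; epoch counts are fixed per suite.
* The scanner-probe audit uses a linear probe; a nonlinear probe could
  find residual scanner information the linear one misses.
* Subject-level metrics on desk-scale cohorts are means over three runs
  but still carry binomial noise of a few percentage points.
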