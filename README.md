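# decorrnet

Decorrelated convolutional networks for neuroimaging slice classification:
a distance-correlation penalty that removes **class bias** (majority-class
collapse on imbalanced cohorts) and **scanner bias** (acquisition
differences that classifiers exploit as shortcuts) from learned features.

## Who this is for

Researchers training slice-level CNN classifiers on structural or
functional MRI collections that are (a) heavily imbalanced between patient
and control groups, or (b) pooled across scanners with different
acquisition protocols, and who need the classifier's decisions to reflect
biology rather than the class prior or the scanner signature.

## The method

For a minibatch with per-sample *bias variables* `B` (what we want the
model to ignore) and *features* `F` (flattened, concatenated activations
of chosen network layers — the "feature taps"), the squared distance
correlation

    DC²(B, F) = V²(B, F) / sqrt(V²(B, B) · V²(F, F))   ∈ [0, 1]

measures linear **and** nonlinear dependence between `B` and `F`
(`V²` is the double-centered V-statistic distance covariance; DC = 0 iff
independent in the population version).  It enters the training objective
as a differentiable penalty:

* **class bias** — `J(θ) = L_WCE + λ·DC²(B, F) + c‖θ‖²`, where `B` is a
  dummy variable drawn from a class-dependent discrete uniform
  distribution (wider support for the majority class), combined with
  random oversampling and class-weighted cross-entropy ("fusion");
* **scanner bias** — `J(θ) = λ₁·L_CE + λ₂·DC²_control(B, F) + c‖θ‖²`,
  where the penalty is evaluated on control subjects only (they appear on
  both scanners, so decorrelating them removes scanner information without
  erasing the disease signal), with per-scanner sample weights, and `B` is
  voxel-size metadata, frozen scanner-classifier features, or the temporal
  standard deviation of the frame sequence.

Everything runs on a small numpy reverse-mode autodiff core
(`decorrnet.autodiff` / `decorrnet.nn`) — conv/pool/batch-norm stacks,
fully connected layers, a convolutional GRU for temporal inputs — so no
deep-learning framework is required.

## Worked example

Train on a synthetic 9:1 imbalanced cohort and watch the plain CNN
collapse while the fusion objective balances both classes:

```python
from decorrnet.experiments import ClassBiasConfig, class_bias_suite

results = class_bias_suite(ClassBiasConfig(seed=0),
                           methods=("baseline", "ros", "fusion"))
for method, r in results.items():
    print(f"{method:9s} sens={r['sensitivity']:5.1f}%  "
          f"spec={r['specificity']:5.1f}%  BA={r['balanced_accuracy']:5.1f}%")
```

```
baseline  sens= 98.7%  spec=  2.7%  BA= 50.7%
ros       sens= 62.0%  spec= 50.0%  BA= 56.0%
fusion    sens= 67.3%  spec= 72.7%  BA= 70.0%
```

The plain CNN predicts nearly everything as the majority (patient) class —
specificity 2.7%, balanced accuracy at chance.  Random oversampling (ros)
recovers some specificity; the fusion pipeline (oversampling + weighted
cross-entropy + decorrelation) balances sensitivity and specificity and
reaches the best balanced accuracy.  Metrics are subject-level (max-wins
voting over slices), means over three seeded retrainings.

The same pattern for scanner bias:

```python
from decorrnet.experiments import ScannerBiasConfig, scanner_bias_suite

res = scanner_bias_suite(ScannerBiasConfig(seed=0))
print("baseline probe:", res["baseline"]["scanner_probe_accuracy"])  # 98.9
print("DcCNN probe:   ", res["dccnn"]["scanner_probe_accuracy"])     # 76.1
print("DcCNN accuracy:", res["dccnn"]["class_accuracy"])             # 70.0
```

A linear probe on the baseline CNN's features identifies the scanner with
~99% accuracy (the features are a scanner shortcut); after control-only
decorrelation the probe drops by ~20 points while class accuracy stays
around 70% on a cohort where the null classifier scores 50%.

There is also a small CLI (`decorrnet simulate / train / evaluate /
probe / report`) for running the pipeline from a shell on PNG + manifest
datasets.

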