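"""Composite training objectives: cross-entropy + decorrelation + L2.

Two objectives are implemented, differing in where the decorrelation
penalty applies:

*class-bias* (imbalanced single-scanner data)::

    J(θ) = L_WCE(Y, Ŷ) + λ · DC²(B, F) + c·‖θ‖²

where L_WCE is class-weighted cross-entropy, B the dummy class-bias
variable and F the tapped features;

*scanner-bias* (multiscanner data)::

    J(θ) = λ1 · L(Y, Ŷ) + λ2 · DC²_control(B, F) + c·‖θ‖²

where the penalty is evaluated on *control* samples only — controls are
the subjects scanned on both scanners, so decorrelating their features
removes scanner information without erasing the disease signal — with
per-scanner sample weights compensating the control imbalance between
scanners.

Every objective returns the scalar loss (in the autodiff graph) plus a
per-term breakdown for logging; with λ = 0 (or λ2 = 0) the penalty branch
is never entered, so training reduces bitwise to the unpenalised baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dcor
from .autodiff import Tensor, gather_rows, log_softmax
from .models import FeatureTapSet, TapNet, features_from_acts

__all__ = [
    "ClassBiasObjectiveSpec", "ScannerObjectiveSpec",
    "weighted_cross_entropy", "class_bias_objective", "scanner_objective",
    "l2_penalty", "default_scanner_weights",
]

PROB_CLIP = 1e-7


@dataclass
class ClassBiasObjectiveSpec:
    lambda_dc: float = 0.2            # λ: weight of the decorrelation term
    class_weights: np.ndarray | None = None   # per-class, positive; None = 1
    l2_coeff: float = 0.0

    def __post_init__(self):
        if self.lambda_dc < 0 or self.l2_coeff < 0:
            raise ValueError("coefficients must be nonnegative")


@dataclass
class ScannerObjectiveSpec:
    lambda1: float = 0.5              # cross-entropy weight
    lambda2: float = 5.0              # decorrelation weight
    control_label: int = 0
    scanner_weights: dict = field(default_factory=dict)  # scanner id -> weight
    l2_coeff: float = 0.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.l2_coeff) < 0:
            raise ValueError("coefficients must be nonnegative")


def _check_labels(y: np.ndarray, n_classes: int):
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels outside 0..{n_classes - 1}: "
                         f"{sorted(set(y) - set(range(n_classes)))}")


def weighted_cross_entropy(y_true, y_pred, class_weights=None) -> float:
    """Mean over samples of −w_{y_i} · log p_i(y_i) (probabilities clipped)."""
    y = np.asarray(y_true, dtype=np.intp)
    p = np.asarray(y_pred, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("y_pred must be (n, n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    _check_labels(y, p.shape[1])
    w = np.ones(p.shape[1]) if class_weights is None else np.asarray(class_weights, float)
    picked = np.clip(p[np.arange(len(y)), y], PROB_CLIP, 1.0)
    return float(np.mean(-w[y] * np.log(picked)))


def _wce_tensor(logits: Tensor, y: np.ndarray, class_weights) -> Tensor:
    n, k = logits.shape
    _check_labels(y, k)
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    mask = np.zeros((n, k))
    mask[np.arange(n), y] = w[y] / n
    return -(Tensor(mask) * log_softmax(logits)).sum()


def l2_penalty(model: TapNet) -> Tensor:
    """Sum of squared trainable weights (bias/normalization params excluded)."""
    terms = [p.square().sum() for p in model.parameters() if p.decay]
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def default_scanner_weights(scanner_ids) -> dict:
    """Inverse-frequency weights over scanners, normalized to mean 1.

    Computed from the *training-split controls*: the penalty should pull
    features away from both scanners equally even when one scanner
    dominates the control group.
    """
    ids, counts = np.unique(np.asarray(scanner_ids), return_counts=True)
    if len(ids) == 0:
        raise ValueError("no scanner ids given")
    inv = 1.0 / counts
    inv = inv / inv.mean()
    return {i: float(v) for i, v in zip(ids.tolist(), inv)}


def class_bias_objective(batch: dict, model: TapNet,
                         spec: ClassBiasObjectiveSpec, B,
                         taps: FeatureTapSet | None = None):
    """Evaluate the class-bias objective on one minibatch.

    ``batch``: dict with ``x`` (n,H,W) and ``y`` (n,); ``B``: bias variable
    rows aligned with the batch.  Returns ``(loss, breakdown)`` where the
    breakdown maps term names to floats and flags a skipped penalty.
    """
    y = np.asarray(batch["y"], dtype=np.intp)
    logits, acts = model.forward(batch["x"])
    wce = _wce_tensor(logits, y, spec.class_weights)
    l2 = l2_penalty(model) * spec.l2_coeff
    breakdown = {"wce": float(wce.data), "l2": float(l2.data),
                 "dc2": 0.0, "dc_term": 0.0, "dc_skipped": False}
    loss = wce + l2
    if spec.lambda_dc > 0:
        n = len(y)
        if n < dcor.PENALTY_MIN_BATCH:
            breakdown["dc_skipped"] = True
        else:
            taps = taps or FeatureTapSet.default_for(model.spec.variant)
            F = features_from_acts(acts, taps)
            Bv = B.values if hasattr(B, "values") else np.asarray(B)
            if Bv.shape[0] != n:
                raise ValueError("bias variable not aligned with batch")
            dc2 = dcor.dcor_penalty(F, Bv)
            breakdown["dc2"] = float(dc2.data)
            breakdown["dc_term"] = spec.lambda_dc * float(dc2.data)
            loss = loss + spec.lambda_dc * dc2
    breakdown["total"] = float(loss.data)
    return loss, breakdown


def scanner_objective(batch: dict, model: TapNet,
                      spec: ScannerObjectiveSpec, B,
                      taps: FeatureTapSet | None = None):
    """Evaluate the scanner-bias objective on one minibatch.

    ``batch`` additionally carries ``scanner`` ids; the decorrelation term
    uses only rows with ``y == control_label`` and weights them by
    ``spec.scanner_weights``.  Fewer than the penalty minimum of control
    samples sets the term to 0 and flags the skip.
    """
    y = np.asarray(batch["y"], dtype=np.intp)
    logits, acts = model.forward(batch["x"])
    ce = _wce_tensor(logits, y, None) * spec.lambda1
    l2 = l2_penalty(model) * spec.l2_coeff
    breakdown = {"ce": float(ce.data), "l2": float(l2.data),
                 "dc2": 0.0, "dc_term": 0.0, "dc_skipped": False,
                 "n_control": 0}
    loss = ce + l2
    if spec.lambda2 > 0:
        ctrl = np.flatnonzero(y == spec.control_label)
        breakdown["n_control"] = int(len(ctrl))
        if len(ctrl) < dcor.PENALTY_MIN_BATCH:
            breakdown["dc_skipped"] = True
        else:
            scanner = np.asarray(batch["scanner"])[ctrl]
            if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in scanner):
                raise ValueError("control sample with missing scanner id")
            w = (np.array([spec.scanner_weights[s] for s in scanner])
                 if spec.scanner_weights else None)
            taps = taps or FeatureTapSet.default_for(model.spec.variant)
            F = gather_rows(features_from_acts(acts, taps), ctrl)
            Bv = B.values if hasattr(B, "values") else np.asarray(B)
            if Bv.shape[0] != len(y):
                raise ValueError("bias variable not aligned with batch")
            dc2 = dcor.dcor_penalty(F, Bv[ctrl], w=w)
            breakdown["dc2"] = float(dc2.data)
            breakdown["dc_term"] = spec.lambda2 * float(dc2.data)
            loss = loss + spec.lambda2 * dc2
    breakdown["total"] = float(loss.data)
    return loss, breakdown
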