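"""Seeded training loops, learning-rate policies, and the multi-run protocol.

Runs are fully deterministic given the config seed: model initialisation,
batch order, dropout masks and bias-variable redraws all derive from it.
Each iteration logs the learning rate and the per-term loss breakdown —
including the evaluated DC² — so the decorrelation trajectory can be
plotted or audited offline.  Checkpoint selection uses validation balanced
accuracy; the published protocol of retraining three times and reporting
mean ± 95% t-interval is provided by :func:`train_multi` /
:func:`run_interval`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bias_variables as bv
from .dataio import SliceDataset
from .models import ArchitectureSpec, FeatureTapSet, TapNet, build_model
from .objectives import (ClassBiasObjectiveSpec, ScannerObjectiveSpec,
                         class_bias_objective, scanner_objective)

__all__ = ["TrainConfig", "TrainResult", "exp_cyclical_lr", "step_decay_lr",
           "subject_split", "train_model", "train_multi", "run_interval",
           "dummy_bias_builder", "voxel_bias_builder", "constant_bias_builder"]


# ---------------------------------------------------------------------------
# learning-rate policies
# ---------------------------------------------------------------------------

def exp_cyclical_lr(iteration: int, base_lr: float = 1e-4, max_lr: float = 1e-2,
                    half_cycle: int = 2000, gamma: float = 0.99994) -> float:
    """Triangular cycle between base and max with exponentially decaying
    amplitude (the 'exp_range' cyclical policy)."""
    if not base_lr < max_lr:
        raise ValueError("need base_lr < max_lr")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    cycle = np.floor(1 + iteration / (2 * half_cycle))
    x = abs(iteration / half_cycle - 2 * cycle + 1)
    return base_lr + (max_lr - base_lr) * max(0.0, 1.0 - x) * gamma ** iteration


def step_decay_lr(epoch: int, initial_lr: float = 1e-3, decay: float = 0.5,
                  every: int = 5) -> float:
    return initial_lr * decay ** (epoch // every)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Optim:
    def __init__(self, params):
        self.params = [p for p in params]

    def step(self, lr: float):
        raise NotImplementedError


class RMSProp(_Optim):
    def __init__(self, params, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(_Optim):
    def __init__(self, params, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params)
        self.b1, self.b2, self.eps, self.t = b1, b2, eps, 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# config / splits
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    objective: object                   # ClassBias- or ScannerObjectiveSpec
    optimizer: str = "rmsprop"          # {rmsprop, adam}
    batch_size: int = 128
    epochs: int = 10
    seed: int = 0
    n_runs: int = 3
    lr_policy: str = "exp_cyclical"     # {exp_cyclical, step_decay}
    lr_params: dict = field(default_factory=dict)
    augment: bool = False
    checkpoint_metric: str = "balanced_accuracy"   # or "min_class_accuracy"
    eval_every: int = 1        # validate/checkpoint every k epochs

    def lr_at(self, iteration: int, epoch: int) -> float:
        if self.lr_policy == "exp_cyclical":
            return exp_cyclical_lr(iteration, **self.lr_params)
        if self.lr_policy == "step_decay":
            return step_decay_lr(epoch, **self.lr_params)
        raise ValueError(f"unknown lr policy {self.lr_policy!r}")


def subject_split(manifest: pd.DataFrame, fractions=(0.70, 0.15, 0.15),
                  seed: int = 0) -> dict:
    """70/15/15 row-index split grouped by subject, stratified by class.

    Every subject lands in exactly one split, so follow-up slices of one
    subject can never leak across the train/val/test boundary.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three numbers summing to 1")
    rng = np.random.default_rng(seed)
    per_subject = manifest.groupby("subject_id")["class"].first()
    buckets: dict[str, list] = {"train": [], "val": [], "test": []}
    for cls in per_subject.unique():
        subs = per_subject.index[per_subject == cls].to_numpy()
        rng.shuffle(subs)
        n = len(subs)
        n_train = max(1, int(round(fractions[0] * n)))
        n_val = max(1, int(round(fractions[1] * n))) if n >= 3 else 0
        n_train = min(n_train, n - n_val - 1) if n >= 2 else n
        buckets["train"].extend(subs[:n_train])
        buckets["val"].extend(subs[n_train:n_train + n_val])
        buckets["test"].extend(subs[n_train + n_val:])
    out = {}
    subject_col = manifest["subject_id"]
    for name, subs in buckets.items():
        out[name] = np.flatnonzero(subject_col.isin(subs).to_numpy())
    return out


# ---------------------------------------------------------------------------
# bias-variable builders (callables: (dataset, epoch) -> (n, d) array)
# ---------------------------------------------------------------------------

def dummy_bias_builder(width_majority: int = 10, width_minority: int = 2,
                       base_seed: int = 0, majority_label: int | None = None):
    """Dummy class-bias variable, redrawn every epoch from a derived seed.

    Set ``majority_label`` when training on oversampled data (the counts
    there are tied, so the original majority must be named)."""
    def build(ds: SliceDataset, epoch: int) -> np.ndarray:
        return bv.dummy_class_bias(ds.labels, width_majority, width_minority,
                                   seed=(base_seed + epoch) % (2 ** 31),
                                   majority_label=majority_label).values
    return build


def voxel_bias_builder():
    """Voxel-size bias standardized with training-split statistics."""
    state: dict = {}

    def build(ds: SliceDataset, epoch: int) -> np.ndarray:
        bias, stats_ = bv.voxel_size_bias(ds.manifest, state.get("stats"))
        state["stats"] = stats_
        return bias.values
    return build


def constant_bias_builder(values: np.ndarray):
    """A fixed precomputed bias matrix (FE features, temporal std)."""
    values = np.asarray(values, dtype=np.float64)

    def build(ds: SliceDataset, epoch: int) -> np.ndarray:
        if len(values) != len(ds):
            raise ValueError("precomputed bias rows do not match the dataset")
        return values
    return build


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: TapNet
    log: pd.DataFrame
    best_val_ba: float
    seed: int


def _model_inputs(ds: SliceDataset, arch: ArchitectureSpec) -> np.ndarray:
    if arch.variant == "convgru_dccnn":
        if ds.frames is None:
            raise ValueError("temporal architecture needs a dataset with frames")
        return ds.frames
    return ds.images


def _class_accuracies(y_true: np.ndarray, y_pred: np.ndarray) -> list:
    vals = []
    for cls in (0, 1):
        m = y_true == cls
        if m.any():
            vals.append(float((y_pred[m] == cls).mean()))
    return vals


def _checkpoint_score(y_true, y_pred, metric: str) -> float:
    vals = _class_accuracies(y_true, y_pred)
    if not vals:
        return float("nan")
    if metric == "balanced_accuracy":
        return float(np.mean(vals))
    if metric == "min_class_accuracy":
        return float(np.min(vals))
    raise ValueError(f"unknown checkpoint metric {metric!r}")


def train_model(train: SliceDataset, val: SliceDataset,
                arch: ArchitectureSpec, cfg: TrainConfig,
                bias_builder=None, taps: FeatureTapSet | None = None
                ) -> TrainResult:
    """Train one model; returns the best-validation checkpoint and the log."""
    spec = cfg.objective
    is_scanner = isinstance(spec, ScannerObjectiveSpec)
    if not is_scanner and not isinstance(spec, ClassBiasObjectiveSpec):
        raise TypeError("objective must be a ClassBias- or ScannerObjectiveSpec")
    penalty_on = (spec.lambda2 if is_scanner else spec.lambda_dc) > 0
    if penalty_on and bias_builder is None:
        raise ValueError("an active decorrelation term needs a bias_builder")

    model = build_model(arch, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    model.seed_dropout(rng)
    opt = {"rmsprop": RMSProp, "adam": Adam}[cfg.optimizer](model.parameters())

    x_all = _model_inputs(train, arch)
    y_all = train.labels
    scanner_all = train.scanners
    x_val = _model_inputs(val, arch)
    y_val = val.labels

    from .sampling import augment_images  # local import avoids cycle

    n = len(train)
    rows = []
    it = 0
    best = (-np.inf, None)
    for epoch in range(cfg.epochs):
        B_epoch = bias_builder(train, epoch) if penalty_on else None
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_all[idx]
            if cfg.augment and arch.variant != "convgru_dccnn":
                xb = augment_images(xb, rng)
            batch = {"x": xb, "y": y_all[idx], "scanner": scanner_all[idx]}
            Bb = B_epoch[idx] if B_epoch is not None else None
            model.train()
            if is_scanner:
                loss, terms = scanner_objective(batch, model, spec, Bb, taps)
            else:
                loss, terms = class_bias_objective(batch, model, spec, Bb, taps)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at iteration {it}: {terms}")
            model.zero_grad()
            loss.backward()
            lr = cfg.lr_at(it, epoch)
            opt.step(lr)
            rows.append({"iteration": it, "epoch": epoch, "lr": lr, **terms})
            it += 1
        # precise-BN recalibration, then validation checkpointing
        if (epoch + 1) % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
            model.recalibrate_bn(x_all[:512])
            proba = model.predict_proba(x_val)
            score = _checkpoint_score(y_val, proba.argmax(axis=1),
                                      cfg.checkpoint_metric)
            rows[-1]["val_score"] = score
            if score > best[0]:
                best = (score, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    model.trained = True
    return TrainResult(model, pd.DataFrame(rows), best[0], cfg.seed)


def train_multi(train: SliceDataset, val: SliceDataset,
                arch: ArchitectureSpec, cfg: TrainConfig,
                bias_builder=None, taps: FeatureTapSet | None = None
                ) -> list[TrainResult]:
    """The published protocol: retrain ``cfg.n_runs`` times with derived seeds."""
    results = []
    for r in range(cfg.n_runs):
        run_cfg = TrainConfig(**{**cfg.__dict__, "seed": (cfg.seed + 1009 * r) % (2 ** 31)})
        results.append(train_model(train, val, arch, run_cfg, bias_builder, taps))
    return results


def run_interval(values) -> tuple[float, float]:
    """Mean ± 95% t-interval half-width across runs (t_{0.975, n−1})."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return float(v.mean()), float("nan")
    t = stats.t.ppf(0.975, df=v.size - 1)
    half = t * v.std(ddof=1) / np.sqrt(v.size)
    return float(v.mean()), float(half)
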