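"""Classifier architectures with configurable feature taps.

Five named variants are provided, each a stack of conv(3x3, 'same') → ReLU →
batch-norm → max-pool(2x2) blocks followed by two fully connected layers and
a softmax head:

==================  ===================  ============  =========================
variant             conv filters         fc sizes      default taps (features F)
==================  ===================  ============  =========================
classbias_dccnn     32, 64, 128          64, 32        fc1, fc2, softmax
scanner_dccnn       32, 16, 16           40, 100       conv1, fc1, fc2
fe_model            32, 16, 16, 8, 8     40, 100       (bias source: conv5)
fe_dccnn            32, 16, 16, 8, 8     40, 100       conv5, fc1, fc2
convgru_dccnn       16, 32, 32 (+GRU)    1000, 500     conv2, fc1
==================  ===================  ============  =========================

The *feature taps* name the layers whose flattened outputs are concatenated
into the feature matrix F fed to the decorrelation penalty; taps stay in the
autodiff graph, so the penalty's gradient reaches the model parameters.
``convgru_dccnn`` prepends a convolutional GRU that summarises a (T, H, W)
frame sequence into a spatial map before the conv stack.

Filter/neuron counts of the named variants are fixed; input shape, kernel
size, dropout, and GRU width are configurable so the same architectures run
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .autodiff import Tensor, concat, softmax

__all__ = ["ArchitectureSpec", "FeatureTapSet", "build_model",
           "extract_features", "DEFAULT_TAPS"]

_NAMED = {
    "classbias_dccnn": dict(conv_filters=[32, 64, 128], fc_sizes=[64, 32],
                            dropout=0.0, n_dropout_blocks=0),
    "scanner_dccnn": dict(conv_filters=[32, 16, 16], fc_sizes=[40, 100],
                          dropout=0.0, n_dropout_blocks=0),
    "fe_model": dict(conv_filters=[32, 16, 16, 8, 8], fc_sizes=[40, 100],
                     dropout=0.2, n_dropout_blocks=4),
    "fe_dccnn": dict(conv_filters=[32, 16, 16, 8, 8], fc_sizes=[40, 100],
                     dropout=0.2, n_dropout_blocks=4),
    "convgru_dccnn": dict(conv_filters=[16, 32, 32], fc_sizes=[1000, 500],
                          dropout=0.0, n_dropout_blocks=0),
}

DEFAULT_TAPS = {
    "classbias_dccnn": ["fc1", "fc2", "softmax"],
    "scanner_dccnn": ["conv1", "fc1", "fc2"],
    "fe_model": ["conv5"],
    "fe_dccnn": ["conv5", "fc1", "fc2"],
    "convgru_dccnn": ["conv2", "fc1"],
}


@dataclass
class ArchitectureSpec:
    variant: str
    input_shape: tuple          # (H, W) or (T, H, W) for convgru_dccnn
    conv_filters: list = field(default_factory=list)
    fc_sizes: list = field(default_factory=list)
    dropout: float = 0.0
    n_dropout_blocks: int = 0
    n_classes: int = 2
    kernel: int = 3
    pool: int = 2
    gru_hidden: int = 8

    @staticmethod
    def named(variant: str, input_shape: tuple, **overrides) -> "ArchitectureSpec":
        """A spec with the printed filter/neuron counts of a named variant."""
        if variant not in _NAMED:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {sorted(_NAMED)}")
        spec = ArchitectureSpec(variant=variant, input_shape=tuple(input_shape),
                                **_NAMED[variant])
        return replace(spec, **overrides) if overrides else spec

    def validate(self):
        if self.variant not in _NAMED:
            raise ValueError(f"unknown variant {self.variant!r}")
        want = len(self.input_shape)
        need = 3 if self.variant == "convgru_dccnn" else 2
        if want != need:
            raise ValueError(f"{self.variant} expects a {need}-D input shape, "
                             f"got {self.input_shape}")
        if not self.conv_filters or len(self.fc_sizes) != 2:
            raise ValueError("need conv filters and exactly two fc sizes")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")


@dataclass(frozen=True)
class FeatureTapSet:
    """Ordered layer names whose flattened outputs are concatenated into F."""
    tap_names: tuple

    def __init__(self, tap_names):
        object.__setattr__(self, "tap_names", tuple(tap_names))
        if not self.tap_names:
            raise ValueError("tap set must name at least one layer")

    @staticmethod
    def default_for(variant: str) -> "FeatureTapSet":
        return FeatureTapSet(DEFAULT_TAPS[variant])


class TapNet(nn.Module):
    """Conv/pool/BN stack + 2 FC + softmax, recording named activations."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.temporal = spec.variant == "convgru_dccnn"
        if self.temporal:
            t, h, w = spec.input_shape
            self.gru = nn.ConvGRUCell(1, spec.gru_hidden, spec.kernel, rng)
            cin = spec.gru_hidden
        else:
            h, w = spec.input_shape
            cin = 1
        self.convs, self.bns, self.drops = [], [], []
        for i, f in enumerate(spec.conv_filters):
            self.convs.append(nn.Conv2d(cin, f, spec.kernel, rng))
            self.bns.append(nn.BatchNorm(f, spatial=True))
            p = spec.dropout if i < spec.n_dropout_blocks else 0.0
            self.drops.append(nn.Dropout(p))
            cin = f
            h, w = h // spec.pool, w // spec.pool
            if h < 1 or w < 1:
                raise ValueError("input too small for the conv/pool stack")
        flat = cin * h * w
        self.fc1 = nn.Dense(flat, spec.fc_sizes[0], rng)
        self.fc2 = nn.Dense(spec.fc_sizes[0], spec.fc_sizes[1], rng)
        self.head = nn.Dense(spec.fc_sizes[1], spec.n_classes, rng)

    def seed_dropout(self, rng: np.random.Generator):
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng

    def forward(self, x) -> tuple[Tensor, dict]:
        """``x``: (N,H,W) or (N,T,H,W) array -> (logits, named activations)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        acts: dict[str, Tensor] = {}
        if self.temporal:
            n, t, h, w = x.shape
            out = self.gru(x.reshape(n, t, 1, h, w))
            acts["gru"] = out
        else:
            n, h, w = x.shape
            out = x.reshape(n, 1, h, w)
        for i, (conv, bn, drop) in enumerate(zip(self.convs, self.bns, self.drops), 1):
            out = nn.maxpool2d(bn(conv(out).relu()), self.spec.pool)
            out = drop(out)
            acts[f"conv{i}"] = out
        out = nn.flatten(out)
        out = self.fc1(out).relu()
        acts["fc1"] = out
        out = self.fc2(out).relu()
        acts["fc2"] = out
        logits = self.head(out)
        acts["logits"] = logits
        acts["softmax"] = softmax(logits)
        return logits, acts

    __call__ = forward

    def recalibrate_bn(self, x, batch_size: int = 128):
        """Recompute batch-norm running statistics over ``x`` (precise BN).

        EMA statistics lag the weights they were collected under; a fresh
        uniform average over training batches makes inference-mode
        normalization consistent with the current parameters.  Dropout and
        other stochastic layers stay in inference mode.
        """
        bns = [m for m in self.modules() if isinstance(m, nn.BatchNorm)]
        if not bns:
            return
        modes = [m.training for m in self.modules()]
        for m in self.modules():
            m.training = isinstance(m, nn.BatchNorm)
        for b in bns:
            b.start_accumulate()
        x = np.asarray(x, dtype=np.float64)
        for i in range(0, len(x), batch_size):
            chunk = x[i:i + batch_size]
            if len(chunk) >= 2:     # batch stats undefined for single samples
                self.forward(chunk)
        for b in bns:
            b.finish_accumulate()
        for m, mode in zip(self.modules(), modes):
            m.training = mode

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities, batched, no graph kept."""
        was_training = self.training
        self.eval()
        x = np.asarray(x, dtype=np.float64)
        out = []
        for i in range(0, len(x), batch_size):
            _, acts = self.forward(x[i:i + batch_size])
            out.append(acts["softmax"].data)
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> TapNet:
    spec.validate()
    return TapNet(spec, np.random.default_rng(seed))


def extract_features(model: TapNet, x, taps: FeatureTapSet) -> Tensor:
    """Concatenated flattened tap activations F (n x d), in the autodiff graph."""
    _, acts = model.forward(x)
    return features_from_acts(acts, taps)


def features_from_acts(acts: dict, taps: FeatureTapSet) -> Tensor:
    missing = [t for t in taps.tap_names if t not in acts]
    if missing:
        raise ValueError(f"unknown tap(s) {missing}; available: {sorted(acts)}")
    return concat([nn.flatten(acts[t]) for t in taps.tap_names], axis=1)
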