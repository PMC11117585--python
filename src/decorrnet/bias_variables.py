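"""Constructions of the per-sample bias variable B.

The decorrelation penalty needs, for every training sample, a vector that
encodes the nuisance to be removed from the learned features:

``dummy_class_bias``
    class imbalance — integers drawn from a class-dependent discrete
    uniform distribution (the majority class gets the wider support, so
    the variable carries the class-prior signal the penalty removes);
``voxel_size_bias``
    acquisition geometry — (slice thickness, pixel spacing x/y) in mm
    from the manifest, standardized on the training split;
``fe_feature_bias``
    learned scanner signature — frozen activations of a scanner-classifier
    ("feature extraction") model;
``temporal_std_bias``
    scanner noise spectrum — per-pixel temporal standard deviation of a
    frame sequence, average-pooled to a manageable dimension.

Bias variables are inputs: they are constant in the autodiff graph and
never receive gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BiasVariable", "dummy_class_bias", "voxel_size_bias",
           "fe_feature_bias", "temporal_std_bias", "VOXEL_COLUMNS"]

VOXEL_COLUMNS = ["slice_thickness_mm", "pixel_spacing_x_mm", "pixel_spacing_y_mm"]


@dataclass
class BiasVariable:
    values: np.ndarray          # (n, d_b), finite, row-aligned with the batch
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2:
            raise ValueError("bias variable must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("bias variable contains non-finite values")

    def __len__(self):
        return self.values.shape[0]

    def take(self, index) -> "BiasVariable":
        return BiasVariable(self.values[np.asarray(index)], self.kind,
                            dict(self.provenance))


def dummy_class_bias(labels, width_majority: int = 10, width_minority: int = 2,
                     seed: int = 0, majority_label: int | None = None) -> BiasVariable:
    """Discrete-uniform dummy variable; the majority class gets the wider support.

    Each sample draws an integer uniformly from {0, …, width−1} where the
    width depends on its class.  By construction the draw correlates with
    the class label (through its variance), which is exactly the lever the
    class-bias objective decorrelates away.  Draws are seeded; redraw each
    epoch with a fresh seed.

    ``majority_label`` names the class that gets the wide support; by
    default it is inferred from the label counts.  Pass it explicitly for
    oversampled data, where the counts are tied and no longer reflect the
    original imbalance.
    """
    if not width_majority > width_minority >= 1:
        raise ValueError("need width_majority > width_minority >= 1 "
                         "(equal widths carry no class-bias signal)")
    y = np.asarray(labels, dtype=np.intp)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"dummy class bias expects 2 classes, got {len(classes)}")
    if majority_label is None:
        if counts[0] == counts[1]:
            raise ValueError("tied class counts: pass majority_label explicitly "
                             "(counts no longer identify the original majority)")
        majority = classes[np.argmax(counts)]
    else:
        majority = majority_label
    widths = np.where(y == majority, width_majority, width_minority)
    rng = np.random.default_rng(seed)
    draws = np.floor(rng.random(len(y)) * widths).astype(np.float64)
    return BiasVariable(draws[:, None], "dummy_class",
                        {"width_majority": width_majority,
                         "width_minority": width_minority,
                         "majority_label": int(majority), "seed": seed})


def voxel_size_bias(manifest: pd.DataFrame,
                    stats: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> tuple[BiasVariable, tuple[np.ndarray, np.ndarray]]:
    """(slice thickness, pixel spacing x, y) in mm, standardized.

    ``stats`` are the (mean, std) fit on the training split; pass them back
    in for validation/test rows.  Returns ``(bias, stats)``.  A constant
    column (single-scanner data) stays identically zero, so the penalty's
    zero-denominator branch makes DC² = 0.
    """
    missing_cols = [c for c in VOXEL_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest lacks metadata columns {missing_cols}")
    vals = manifest[VOXEL_COLUMNS].to_numpy(dtype=np.float64)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.any():
        subjects = manifest.iloc[np.flatnonzero(bad)]["subject_id"].tolist()
        raise ValueError(f"missing voxel metadata for subjects {sorted(set(subjects))}")
    if stats is None:
        mean = vals.mean(axis=0)
        std = vals.std(axis=0)
        stats = (mean, std)
    mean, std = stats
    safe = np.where(std > 0, std, 1.0)
    return BiasVariable((vals - mean) / safe, "voxel_size",
                        {"mean": mean.tolist(), "std": std.tolist()}), stats


def fe_feature_bias(fe_model, images, tap: str = None,
                    batch_size: int = 256) -> BiasVariable:
    """Frozen activations of a trained scanner-classifier as bias variable.

    The default tap is the last convolutional block of the FE model.  The
    model must have been trained (``fe_model.trained``); activations are
    computed in inference mode and detached from the graph.
    """
    if not getattr(fe_model, "trained", False):
        raise ValueError("FE model is untrained; train it on the scanner "
                         "classification task first")
    tap = tap or f"conv{len(fe_model.convs)}"
    was_training = fe_model.training
    fe_model.eval()
    images = np.asarray(images, dtype=np.float64)
    rows = []
    for i in range(0, len(images), batch_size):
        _, acts = fe_model.forward(images[i:i + batch_size])
        a = acts[tap].data
        rows.append(a.reshape(a.shape[0], -1))
    if was_training:
        fe_model.train()
    return BiasVariable(np.concatenate(rows, axis=0), "fe_features",
                        {"tap": tap})


def temporal_std_bias(time_series, pool: int = 4) -> BiasVariable:
    """Per-pixel temporal std (population, 1/T), average-pooled, flattened.

    ``time_series``: (n, T, H, W) with T >= 2.  The temporal fluctuation
    level is a scanner signature (noise spectra differ between scanners).
    """
    x = np.asarray(time_series, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("time series must be (n, T, H, W)")
    n, t, h, w = x.shape
    if t < 2:
        raise ValueError("temporal std needs at least 2 frames")
    std = x.std(axis=1)                      # population std over T
    ho, wo = h // pool, w // pool
    if ho < 1 or wo < 1:
        raise ValueError(f"pool factor {pool} too large for {h}x{w} maps")
    pooled = std[:, :ho * pool, :wo * pool].reshape(n, ho, pool, wo, pool)
    pooled = pooled.mean(axis=(2, 4))
    return BiasVariable(pooled.reshape(n, -1), "temporal_std", {"pool": pool})
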