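"""Class-imbalance baselines: oversampling, SMOTE, stratified resampling,
class weights, and the image augmentations applied to training data.

All resampling applies to the *training split only*; resampled manifests
carry a ``sampled`` provenance column so split integrity can be audited.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.neighbors import NearestNeighbors

__all__ = ["random_oversample", "smote_oversample", "stratified_balanced_split",
           "inverse_frequency_weights", "augment_images"]


def _class_counts(labels: pd.Series):
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("resampling needs at least two classes present")
    return counts


def random_oversample(records: pd.DataFrame, seed: int = 0,
                      label_col: str = "class") -> pd.DataFrame:
    """Duplicate minority rows (with replacement) until class counts are equal."""
    counts = _class_counts(records[label_col])
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    out = [records.assign(sampled="original")]
    for cls, n in counts.items():
        if n < n_max:
            pool = records[records[label_col] == cls]
            picks = rng.integers(0, n, size=n_max - n)
            out.append(pool.iloc[picks].assign(sampled="ros_duplicate"))
    return pd.concat(out, ignore_index=True)


def stratified_balanced_split(records: pd.DataFrame, seed: int = 0,
                              label_col: str = "class") -> pd.DataFrame:
    """Resample every class stratum (with replacement) to the majority size."""
    counts = _class_counts(records[label_col])
    if (counts == 0).any():
        raise ValueError("empty stratum")
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    out = []
    for cls in counts.index:
        pool = records[records[label_col] == cls]
        if len(pool) == n_max:
            out.append(pool.assign(sampled="original"))
        else:
            picks = rng.integers(0, len(pool), size=n_max)
            out.append(pool.iloc[picks].assign(sampled="stratum_resample"))
    return pd.concat(out, ignore_index=True)


def smote_oversample(feature_rows, labels, k: int = 5, seed: int = 0,
                     n_new: int | None = None):
    """Synthetic minority oversampling by nearest-neighbor interpolation.

    New minority samples are ``x + u·(x_nn − x)`` with ``u ~ U(0,1)`` and
    ``x_nn`` one of the ``k`` nearest *minority* neighbors of ``x``.
    Images of any shape are flattened for interpolation and reshaped after.
    Returns ``(synthetic_rows, synthetic_labels)``; by default enough rows
    to balance the two classes.
    """
    X = np.asarray(feature_rows, dtype=np.float64)
    y = np.asarray(labels)
    orig_shape = X.shape[1:]
    Xf = X.reshape(len(X), -1)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here supports exactly two classes")
    minority = classes[np.argmin(counts)]
    Xmin = Xf[y == minority]
    if len(Xmin) <= k:
        raise ValueError(f"minority count {len(Xmin)} must exceed k={k}")
    if n_new is None:
        n_new = int(counts.max() - counts.min())
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)          # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), size=n_new)
    neigh = idx[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.random((n_new, 1))
    synth = Xmin[base] + u * (Xmin[neigh] - Xmin[base])
    return synth.reshape((n_new,) + orig_shape), np.full(n_new, minority, dtype=y.dtype)


def inverse_frequency_weights(labels) -> np.ndarray:
    """Per-class weights ``n_total / (n_classes · n_c)``, normalized to mean 1.

    Indexed by class id (classes must be 0..K-1)."""
    y = np.asarray(labels, dtype=np.intp)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if not np.array_equal(classes, np.arange(len(classes))):
        raise ValueError("labels must be 0..K-1")
    w = len(y) / (len(classes) * counts.astype(np.float64))
    return w / w.mean()


def augment_images(images: np.ndarray, rng: np.random.Generator,
                   max_rotation_deg: float = 10.0, max_shift_px: float = 3.0,
                   elastic_alpha: float = 8.0, elastic_sigma: float = 2.0
                   ) -> np.ndarray:
    """Random rotation, translation, and elastic deformation per image."""
    out = np.empty_like(images)
    h, w = images.shape[-2:]
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for i, img in enumerate(images):
        # rotation + translation as one affine resampling
        ang = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        shift = rng.uniform(-max_shift_px, max_shift_px, size=2)
        c, s = np.cos(ang), np.sin(ang)
        mat = np.array([[c, -s], [s, c]])
        offset = center - mat @ (center + shift)
        img2 = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                        mode="nearest")
        if elastic_alpha > 0:
            dx = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                         elastic_sigma) * elastic_alpha
            dy = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                         elastic_sigma) * elastic_alpha
            img2 = ndimage.map_coordinates(img2, [yy + dy, xx + dx],
                                           order=1, mode="nearest")
        out[i] = img2
    return out
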