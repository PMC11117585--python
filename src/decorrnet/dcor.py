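"""Squared distance correlation: analysis statistic and training penalty.

Distance correlation (dCor) measures linear *and* nonlinear dependence
between two random vectors of arbitrary, possibly different, dimension.
For samples ``B`` (bias variable, n x d_b) and ``F`` (features, n x d_f)
the squared statistic is

    DC^2(B, F) = V^2(B, F) / sqrt(V^2(B, B) * V^2(F, F))

when the denominator product is positive, and 0 otherwise; it lies in
[0, 1] and the population version vanishes iff B and F are independent.
``V^2`` is the biased V-statistic distance covariance built from
double-centered Euclidean distance matrices:

    A_jk = d_jk − rowmean_j − colmean_k + grandmean
    V^2(B, F) = (1/n^2) * sum_jk A_jk * A'_jk

The sample-weighted variant replaces every empirical mean by a
w-weighted mean (the V-statistic of the weighted empirical distribution),
so a sample carrying weight 2 is exactly equivalent to duplicating it.

Two call surfaces are provided:

* plain-numpy functions for analysis and testing;
* :func:`dcor_penalty`, the same computation expressed on autodiff
  tensors so that, used inside a training objective, gradients flow
  through the features ``F`` (the bias variable ``B`` is constant).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "pairwise_distances", "double_center", "distance_covariance_sq",
    "distance_correlation_sq", "weighted_distance_correlation_sq",
    "dcor_penalty", "EPS_DEFAULT", "PENALTY_MIN_BATCH",
]

EPS_DEFAULT = 1e-12
#: Minimum samples for the differentiable penalty; tiny batches make the
#: V-statistic too noisy to serve as a useful training signal.
PENALTY_MIN_BATCH = 8


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"sample matrix must be 1-D or 2-D, got ndim={X.ndim}")
    return X


def pairwise_distances(X) -> np.ndarray:
    """Euclidean distance matrix of the rows of ``X`` (n >= 2 required)."""
    X = _as_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite values in rows {np.flatnonzero(bad).tolist()}")
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    D = np.sqrt(d2)
    return 0.5 * (D + D.T)


def double_center(D: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Double-center a distance matrix: A_jk = d_jk − m_j − m_k + m̄.

    With weights ``w`` the means are w-weighted (``m_j = Σ_k p_k d_jk`` with
    ``p = w / Σw``); ``w=None`` gives the ordinary uniform centering.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if w is None:
        row = D.mean(axis=1, keepdims=True)
        grand = D.mean()
    else:
        p = _norm_weights(w, D.shape[0])[:, None]
        row = D @ p
        grand = float((p.T @ row)[0, 0])
    return D - row - row.T + grand


def _norm_weights(w, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64).ravel()
    if w.shape[0] != n:
        raise ValueError(f"weight length {w.shape[0]} != sample count {n}")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return w / total


def distance_covariance_sq(A: np.ndarray, B: np.ndarray,
                           w: np.ndarray | None = None) -> float:
    """V-statistic distance covariance of two centered matrices.

    ``(1/n^2) Σ_jk A_jk B_jk`` (or ``Σ_jk p_j p_k A_jk B_jk`` weighted).
    Nonnegative when ``A is B`` (distance variance); any sign otherwise.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if w is None:
        return float((A * B).sum() / (n * n))
    p = _norm_weights(w, n)
    return float(p @ (A * B) @ p)


def distance_correlation_sq(B, F, eps: float = EPS_DEFAULT) -> float:
    """Squared distance correlation of two samples, in [0, 1]."""
    return weighted_distance_correlation_sq(B, F, w=None, eps=eps)


def weighted_distance_correlation_sq(B, F, w=None,
                                     eps: float = EPS_DEFAULT) -> float:
    """Sample-weighted squared distance correlation.

    Uniform weights reduce exactly to :func:`distance_correlation_sq`;
    integer weights are equivalent to sample duplication.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    B = _as_matrix(B)
    F = _as_matrix(F)
    if B.shape[0] != F.shape[0]:
        raise ValueError(f"sample counts differ: {B.shape[0]} vs {F.shape[0]}")
    if B.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Ab = double_center(pairwise_distances(B), w)
    Af = double_center(pairwise_distances(F), w)
    vbf = distance_covariance_sq(Ab, Af, w)
    vbb = distance_covariance_sq(Ab, Ab, w)
    vff = distance_covariance_sq(Af, Af, w)
    denom_sq = vbb * vff
    if denom_sq <= eps:
        return 0.0
    return float(np.clip(vbf / np.sqrt(denom_sq), 0.0, 1.0))


# ---------------------------------------------------------------------------
# differentiable penalty
# ---------------------------------------------------------------------------

#: gradient clamp for sqrt at near-zero distances: d(sqrt)/dx <= 0.5/_GRAD_FLOOR.
#: The forward value stays the exact Euclidean distance, so the logged penalty
#: equals the analysis statistic; only the (unbounded) derivative at duplicated
#: rows — routine after random oversampling — is capped.
_GRAD_FLOOR = 1e-3


def _sqrt_clamped_grad(x: Tensor) -> Tensor:
    out = np.sqrt(np.maximum(x.data, 0.0))

    def bw(g):
        return ((x, g * 0.5 / np.maximum(out, _GRAD_FLOOR)),)
    return Tensor(out, parents=(x,), backward=bw)


def _pairwise_tensor(F: Tensor, n: int) -> Tensor:
    sq = F.square().sum(axis=1, keepdims=True)            # (n,1)
    d2 = sq + sq.T - 2.0 * (F @ F.T)
    mask = Tensor(1.0 - np.eye(n))
    return _sqrt_clamped_grad(d2.relu()) * mask


def _center_tensor(D: Tensor, p: np.ndarray) -> Tensor:
    pcol = Tensor(p[:, None])
    row = D @ pcol                                        # (n,1)
    grand = (pcol.T @ row).reshape(1, 1)
    return D - row - row.T + grand


def dcor_penalty(F: Tensor, B: np.ndarray, w: np.ndarray | None = None,
                 eps: float = EPS_DEFAULT,
                 min_batch: int = PENALTY_MIN_BATCH) -> Tensor:
    """Differentiable DC^2(B, F) for use inside a training objective.

    ``F`` is an autodiff tensor (gradients flow into the model); ``B`` is a
    constant numpy bias variable, never trained.  Raises ``ValueError`` for
    batches smaller than ``min_batch`` — callers are expected to skip the
    penalty (and log the skip) in that case.
    """
    Bm = _as_matrix(B)
    n = Bm.shape[0]
    if F.shape[0] != n:
        raise ValueError(f"sample counts differ: B has {n}, F has {F.shape[0]}")
    if n < min_batch:
        raise ValueError(f"penalty needs >= {min_batch} samples, got {n}")
    p = _norm_weights(w, n) if w is not None else np.full(n, 1.0 / n)

    # bias side is constant: compute in plain numpy
    Ab = double_center(pairwise_distances(Bm), p * n)
    vbb = distance_covariance_sq(Ab, Ab, p * n)

    Df = _pairwise_tensor(F, n)
    Af = _center_tensor(Df, p)
    P = Tensor(np.outer(p, p))
    vff = (P * Af * Af).sum()
    vbf = (P * Tensor(Ab) * Af).sum()

    denom_sq = vbb * float(vff.data)
    if denom_sq <= eps:
        return Tensor(0.0)
    return vbf / ((vff * vbb) ** 0.5)
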