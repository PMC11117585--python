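"""Distance-correlation core: oracle equivalence, analytic properties,
weighting semantics, and the differentiability contract of the penalty."""

import numpy as np
import pytest

from decorrnet import dcor
from decorrnet.autodiff import Tensor


# ---------------------------------------------------------------------------
# naive O(n^2 d) oracle, written independently of the implementation
# ---------------------------------------------------------------------------

def naive_dcor_sq(B, F, w=None, eps=1e-12):
    B = np.atleast_2d(np.asarray(B, float).T).T
    F = np.atleast_2d(np.asarray(F, float).T).T
    n = len(B)
    w = np.ones(n) if w is None else np.asarray(w, float)
    p = w / w.sum()

    def dist(X):
        D = np.zeros((n, n))
        for j in range(n):
            for k in range(n):
                D[j, k] = np.sqrt(((X[j] - X[k]) ** 2).sum())
        return D

    def center(D):
        m = np.array([sum(p[k] * D[j, k] for k in range(n)) for j in range(n)])
        gm = sum(p[j] * p[k] * D[j, k] for j in range(n) for k in range(n))
        A = np.zeros((n, n))
        for j in range(n):
            for k in range(n):
                A[j, k] = D[j, k] - m[j] - m[k] + gm
        return A

    def v2(A, C):
        return sum(p[j] * p[k] * A[j, k] * C[j, k]
                   for j in range(n) for k in range(n))

    Ab, Af = center(dist(B)), center(dist(F))
    den = v2(Ab, Ab) * v2(Af, Af)
    return 0.0 if den <= eps else v2(Ab, Af) / np.sqrt(den)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("X, expected", [
    ([[0], [1]], [[0, 1], [1, 0]]),
    ([[0, 0], [3, 4]], [[0, 5], [5, 0]]),
    ([[0], [1], [2]], [[0, 1, 2], [1, 0, 1], [2, 1, 0]]),
])
def test_pairwise_distances_known_values(X, expected):
    assert np.allclose(dcor.pairwise_distances(X), expected)


def test_pairwise_distances_rejects_nonfinite_naming_row():
    X = np.array([[0.0], [np.nan], [1.0]])
    with pytest.raises(ValueError, match=r"\[1\]"):
        dcor.pairwise_distances(X)


def test_pairwise_distances_needs_two_samples():
    with pytest.raises(ValueError):
        dcor.pairwise_distances([[1.0]])


def test_double_center_two_point_case():
    A = dcor.double_center(np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert np.allclose(A, [[-0.5, 0.5], [0.5, -0.5]])


def test_double_center_zero_matrix_and_row_sums(rng):
    assert np.allclose(dcor.double_center(np.zeros((4, 4))), 0.0)
    X = rng.normal(size=(7, 3))
    A = dcor.double_center(dcor.pairwise_distances(X))
    assert np.abs(A.sum(axis=0)).max() < 1e-9
    assert np.abs(A.sum(axis=1)).max() < 1e-9


def test_double_center_rejects_nonsquare():
    with pytest.raises(ValueError):
        dcor.double_center(np.zeros((3, 4)))


def test_distance_covariance_examples(rng):
    A = dcor.double_center(np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert dcor.distance_covariance_sq(A, A) == pytest.approx(0.25)
    # constant sample -> zero matrix -> zero covariance
    Z = dcor.double_center(dcor.pairwise_distances(np.ones((5, 2))))
    assert dcor.distance_covariance_sq(Z, Z) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        dcor.distance_covariance_sq(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def test_oracle_equivalence_50_random_instances(rng):
    """Fast implementation vs naive double loop; n <= 64, d <= 5."""
    worst = 0.0
    for _ in range(50):
        n = int(rng.integers(3, 65))
        B = rng.normal(size=(n, int(rng.integers(1, 6))))
        F = rng.normal(size=(n, int(rng.integers(1, 6))))
        worst = max(worst, abs(dcor.distance_correlation_sq(B, F)
                               - naive_dcor_sq(B, F)))
    assert worst < 1e-10


def test_self_correlation_is_one(rng):
    X = rng.normal(size=(12, 3))
    assert dcor.distance_correlation_sq(X, X) == pytest.approx(1.0)


def test_constant_argument_hits_zero_branch(rng):
    F = rng.normal(size=(10, 2))
    assert dcor.distance_correlation_sq(np.full((10, 1), 3.0), F) == 0.0


def test_affine_invariance_and_symmetry(rng):
    B = rng.normal(size=(15, 2))
    F = rng.normal(size=(15, 3))
    base = dcor.distance_correlation_sq(B, F)
    assert dcor.distance_correlation_sq(3.0 * B + 7.0, F) == pytest.approx(base, abs=1e-9)
    assert dcor.distance_correlation_sq(-0.5 * B + 1.0, F) == pytest.approx(base, abs=1e-9)
    assert dcor.distance_correlation_sq(F, B) == pytest.approx(base, abs=1e-12)
    line = np.arange(10.0)
    assert dcor.distance_correlation_sq(line, 3 * line + 7) == pytest.approx(1.0)


def test_range_on_random_inputs(rng):
    for _ in range(30):
        n = int(rng.integers(2, 30))
        v = dcor.distance_correlation_sq(rng.normal(size=(n, 2)),
                                         rng.standard_cauchy(size=(n, 1)))
        assert 0.0 <= v <= 1.0


def test_independent_large_sample_near_zero():
    g = np.random.default_rng(2024)
    v = dcor.distance_correlation_sq(g.normal(size=(2000, 1)),
                                     g.normal(size=(2000, 1)))
    assert v < 0.01


# ---------------------------------------------------------------------------
# weighted variant
# ---------------------------------------------------------------------------

def test_weighted_uniform_reduces_to_unweighted(rng):
    B = rng.normal(size=(9, 2))
    F = rng.normal(size=(9, 2))
    base = dcor.distance_correlation_sq(B, F)
    assert dcor.weighted_distance_correlation_sq(B, F, np.ones(9)) == pytest.approx(base, abs=1e-14)
    assert dcor.weighted_distance_correlation_sq(B, F, np.full(9, 2.0)) == pytest.approx(base, abs=1e-14)


def test_weighted_matches_duplication(rng):
    B = rng.normal(size=(6, 2))
    F = rng.normal(size=(6, 3))
    w = np.ones(6)
    w[2] = 2.0
    dup = dcor.distance_correlation_sq(np.vstack([B, B[2]]), np.vstack([F, F[2]]))
    assert dcor.weighted_distance_correlation_sq(B, F, w) == pytest.approx(dup, abs=1e-12)


def test_weighted_oracle_equivalence(rng):
    for _ in range(10):
        n = int(rng.integers(3, 20))
        B = rng.normal(size=(n, 2))
        F = rng.normal(size=(n, 1))
        w = rng.random(n) + 0.2
        assert dcor.weighted_distance_correlation_sq(B, F, w) == pytest.approx(
            naive_dcor_sq(B, F, w), abs=1e-10)


def test_weighted_rejects_negative_weights(rng):
    with pytest.raises(ValueError):
        dcor.weighted_distance_correlation_sq(rng.normal(size=(4, 1)),
                                              rng.normal(size=(4, 1)),
                                              [1, 1, -1, 1])


# ---------------------------------------------------------------------------
# differentiable penalty
# ---------------------------------------------------------------------------

def test_penalty_value_matches_statistic(rng):
    B = rng.normal(size=(10, 2))
    F = rng.normal(size=(10, 3))
    pen = dcor.dcor_penalty(Tensor(F, requires_grad=True), B)
    assert float(pen.data) == pytest.approx(dcor.distance_correlation_sq(B, F),
                                            abs=1e-12)


def test_penalty_gradient_matches_finite_differences(rng):
    """Gradients flow through F; checked on a 4-sample toy."""
    B = rng.normal(size=(4, 1))
    F0 = rng.normal(size=(4, 2))
    Ft = Tensor(F0, requires_grad=True)
    pen = dcor.dcor_penalty(Ft, B, min_batch=4)
    pen.backward()
    eps = 1e-6
    for idx in [(0, 0), (1, 1), (3, 0)]:
        Fp, Fm = F0.copy(), F0.copy()
        Fp[idx] += eps
        Fm[idx] -= eps
        fd = (dcor.distance_correlation_sq(B, Fp)
              - dcor.distance_correlation_sq(B, Fm)) / (2 * eps)
        assert Ft.grad[idx] == pytest.approx(fd, abs=1e-5)


def test_penalty_treats_bias_as_constant(rng):
    """B never receives gradients, even if handed in as a tensor-backed array."""
    F = Tensor(rng.normal(size=(8, 2)), requires_grad=True)
    pen = dcor.dcor_penalty(F, rng.normal(size=(8, 1)))
    pen.backward()
    assert F.grad is not None and np.isfinite(F.grad).all()


def test_penalty_enforces_minimum_batch(rng):
    F = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
    with pytest.raises(ValueError, match="8"):
        dcor.dcor_penalty(F, rng.normal(size=(4, 1)))


def test_penalty_constant_bias_returns_zero(rng):
    F = Tensor(rng.normal(size=(8, 2)), requires_grad=True)
    pen = dcor.dcor_penalty(F, np.ones((8, 1)))
    assert float(pen.data) == 0.0
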