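"""Composite objectives: closed-form terms, breakdown consistency,
baseline reduction, and the control-only scanner penalty."""

import numpy as np
import pytest

from decorrnet import dcor
from decorrnet.models import ArchitectureSpec, FeatureTapSet, build_model
from decorrnet.objectives import (ClassBiasObjectiveSpec, ScannerObjectiveSpec,
                                  class_bias_objective, default_scanner_weights,
                                  l2_penalty, scanner_objective,
                                  weighted_cross_entropy)


@pytest.fixture
def small_model():
    spec = ArchitectureSpec(variant="classbias_dccnn", input_shape=(16, 16),
                            conv_filters=[4], fc_sizes=[8, 4])
    return build_model(spec, seed=0)


# ---------------------------------------------------------------------------
# weighted cross-entropy
# ---------------------------------------------------------------------------

def test_wce_closed_forms():
    y = [0, 1]
    perfect = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert weighted_cross_entropy(y, perfect) < 1e-6
    uniform = np.full((4, 2), 0.5)
    assert weighted_cross_entropy([0, 1, 0, 1], uniform) == pytest.approx(np.log(2))
    p = np.array([[0.7, 0.3], [0.2, 0.8], [0.6, 0.4]])
    assert weighted_cross_entropy([0, 1, 1], p, [1.0, 1.0]) == pytest.approx(
        weighted_cross_entropy([0, 1, 1], p))
    # minority emphasis scales its terms
    w = weighted_cross_entropy([0, 1], uniform[:2], [1.0, 3.0])
    assert w == pytest.approx(np.log(2) * 2.0)


def test_wce_rejects_bad_inputs():
    with pytest.raises(ValueError, match="sum to 1"):
        weighted_cross_entropy([0, 1], np.array([[0.9, 0.3], [0.5, 0.5]]))
    with pytest.raises(ValueError, match="labels"):
        weighted_cross_entropy([0, 2], np.full((2, 2), 0.5))


# ---------------------------------------------------------------------------
# L2
# ---------------------------------------------------------------------------

def test_l2_penalty_counts_only_decaying_weights(small_model):
    for p in small_model.parameters():
        p.data[:] = 0.0
    assert float(l2_penalty(small_model).data) == 0.0
    wp = [p for p in small_model.parameters() if p.decay]
    wp[0].data.flat[0] = 3.0
    wp[1].data.flat[0] = 2.0
    assert float(l2_penalty(small_model).data) == pytest.approx(13.0)
    # bias / normalization params are excluded
    bp = [p for p in small_model.parameters() if not p.decay]
    bp[0].data[:] = 100.0
    assert float(l2_penalty(small_model).data) == pytest.approx(13.0)


# ---------------------------------------------------------------------------
# class-bias objective
# ---------------------------------------------------------------------------

def test_class_bias_lambda_zero_is_wce_plus_l2(small_model, rng):
    batch = {"x": rng.random((6, 16, 16)), "y": np.array([0, 1, 1, 0, 1, 0])}
    spec = ClassBiasObjectiveSpec(lambda_dc=0.0, l2_coeff=0.01)
    loss, terms = class_bias_objective(batch, small_model, spec, None)
    assert terms["dc_term"] == 0.0
    assert float(loss.data) == pytest.approx(terms["wce"] + terms["l2"])


def test_class_bias_breakdown_sums_to_total(small_model, rng):
    n = 10
    batch = {"x": rng.random((n, 16, 16)), "y": rng.integers(0, 2, n)}
    B = rng.normal(size=(n, 1))
    spec = ClassBiasObjectiveSpec(lambda_dc=0.7, l2_coeff=0.01)
    loss, terms = class_bias_objective(batch, small_model, spec, B)
    assert terms["wce"] + terms["dc_term"] + terms["l2"] == pytest.approx(
        terms["total"], abs=1e-9)
    assert terms["total"] == pytest.approx(float(loss.data))


def test_class_bias_feature_equals_bias_gives_full_penalty(small_model, rng):
    """F proportional to B -> DC^2 = 1, so the DC term contributes lambda."""
    n = 10
    batch = {"x": rng.random((n, 16, 16)), "y": rng.integers(0, 2, n)}
    _, acts = small_model.forward(batch["x"])
    F = acts["fc2"].data   # use the model's own features as "bias"
    spec = ClassBiasObjectiveSpec(lambda_dc=0.4)
    _, terms = class_bias_objective(batch, small_model, spec, 3.0 * F + 1.0,
                                    taps=FeatureTapSet(["fc2"]))
    assert terms["dc2"] == pytest.approx(1.0, abs=1e-9)
    assert terms["dc_term"] == pytest.approx(0.4, abs=1e-9)


def test_class_bias_small_batch_skips_penalty(small_model, rng):
    batch = {"x": rng.random((4, 16, 16)), "y": np.array([0, 1, 0, 1])}
    spec = ClassBiasObjectiveSpec(lambda_dc=0.5)
    _, terms = class_bias_objective(batch, small_model, spec,
                                    rng.normal(size=(4, 1)))
    assert terms["dc_skipped"] and terms["dc_term"] == 0.0


def test_monotone_in_lambda(small_model, rng):
    n = 12
    batch = {"x": rng.random((n, 16, 16)), "y": rng.integers(0, 2, n)}
    _, acts = small_model.forward(batch["x"])
    B = acts["fc1"].data[:, :2]    # correlated with features -> DC^2 > 0
    totals = []
    for lam in (0.1, 0.5, 2.0):
        _, terms = class_bias_objective(batch, small_model,
                                        ClassBiasObjectiveSpec(lambda_dc=lam), B)
        assert terms["dc2"] > 0
        totals.append(terms["total"])
    assert totals[0] < totals[1] < totals[2]


# ---------------------------------------------------------------------------
# scanner objective
# ---------------------------------------------------------------------------

def _scanner_batch(rng, n_ctrl, n_pat):
    n = n_ctrl + n_pat
    return {"x": rng.random((n, 16, 16)),
            "y": np.array([0] * n_ctrl + [1] * n_pat),
            "scanner": np.array(["A", "B"] * (n_ctrl // 2) + ["A"] * (n_ctrl % 2)
                                + ["A"] * n_pat)}


def test_scanner_objective_no_controls_skips_penalty(small_model, rng):
    batch = {"x": rng.random((6, 16, 16)), "y": np.ones(6, dtype=int),
             "scanner": np.array(["A"] * 6)}
    spec = ScannerObjectiveSpec(lambda1=0.5, lambda2=5.0)
    loss, terms = scanner_objective(batch, small_model, spec,
                                    rng.normal(size=(6, 3)))
    assert terms["dc_skipped"] and terms["n_control"] == 0
    assert float(loss.data) == pytest.approx(terms["ce"] + terms["l2"])


def test_scanner_objective_uniform_weights_match_unweighted(small_model, rng):
    batch = _scanner_batch(rng, 10, 4)
    B = rng.normal(size=(14, 2))
    ctrl = batch["y"] == 0
    specw = ScannerObjectiveSpec(lambda1=1.0, lambda2=1.0,
                                 scanner_weights={"A": 1.0, "B": 1.0})
    _, terms = scanner_objective(batch, small_model, specw, B)
    _, acts = small_model.forward(batch["x"])
    from decorrnet.models import features_from_acts
    F = features_from_acts(acts, FeatureTapSet.default_for("classbias_dccnn")).data
    expect = dcor.distance_correlation_sq(B[ctrl], F[ctrl])
    assert terms["dc2"] == pytest.approx(expect, abs=1e-9)


def test_scanner_objective_scanner_coded_features_give_full_penalty(small_model, rng):
    batch = _scanner_batch(rng, 10, 4)
    scan = batch["scanner"][batch["y"] == 0]
    onehot = np.stack([(scan == "A").astype(float), (scan == "B").astype(float)], 1)
    B = np.zeros((14, 2))
    B[batch["y"] == 0] = onehot
    spec = ScannerObjectiveSpec(lambda1=0.5, lambda2=2.0)
    # features == scanner one-hot: patch taps via a crafted bias equal to F
    _, terms = scanner_objective(batch, small_model, spec, B,
                                 taps=FeatureTapSet(["softmax"]))
    # oracle: dCor of the model's control softmax vs scanner coding
    _, acts = small_model.forward(batch["x"])
    expect = dcor.distance_correlation_sq(onehot,
                                          acts["softmax"].data[batch["y"] == 0])
    assert terms["dc2"] == pytest.approx(expect, abs=1e-9)


def test_scanner_objective_missing_scanner_id_rejected(small_model, rng):
    batch = _scanner_batch(rng, 10, 2)
    batch["scanner"] = batch["scanner"].astype(object)
    batch["scanner"][0] = None
    spec = ScannerObjectiveSpec(lambda1=0.5, lambda2=1.0)
    with pytest.raises(ValueError, match="missing scanner"):
        scanner_objective(batch, small_model, spec, rng.normal(size=(12, 2)))


def test_default_scanner_weights_inverse_frequency():
    w = default_scanner_weights(["A"] * 9 + ["B"])
    assert w["B"] / w["A"] == pytest.approx(9.0)
    assert np.mean(list(w.values())) == pytest.approx(1.0)
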