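"""Training loop contracts: LR policies, determinism, penalty logging,
baseline reduction, split integrity, run intervals."""

import numpy as np
import pytest

from decorrnet import dcor
from decorrnet.models import ArchitectureSpec, FeatureTapSet, extract_features
from decorrnet.objectives import ClassBiasObjectiveSpec, ScannerObjectiveSpec
from decorrnet.training import (TrainConfig, dummy_bias_builder,
                                exp_cyclical_lr, run_interval, step_decay_lr,
                                subject_split, train_model, train_multi,
                                voxel_bias_builder)


@pytest.fixture(scope="module")
def splits(tiny_cohort):
    idx = subject_split(tiny_cohort.manifest, seed=3)
    return {k: tiny_cohort.take(v) for k, v in idx.items()}


def _quick_cfg(objective, seed=0, epochs=2, **kw):
    return TrainConfig(objective=objective, batch_size=16, epochs=epochs,
                       seed=seed, lr_policy="step_decay",
                       lr_params={"initial_lr": 1e-3}, **kw)


def _tiny_arch():
    return ArchitectureSpec(variant="classbias_dccnn", input_shape=(24, 24),
                            conv_filters=[4], fc_sizes=[8, 4])


# ---------------------------------------------------------------------------
# LR policies
# ---------------------------------------------------------------------------

def test_exp_cyclical_lr_shape():
    assert exp_cyclical_lr(0, 1e-4, 1e-2, 100, 1.0) == pytest.approx(1e-4)
    assert exp_cyclical_lr(100, 1e-4, 1e-2, 100, 1.0) == pytest.approx(1e-2)
    # gamma < 1: successive cycle peaks decay strictly
    p1 = exp_cyclical_lr(100, 1e-4, 1e-2, 100, 0.999)
    p2 = exp_cyclical_lr(300, 1e-4, 1e-2, 100, 0.999)
    assert p2 < p1
    with pytest.raises(ValueError):
        exp_cyclical_lr(0, 1e-2, 1e-4, 100, 1.0)


def test_step_decay_lr():
    assert step_decay_lr(0, 1e-3, 0.5, 5) == pytest.approx(1e-3)
    assert step_decay_lr(10, 1e-3, 0.5, 5) == pytest.approx(2.5e-4)


# ---------------------------------------------------------------------------
# run interval
# ---------------------------------------------------------------------------

def test_run_interval_closed_forms():
    mean, half = run_interval([1.0, 1.0, 1.0])
    assert (mean, half) == (1.0, 0.0)
    mean, half = run_interval([0.0, 1.0, 2.0])
    assert mean == pytest.approx(1.0)
    assert half == pytest.approx(4.302652 / np.sqrt(3), rel=1e-4)
    _, half2 = run_interval([0.0, 1.0])
    assert half2 == pytest.approx(12.7062 * np.sqrt(0.5) / np.sqrt(2), rel=1e-3)
    mean_only, nan_half = run_interval([5.0])
    assert mean_only == 5.0 and np.isnan(nan_half)


# ---------------------------------------------------------------------------
# training determinism and reduction
# ---------------------------------------------------------------------------

def test_training_is_bitwise_deterministic(splits):
    cfg = _quick_cfg(ClassBiasObjectiveSpec(lambda_dc=0.0), seed=11)
    r1 = train_model(splits["train"], splits["val"], _tiny_arch(), cfg)
    r2 = train_model(splits["train"], splits["val"], _tiny_arch(), cfg)
    assert np.array_equal(r1.log["total"].to_numpy(), r2.log["total"].to_numpy())
    for p1, p2 in zip(r1.model.parameters(), r2.model.parameters()):
        assert np.array_equal(p1.data, p2.data)


def test_lambda_zero_matches_degenerate_penalty_bitwise(splits):
    """λ=0 and an always-zero penalty (constant bias) give identical
    loss trajectories: the decorrelated objective reduces to the baseline."""
    base_cfg = _quick_cfg(ClassBiasObjectiveSpec(lambda_dc=0.0, l2_coeff=1e-3),
                          seed=21)
    pen_cfg = _quick_cfg(ClassBiasObjectiveSpec(lambda_dc=0.4, l2_coeff=1e-3),
                         seed=21)
    constant_bias = lambda ds, epoch: np.ones((len(ds), 1))
    r_base = train_model(splits["train"], splits["val"], _tiny_arch(), base_cfg)
    r_pen = train_model(splits["train"], splits["val"], _tiny_arch(), pen_cfg,
                        bias_builder=constant_bias)
    assert np.array_equal(r_base.log["total"].to_numpy(),
                          r_pen.log["total"].to_numpy())
    for p1, p2 in zip(r_base.model.parameters(), r_pen.model.parameters()):
        assert np.array_equal(p1.data, p2.data)


def test_logged_dc_term_matches_offline_recomputation(splits):
    """The logged DC² equals the statistic recomputed on the same batch."""
    train = splits["train"]
    cfg = TrainConfig(objective=ClassBiasObjectiveSpec(lambda_dc=0.5),
                      batch_size=len(train), epochs=1, seed=2,
                      lr_policy="step_decay", lr_params={"initial_lr": 1e-9})
    builder = dummy_bias_builder(10, 2, base_seed=2)
    res = train_model(train, splits["val"], _tiny_arch(), cfg, builder)
    row = res.log.iloc[0]
    # reproduce the batch: full-batch training, first iteration, epoch 0
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(len(train))
    model2 = train_model(train, splits["val"], _tiny_arch(),
                         _quick_cfg(ClassBiasObjectiveSpec(0.0), seed=2,
                                    epochs=0)).model
    model2.train()
    F = extract_features(model2, train.images[order],
                         FeatureTapSet.default_for("classbias_dccnn")).data
    B = builder(train, 0)[order]
    dc2 = dcor.distance_correlation_sq(B, F)
    assert row["dc2"] == pytest.approx(dc2, abs=1e-6)
    assert row["dc_term"] == pytest.approx(0.5 * dc2, abs=1e-6)


def test_scanner_training_with_voxel_bias(tiny_multiscanner):
    idx = subject_split(tiny_multiscanner.manifest, seed=5)
    parts = {k: tiny_multiscanner.take(v) for k, v in idx.items()}
    spec = ScannerObjectiveSpec(lambda1=0.5, lambda2=2.0,
                                scanner_weights={"scannerA": 1.5, "scannerB": 0.5})
    arch = ArchitectureSpec(variant="scanner_dccnn", input_shape=(24, 24),
                            conv_filters=[4, 4], fc_sizes=[8, 4])
    cfg = _quick_cfg(spec, seed=1, epochs=1)
    res = train_model(parts["train"], parts["val"], arch, cfg,
                      voxel_bias_builder(), FeatureTapSet(["fc1", "fc2"]))
    assert res.model.trained
    assert {"ce", "dc2", "n_control"} <= set(res.log.columns)


def test_penalty_without_builder_rejected(splits):
    cfg = _quick_cfg(ClassBiasObjectiveSpec(lambda_dc=0.5))
    with pytest.raises(ValueError, match="bias_builder"):
        train_model(splits["train"], splits["val"], _tiny_arch(), cfg)


def test_train_multi_returns_distinct_seeded_runs(splits):
    cfg = _quick_cfg(ClassBiasObjectiveSpec(lambda_dc=0.0), epochs=1)
    cfg.n_runs = 2
    results = train_multi(splits["train"], splits["val"], _tiny_arch(), cfg)
    assert len(results) == 2
    assert results[0].seed != results[1].seed


def test_temporal_model_trains_on_frame_sequences():
    """ConvGRU front end + temporal-std bias variable, end to end."""
    from decorrnet import synthetic
    from decorrnet.bias_variables import temporal_std_bias
    from decorrnet.training import constant_bias_builder

    spec = synthetic.CohortSpec(image_size=(16, 16), slices_per_subject=2,
                                volumes_per_subject=3, seed=21)
    ds = synthetic.generate_multiscanner(spec, n_patient_a=4, n_control_a=2,
                                         n_control_b=4)
    idx = subject_split(ds.manifest, seed=2)
    parts = {k: ds.take(v) for k, v in idx.items()}
    arch = ArchitectureSpec(variant="convgru_dccnn", input_shape=(3, 16, 16),
                            conv_filters=[4, 4], fc_sizes=[8, 4], gru_hidden=2)
    bias = temporal_std_bias(parts["train"].frames, pool=4)
    cfg = TrainConfig(objective=ScannerObjectiveSpec(lambda1=0.2, lambda2=0.6),
                      batch_size=len(parts["train"]), epochs=1, seed=3,
                      lr_policy="step_decay", lr_params={"initial_lr": 1e-3})
    res = train_model(parts["train"], parts["val"], arch, cfg,
                      constant_bias_builder(bias.values),
                      FeatureTapSet(["conv2", "fc1"]))
    assert res.model.trained
    assert np.isfinite(res.log["total"]).all()


def test_fe_feature_pipeline_provides_scanner_bias():
    """FE model trained on the scanner task feeds the FE-DcCNN objective."""
    from decorrnet import synthetic
    from decorrnet.bias_variables import fe_feature_bias
    from decorrnet.training import constant_bias_builder

    spec = synthetic.CohortSpec(image_size=(32, 32), slices_per_subject=2,
                                class_effect_amplitude=0.0, seed=23)
    ds = synthetic.generate_multiscanner(spec, n_patient_a=0, n_control_a=6,
                                         n_control_b=6)
    # scanner-classification task: relabel classes by scanner
    ds.manifest["class"] = (ds.scanners == "scannerB").astype(int)
    idx = subject_split(ds.manifest, seed=4)
    parts = {k: ds.take(v) for k, v in idx.items()}
    fe_arch = ArchitectureSpec(variant="fe_model", input_shape=(32, 32),
                               conv_filters=[4, 4, 4, 4, 4], fc_sizes=[8, 4])
    cfg = TrainConfig(objective=ClassBiasObjectiveSpec(lambda_dc=0.0),
                      batch_size=16, epochs=2, seed=5,
                      lr_policy="step_decay", lr_params={"initial_lr": 1e-3})
    fe = train_model(parts["train"], parts["val"], fe_arch, cfg)
    B = fe_feature_bias(fe.model, parts["train"].images)
    assert B.values.shape[0] == len(parts["train"])
    builder = constant_bias_builder(B.values)
    # downstream model decorrelates against the frozen FE features
    arch = ArchitectureSpec(variant="fe_dccnn", input_shape=(32, 32),
                            conv_filters=[4, 4, 4, 4, 4], fc_sizes=[8, 4])
    cfg2 = TrainConfig(objective=ScannerObjectiveSpec(lambda1=0.5, lambda2=1.0,
                                                      control_label=0),
                       batch_size=len(parts["train"]), epochs=1, seed=6,
                       lr_policy="step_decay", lr_params={"initial_lr": 1e-3})
    res = train_model(parts["train"], parts["val"], arch, cfg2, builder,
                      FeatureTapSet(["conv5", "fc1", "fc2"]))
    assert res.log["dc2"].iloc[0] >= 0.0
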