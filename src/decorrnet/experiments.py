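"""Prebuilt desk-scale experiments: the class-bias suite and the
scanner-bias suite on synthetic fixtures.

These functions reproduce, at laptop scale and on synthetic phantom data,
the two study designs the method targets:

* :func:`class_bias_suite` — a single-scanner cohort with 9:1
  patient:control imbalance.  A plain CNN trained on it collapses to the
  majority class; classical resampling baselines (ROS, SMOTE, stratified,
  feature-space SMOTE, weighted loss) help only partially; the proposed
  fusion pipeline (oversampling + weighted cross-entropy + dummy-class
  decorrelation, trained with the augmented protocol) balances
  sensitivity and specificity.
* :func:`scanner_bias_suite` — a two-scanner cohort where patients appear
  on one scanner only.  A plain CNN's features identify the scanner
  almost perfectly (the shortcut); the control-only decorrelation
  objective removes most of that scanner information at a modest cost in
  class accuracy.

Cohort sizes, image size, epochs, and architecture widths here are the
package's desk-scale defaults: large enough for the phenomena to be
stable across seeded reruns, small enough to run on one CPU core in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import evaluation as ev
from . import synthetic
from .dataio import SliceDataset
from .models import ArchitectureSpec, FeatureTapSet, extract_features
from .objectives import (ClassBiasObjectiveSpec, ScannerObjectiveSpec,
                         default_scanner_weights)
from .sampling import inverse_frequency_weights, smote_oversample
from .training import (TrainConfig, dummy_bias_builder, train_model,
                       voxel_bias_builder)

__all__ = ["ClassBiasConfig", "class_bias_suite", "oversample_indices",
           "ScannerBiasConfig", "scanner_bias_suite", "smote_dataset"]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def oversample_indices(labels, seed: int) -> np.ndarray:
    """Row indices realizing random oversampling to balanced class counts."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    idx = [np.arange(len(y))]
    for cls, cnt in zip(classes, counts):
        if cnt < n_max:
            pool = np.flatnonzero(y == cls)
            idx.append(rng.choice(pool, size=n_max - cnt, replace=True))
    return np.concatenate(idx)


def smote_dataset(ds: SliceDataset, k: int = 5, seed: int = 0) -> SliceDataset:
    """Append SMOTE-interpolated minority slice images to a dataset."""
    synth, labels = smote_oversample(ds.images, ds.labels, k=k, seed=seed)
    rows = []
    template = ds.manifest[ds.manifest["class"] == labels[0]].iloc[0].to_dict()
    for i in range(len(synth)):
        row = dict(template)
        row.update(subject_id=f"smote{i:05d}", slice_idx=0, volume_idx=0, path="")
        rows.append(row)
    manifest = pd.concat([ds.manifest, pd.DataFrame(rows)], ignore_index=True)
    return SliceDataset(np.concatenate([ds.images, np.clip(synth, 0, 1)]),
                        manifest)


def _predict_table(model, ds: SliceDataset) -> pd.DataFrame:
    proba = model.predict_proba(ds.images)
    return pd.DataFrame({"subject_id": ds.subjects,
                         "scanner_id": ds.scanners,
                         "y_true": ds.labels,
                         "y_pred": proba.argmax(axis=1),
                         "proba_positive": proba[:, 1]})


def _subject_metrics(table: pd.DataFrame) -> ev.EvalReport:
    votes = ev.max_wins_vote(table)
    return ev.confusion_metrics(votes["y_true"], votes["y_pred"], level="subject")


# ---------------------------------------------------------------------------
# class-bias suite
# ---------------------------------------------------------------------------

@dataclass
class ClassBiasConfig:
    """Desk-scale study conditions for the imbalanced single-scanner design."""
    image_size: tuple = (32, 32)
    slices_per_subject: int = 5
    n_patients: int = 135            # ~9:1 subject imbalance
    n_controls: int = 15
    n_val: int = 30                  # subjects per class, validation cohort
    n_test: int = 50                 # subjects per class, held-out cohort
    class_effect_amplitude: float = 0.16
    subject_texture_sigma: float = 0.12
    noise_sigma: float = 0.12
    conv_filters: list = field(default_factory=lambda: [8, 16, 16])
    fc_sizes: list = field(default_factory=lambda: [32, 16])
    epochs: int = 18               # baseline/resampling training length
    fusion_epochs: int = 50        # the fusion protocol anneals longer
    batch_size: int = 256
    lambda_dc: float = 1.0
    n_runs: int = 3
    seed: int = 0

    def cohort(self, n_pd: int, n_hc: int, seed: int) -> SliceDataset:
        h, w = self.image_size
        spec = synthetic.CohortSpec(
            image_size=self.image_size,
            slices_per_subject=self.slices_per_subject,
            class_effect_amplitude=self.class_effect_amplitude,
            subject_texture_sigma=self.subject_texture_sigma,
            class_effect_region=(int(0.40 * h), int(0.60 * w), h / 6.0),
            seed=seed)
        base, _ = synthetic.default_profiles()
        prof = synthetic.ScannerProfile(
            "scannerA", base.smoothing_sigma, base.gain, self.noise_sigma,
            base.temporal_noise_sigma, base.slice_thickness_mm,
            base.pixel_spacing_mm)
        return synthetic.generate_singlescanner_imbalanced(
            spec, self.n_patients if n_pd is None else n_pd, n_hc, profile=prof)

    def arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(variant="classbias_dccnn",
                                input_shape=self.image_size,
                                conv_filters=list(self.conv_filters),
                                fc_sizes=list(self.fc_sizes))


def _cb_train(cfg: ClassBiasConfig, train_ds, val_ds, seed, lam,
              weights=None, augment=False, taps=None, epochs=None):
    ocfg = TrainConfig(
        objective=ClassBiasObjectiveSpec(lambda_dc=lam, class_weights=weights,
                                         l2_coeff=1e-3),
        optimizer="rmsprop", batch_size=cfg.batch_size,
        epochs=cfg.epochs if epochs is None else epochs,
        seed=seed, lr_policy="exp_cyclical",
        lr_params={"base_lr": 2e-4, "max_lr": 2e-3, "half_cycle": 50,
                   "gamma": 0.9975},
        augment=augment, checkpoint_metric="min_class_accuracy", eval_every=2)
    builder = (dummy_bias_builder(10, 2, base_seed=seed, majority_label=1)
               if lam > 0 else None)
    return train_model(train_ds, val_ds, cfg.arch(), ocfg, builder, taps)


def class_bias_suite(cfg: ClassBiasConfig | None = None,
                     methods: tuple = ("baseline", "ros", "smote",
                                       "fe_smote", "stratified",
                                       "ros_weighted", "fusion")) -> dict:
    """Train the method suite on the imbalanced fixture; subject-level metrics.

    Baselines run the plain training protocol; the fusion pipeline
    (ROS + weighted CE + decorrelation) runs the full proposed protocol
    including augmentation.  Every method is retrained ``cfg.n_runs`` times;
    reported sensitivity/specificity are means across runs.  Returns
    ``{method: {"sensitivity", "specificity", "balanced_accuracy",
    "runs", "logs"}}``.
    """
    cfg = cfg or ClassBiasConfig()
    train_ds = cfg.cohort(cfg.n_patients, cfg.n_controls, cfg.seed + 17)
    val_ds = cfg.cohort(cfg.n_val, cfg.n_val, cfg.seed + 29)
    test_ds = cfg.cohort(cfg.n_test, cfg.n_test, cfg.seed + 43)
    out: dict = {}
    for method in methods:
        if method == "ros_weighted" and "ros" in out:
            # unity class weights after ROS make the objective identical to
            # plain ROS, so the trained models coincide run for run
            out["ros_weighted"] = dict(out["ros"])
            continue
        reports, logs = [], []
        for r in range(cfg.n_runs):
            seed = (cfg.seed + 101 * r + 7) % (2 ** 31)
            tr, lam, weights, augment = train_ds, 0.0, None, False
            if method in ("ros", "ros_weighted", "fusion"):
                tr = train_ds.take(oversample_indices(train_ds.labels, seed))
            if method == "stratified":
                tr = train_ds.take(oversample_indices(train_ds.labels, seed + 1))
            if method == "smote":
                tr = smote_dataset(train_ds, seed=seed)
            if method in ("ros_weighted", "fusion"):
                weights = inverse_frequency_weights(tr.labels)  # unity after ROS
            if method == "fusion":
                lam, augment = cfg.lambda_dc, True
            if method == "fe_smote":
                reports.append(_fe_smote(cfg, train_ds, val_ds, test_ds, seed))
                continue
            res = _cb_train(cfg, tr, val_ds, seed, lam, weights, augment,
                            epochs=cfg.fusion_epochs if method == "fusion" else None)
            table = _predict_table(res.model, test_ds)
            reports.append(_subject_metrics(table))
            logs.append(res.log)
        sens = float(np.mean([r.sensitivity for r in reports]))
        spec = float(np.mean([r.specificity for r in reports]))
        out[method] = {"sensitivity": sens, "specificity": spec,
                       "balanced_accuracy": (sens + spec) / 2.0,
                       "runs": reports, "logs": logs}
    return out


def _fe_smote(cfg: ClassBiasConfig, train_ds, val_ds, test_ds, seed):
    """Feature-extraction + SMOTE baseline: plain CNN features, SMOTE in
    feature space, balanced linear head."""
    res = _cb_train(cfg, train_ds, val_ds, seed, 0.0)
    taps = FeatureTapSet(["fc2"])
    def feats(ds):
        return extract_features(res.model, ds.images, taps).data
    Xtr, ytr = feats(train_ds), train_ds.labels
    synth, ylab = smote_oversample(Xtr, ytr, k=5, seed=seed)
    Xb = np.concatenate([Xtr, synth])
    yb = np.concatenate([ytr, ylab])
    head = LogisticRegression(max_iter=2000, random_state=seed).fit(Xb, yb)
    proba = head.predict_proba(feats(test_ds))
    table = pd.DataFrame({"subject_id": test_ds.subjects,
                          "y_true": test_ds.labels,
                          "y_pred": proba.argmax(axis=1),
                          "proba_positive": proba[:, 1]})
    return _subject_metrics(table)


# ---------------------------------------------------------------------------
# scanner-bias suite
# ---------------------------------------------------------------------------

@dataclass
class ScannerBiasConfig:
    """Desk-scale study conditions for the confounded two-scanner design."""
    image_size: tuple = (32, 32)
    slices_per_subject: int = 5
    n_patient_a: int = 40
    n_control_a: int = 4
    n_control_b: int = 36
    n_test: int = 20                 # per (class, scanner) where available
    class_effect_amplitude: float = 0.16
    subject_texture_sigma: float = 0.10
    conv_filters: list = field(default_factory=lambda: [8, 16, 16])
    fc_sizes: list = field(default_factory=lambda: [40, 16])
    epochs: int = 16
    batch_size: int = 128
    lambda1: float = 0.5
    lambda2: float = 7.5
    n_runs: int = 3
    seed: int = 0
    scanner_null: bool = False       # identical profiles on both scanners

    def profiles(self):
        a, b = synthetic.default_profiles()
        if self.scanner_null:
            b = synthetic.ScannerProfile("scannerB", a.smoothing_sigma, a.gain,
                                         a.noise_sigma, a.temporal_noise_sigma,
                                         a.slice_thickness_mm,
                                         a.pixel_spacing_mm)
        return a, b

    def _spec(self, seed: int) -> synthetic.CohortSpec:
        h, w = self.image_size
        return synthetic.CohortSpec(
            image_size=self.image_size,
            slices_per_subject=self.slices_per_subject,
            class_effect_amplitude=self.class_effect_amplitude,
            subject_texture_sigma=self.subject_texture_sigma,
            class_effect_region=(int(0.40 * h), int(0.60 * w), h / 6.0),
            seed=seed)

    def train_cohort(self) -> SliceDataset:
        return synthetic.generate_multiscanner(
            self._spec(self.seed + 17), self.n_patient_a, self.n_control_a,
            self.n_control_b, profiles=self.profiles())

    def eval_cohort(self, seed_offset: int) -> SliceDataset:
        """Held-out cohort, class-balanced and scanner-balanced among
        controls, patients still only on scanner A (the design's constraint)."""
        n = self.n_test
        return synthetic.generate_multiscanner(
            self._spec(self.seed + seed_offset), n_patient_a=2 * n,
            n_control_a=n, n_control_b=n, profiles=self.profiles())

    def arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(variant="scanner_dccnn",
                                input_shape=self.image_size,
                                conv_filters=list(self.conv_filters),
                                fc_sizes=list(self.fc_sizes))


def scanner_bias_suite(cfg: ScannerBiasConfig | None = None,
                       methods: tuple = ("baseline", "dccnn")) -> dict:
    """Train baseline CNN and scanner-DcCNN on the confounded fixture.

    Reports subject-level class accuracy (on a class-balanced held-out
    cohort where a null classifier scores 50%), the scanner-probe accuracy
    on held-out control features, and per-scanner error rates; means
    across ``cfg.n_runs`` seeded reruns.
    """
    cfg = cfg or ScannerBiasConfig()
    train_ds = cfg.train_cohort()
    val_ds = cfg.eval_cohort(29)
    test_ds = cfg.eval_cohort(43)
    ctrl_mask = test_ds.labels == 0
    taps = FeatureTapSet(["fc1", "fc2"])
    out: dict = {}
    for method in methods:
        accs, probes, errs, logs = [], [], [], []
        for r in range(cfg.n_runs):
            seed = (cfg.seed + 101 * r + 7) % (2 ** 31)
            lam2 = cfg.lambda2 if method == "dccnn" else 0.0
            ctrl_tr = train_ds.labels == 0
            spec = ScannerObjectiveSpec(
                lambda1=cfg.lambda1 if method == "dccnn" else 1.0,
                lambda2=lam2, control_label=0,
                scanner_weights=default_scanner_weights(
                    train_ds.scanners[ctrl_tr]) if lam2 > 0 else {},
                l2_coeff=1e-3)
            ocfg = TrainConfig(objective=spec, optimizer="rmsprop",
                               batch_size=cfg.batch_size, epochs=cfg.epochs,
                               seed=seed, lr_policy="exp_cyclical",
                               lr_params={"base_lr": 2e-4, "max_lr": 2e-3,
                                          "half_cycle": 50, "gamma": 0.9975})
            builder = voxel_bias_builder() if lam2 > 0 else None
            res = train_model(train_ds, val_ds, cfg.arch(), ocfg, builder,
                              taps if lam2 > 0 else None)
            table = _predict_table(res.model, test_ds)
            votes = ev.max_wins_vote(table)
            accs.append(float(100.0 * (votes["y_pred"] == votes["y_true"]).mean()))
            errs.append(ev.per_dataset_error_rate(
                votes["y_true"], votes["y_pred"],
                table.groupby("subject_id", sort=True)["scanner_id"].first()))
            F = extract_features(res.model, test_ds.images[ctrl_mask],
                                 FeatureTapSet(["fc1", "fc2"])).data
            probes.append(ev.scanner_probe_accuracy(
                F, test_ds.scanners[ctrl_mask], test_ds.subjects[ctrl_mask],
                seed=seed))
            logs.append(res.log)
        out[method] = {
            "class_accuracy": float(np.mean(accs)),
            "scanner_probe_accuracy": float(np.nanmean(probes)),
            "probe_runs": probes, "accuracy_runs": accs,
            "per_scanner_error": {k: float(np.mean([e[k] for e in errs]))
                                  for k in errs[0]},
            "logs": logs}
    return out
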