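"""Metrics, subject-level vote aggregation, and bias audits.

Confusion metrics follow the usual conventions with the patient class as
positive: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), balanced accuracy (sens+spec)/2, F1 = 2·prec·sens/(prec+sens);
all reported as percentages.  Metrics whose denominator is empty are
``nan`` (undefined), never 0.

Bias audits:

* :func:`scanner_probe_accuracy` — a linear probe on frozen features of
  held-out controls, predicting the scanner; high accuracy means the
  features still carry scanner information.
* :func:`per_dataset_error_rate` — 1 − accuracy per scanner/dataset.
* :func:`embedding_export` — seeded 2-D t-SNE of features with a scanner
  silhouette score as the quantitative companion.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.model_selection import GroupShuffleSplit

__all__ = ["EvalReport", "confusion_metrics", "max_wins_vote",
           "scanner_probe_accuracy", "per_dataset_error_rate",
           "embedding_export", "roc_table"]


@dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float
    accuracy: float
    f1: float
    level: str = "slice"            # {slice, subject}

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(y_true, y_pred, positive_class: int = 1,
                      level: str = "slice") -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_class
    neg = ~pos
    tp = int((y_pred[pos] == positive_class).sum())
    fn = int(pos.sum()) - tp
    tn = int((y_pred[neg] != positive_class).sum())
    fp = int(neg.sum()) - tn

    def rate(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sens = rate(tp, tp + fn)
    spec = rate(tn, tn + fp)
    prec = rate(tp, tp + fp)
    ba = (sens + spec) / 2.0
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    acc = rate(tp + tn, len(y_true))
    return EvalReport(sens, spec, prec, ba, acc, f1, level)


def max_wins_vote(slice_table: pd.DataFrame, positive_class: int = 1,
                  proba_col: str = "proba_positive") -> pd.DataFrame:
    """Subject label by majority vote over slice predictions.

    ``slice_table`` needs columns ``subject_id``, ``y_pred`` and (for
    deterministic tie-breaking) ``proba_positive``; ties go to the class
    with the higher mean positive-class probability.  Returns one row per
    subject with the vote tally.  Pure function of the table; slice order
    is irrelevant.
    """
    if slice_table.empty:
        raise ValueError("no slice predictions given")
    out = []
    for subject, grp in slice_table.groupby("subject_id", sort=True):
        votes = grp["y_pred"].value_counts()
        n_pos = int(votes.get(positive_class, 0))
        n_neg = int(len(grp) - n_pos)
        if n_pos > n_neg:
            label = positive_class
        elif n_pos < n_neg:
            label = 1 - positive_class
        else:
            mean_p = float(grp[proba_col].mean()) if proba_col in grp else 0.5
            label = positive_class if mean_p >= 0.5 else 1 - positive_class
        row = {"subject_id": subject, "y_pred": label,
               "votes_positive": n_pos, "votes_negative": n_neg,
               "n_slices": len(grp)}
        if "y_true" in grp:
            row["y_true"] = int(grp["y_true"].iloc[0])
        out.append(row)
    return pd.DataFrame(out)


def scanner_probe_accuracy(features: np.ndarray, scanner_ids, subject_ids,
                           seed: int = 0) -> float:
    """Accuracy (%) of a linear probe predicting the scanner from features.

    Train/test is a 70/30 subject-grouped split; returns ``nan`` (undefined)
    when only one scanner is present.
    """
    X = np.asarray(features, dtype=np.float64)
    scanner_ids = np.asarray(scanner_ids)
    subject_ids = np.asarray(subject_ids)
    if len(np.unique(scanner_ids)) < 2:
        return float("nan")
    gss = GroupShuffleSplit(n_splits=1, test_size=0.3, random_state=seed)
    tr, te = next(gss.split(X, scanner_ids, groups=subject_ids))
    if len(np.unique(scanner_ids[tr])) < 2:
        return float("nan")
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(X[tr], scanner_ids[tr])
    return float(100.0 * (probe.predict(X[te]) == scanner_ids[te]).mean())


def per_dataset_error_rate(y_true, y_pred, dataset_ids) -> dict:
    """1 − accuracy restricted to each dataset's (scanner's) samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    ds = np.asarray(dataset_ids)
    out = {}
    for d in np.unique(ds):
        m = ds == d
        out[d] = float(1.0 - (y_true[m] == y_pred[m]).mean())
    return out


def embedding_export(features: np.ndarray, labels, scanner_ids,
                     seed: int = 0, perplexity: float = 15.0) -> tuple:
    """Seeded 2-D t-SNE table (x, y, class, scanner) + scanner silhouette.

    The silhouette score on the embedding (grouped by scanner) quantifies
    what the plot shows: near 0 means the scanners are mixed, large
    positive means scanner clusters persist.
    """
    X = np.asarray(features, dtype=np.float64)
    if len(X) < 10:
        raise ValueError("need at least 10 samples to embed")
    if perplexity >= len(X):
        raise ValueError(f"perplexity {perplexity} needs > {perplexity} samples; "
                         "reduce perplexity or add samples")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(X)
    table = pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1],
                          "class": np.asarray(labels),
                          "scanner": np.asarray(scanner_ids)})
    sil = (float(silhouette_score(emb, table["scanner"]))
           if len(np.unique(scanner_ids)) > 1 else float("nan"))
    return table, sil


def roc_table(y_true, scores) -> tuple[pd.DataFrame, float]:
    """Threshold sweep (FPR, TPR) and trapezoid AUC; degenerate scores warn."""
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if np.allclose(scores, scores[0]):
        import warnings
        warnings.warn("constant scores: ROC is degenerate, AUC = 0.5")
        return pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]}), 0.5
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc
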