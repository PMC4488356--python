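"""Ternary discretization and decision-tree validation of biomarkers.

Expression is discretized per cohort and per gene by the mu +/- s rule
(value > mu+s -> 1, value < mu-s -> -1, else 0, strict inequalities; mu and
s are the gene's mean and sample sd over the cohort's samples).  Because
the rule only compares a value with affine functions of the cohort values,
the ternary code is invariant to strictly increasing affine transforms of
a gene row — which is what makes it usable across platforms.

A seeded decision tree is trained on the discovery cohort's discretized
biomarker features and evaluated on the validation cohort; the report
carries per-label precision/recall/F1/support plus macro and
support-weighted averages and overall accuracy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError

__all__ = [
    "discretize",
    "train_tree",
    "predict",
    "tree_to_json",
    "classification_report",
    "labels_from_survival",
]


def discretize(m: pd.DataFrame) -> pd.DataFrame:
    """Map each gene row to {-1, 0, 1} by the per-cohort mu +/- s rule."""
    if m.shape[1] < 2:
        raise InputError("discretization requires >= 2 samples")
    mu = m.mean(axis=1)
    s = m.std(axis=1, ddof=1)
    n_zero = int((s == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-sd gene(s) discretized to all zeros", RuntimeWarning)
    up = m.gt(mu + s, axis=0)
    down = m.lt(mu - s, axis=0)
    return (up.astype(np.int8) - down.astype(np.int8)).astype(np.int8)


def train_tree(x: pd.DataFrame, labels, seed: int = 0, **tree_kwargs) -> DecisionTreeClassifier:
    """Fit a seeded classification tree on a genes-by-samples ternary matrix."""
    y = list(labels)
    if len(y) != x.shape[1]:
        raise InputError("one label per sample required")
    if len(set(y)) < 2:
        raise InputError("training labels contain a single class")
    clf = DecisionTreeClassifier(criterion="gini", random_state=seed, **tree_kwargs)
    clf.fit(x.to_numpy().T, y)
    return clf


def predict(model: DecisionTreeClassifier, x: pd.DataFrame) -> list[str]:
    return list(model.predict(x.to_numpy().T))


def tree_to_json(model: DecisionTreeClassifier, feature_names) -> dict:
    """Serializable structure: split gene/value, children, leaf class counts."""
    t = model.tree_
    feature_names = list(feature_names)
    classes = [str(c) for c in model.classes_]

    def node(i: int) -> dict:
        counts = {c: int(v) for c, v in zip(classes, t.value[i][0] * t.weighted_n_node_samples[i])}
        if t.children_left[i] == -1:
            return {"leaf": True, "counts": counts, "class": classes[int(np.argmax(t.value[i][0]))]}
        return {
            "leaf": False,
            "feature": feature_names[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return node(0)


def classification_report(y_true, y_pred, labels=None) -> dict:
    """Per-label precision/recall/F1/support with macro, weighted and accuracy.

    ``labels``, when given, is the closed label set; any other value in the
    inputs raises :class:`InputError`.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise InputError("label vectors must have equal length")
    if not y_true:
        raise InputError("empty label vectors")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    else:
        labels = list(labels)
        offenders = sorted((set(y_true) | set(y_pred)) - set(labels))
        if offenders:
            raise InputError(f"labels outside {labels}: {offenders}")

    report: dict[str, dict | float] = {}
    precisions, recalls, f1s, supports = [], [], [], []
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        support = tp + fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        report[lab] = {"precision": precision, "recall": recall, "f1": f1, "support": support}
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
        supports.append(support)

    total = sum(supports)
    w = [s / total for s in supports] if total else [0.0] * len(supports)
    report["macro avg"] = {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
        "support": total,
    }
    report["weighted avg"] = {
        "precision": float(np.dot(w, precisions)),
        "recall": float(np.dot(w, recalls)),
        "f1": float(np.dot(w, f1s)),
        "support": total,
    }
    report["accuracy"] = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return report


def labels_from_survival(
    ann: pd.DataFrame,
    years: float = 3.0,
    resistant_label: str = "NOCR",
    sensitive_label: str = "CR",
) -> pd.Series:
    """Dichotomize disease-specific survival at ``years`` (default 3).

    Samples with ``dss_years`` strictly below the cutoff are labelled
    chemoresistant; when the column is absent the annotation's ``response``
    column is returned unchanged.
    """
    if "dss_years" in ann.columns and ann["dss_years"].notna().all():
        return pd.Series(
            np.where(ann["dss_years"] < years, resistant_label, sensitive_label),
            index=ann.index,
            name="response",
        )
    return ann["response"]
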