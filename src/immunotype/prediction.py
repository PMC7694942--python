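"""Cross-cohort subtype prediction with a Random Forest.

A forest of 500 trees is trained on one cohort's Z-clipped 28-feature immune
enrichment profiles with its clustering-derived subtype labels, then evaluated
on other cohorts that were normalized and clustered independently (per-cohort
Z; raw-scale transfer across platforms is not meaningful). Reported metrics
are overall accuracy and the class-support-weighted mean of per-class F1
("weighted F-score"), plus per-class precision/recall/F1, the confusion
matrix, and mean-impurity-decrease feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold

from .subtyping import NormalizedFeatureMatrix, SubtypeAssignment

__all__ = [
    "ClassifierReport",
    "SubtypeClassifier",
    "train_subtype_classifier",
    "cross_cohort_predict",
    "kfold_cv",
    "report_from_predictions",
]


@dataclass
class ClassifierReport:
    """Evaluation of one prediction run.

    Invariants: confusion-matrix row sums equal class supports,
    ``accuracy = trace / total`` and
    ``weighted_f = sum(support_c * F1_c) / sum(support_c)``.
    """

    accuracy: float
    weighted_f: float
    per_class: pd.DataFrame       # index class; columns precision, recall, f1, support
    confusion: pd.DataFrame       # true x predicted counts
    feature_importances: pd.Series | None = None
    training_cohort: str | None = None
    seed: int | None = None
    predictions: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        supports = self.confusion.sum(axis=1)
        assert (supports.to_numpy() == self.per_class["support"].to_numpy()).all()
        total = self.confusion.to_numpy().sum()
        assert abs(self.accuracy - np.trace(self.confusion.to_numpy()) / total) < 1e-12

    def to_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "accuracy": self.accuracy,
            "weighted_f": self.weighted_f,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": {
                "classes": self.confusion.index.tolist(),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "training_cohort": self.training_cohort,
            "seed": self.seed,
        }
        if self.feature_importances is not None:
            out["feature_importances"] = self.feature_importances.to_dict()
        return out


@dataclass
class SubtypeClassifier:
    """A fitted forest plus the feature names it was trained on."""

    model: RandomForestClassifier
    feature_names: list[str]
    training_cohort: str | None = None
    seed: int | None = None

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.model.feature_importances_, index=self.feature_names,
                         name="importance")

    def predict(self, features: NormalizedFeatureMatrix) -> pd.Series:
        missing = [f for f in self.feature_names if f not in features.feature_names]
        if missing:
            raise ValueError(f"test cohort is missing model feature(s): {missing}")
        X = features.z.loc[self.feature_names].to_numpy(float).T
        return pd.Series(self.model.predict(X),
                         index=pd.Index(features.sample_ids, name="sample_id"),
                         name="predicted_label")


def _labels_series(labels: SubtypeAssignment | pd.Series) -> pd.Series:
    return labels.labels if isinstance(labels, SubtypeAssignment) else labels


def report_from_predictions(y_true: pd.Series, y_pred: pd.Series,
                            classes: list[str] | None = None,
                            **extra) -> ClassifierReport:
    """Build a :class:`ClassifierReport` from aligned true/predicted labels."""
    y_true, y_pred = y_true.align(y_pred, join="inner")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-support classes
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(classes, name="class"))
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    weighted_f = float((support * f1).sum() / support.sum())
    confusion = pd.DataFrame(cm, index=pd.Index(classes, name="true"),
                             columns=pd.Index(classes, name="predicted"))
    return ClassifierReport(accuracy=accuracy, weighted_f=weighted_f,
                            per_class=per_class, confusion=confusion,
                            predictions=y_pred, **extra)


def train_subtype_classifier(features: NormalizedFeatureMatrix,
                             labels: SubtypeAssignment | pd.Series,
                             n_trees: int = 500, seed: int = 0,
                             cohort: str | None = None) -> SubtypeClassifier:
    """Fit a Random Forest (500 trees by default) on Z-clipped features.

    Hyperparameters beyond tree count stay at scikit-learn defaults
    (sqrt-feature subsampling, unlimited depth). Deterministic given ``seed``.
    """
    y = _labels_series(labels).loc[features.sample_ids]
    if y.nunique() < 2:
        raise ValueError("training labels contain a single class")
    X = features.z.to_numpy(float).T
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(X, y.to_numpy())
    return SubtypeClassifier(model=model, feature_names=features.feature_names,
                             training_cohort=cohort, seed=seed)


def cross_cohort_predict(model: SubtypeClassifier,
                         test_features: NormalizedFeatureMatrix,
                         test_labels: SubtypeAssignment | pd.Series) -> ClassifierReport:
    """Predict subtypes in an independently normalized cohort and score them
    against that cohort's own clustering-derived labels."""
    y_pred = model.predict(test_features)
    y_true = _labels_series(test_labels).loc[y_pred.index]
    return report_from_predictions(
        y_true, y_pred, feature_importances=model.feature_importances,
        training_cohort=model.training_cohort, seed=model.seed)


def kfold_cv(features: NormalizedFeatureMatrix,
             labels: SubtypeAssignment | pd.Series,
             k: int = 10, n_trees: int = 500, seed: int = 0) -> ClassifierReport:
    """Stratified k-fold cross-validation, scored once on pooled out-of-fold
    predictions (micro pooling rather than per-fold averaging)."""
    y = _labels_series(labels).loc[features.sample_ids]
    n = len(y)
    if n < k:
        raise ValueError(f"k={k} exceeds sample count {n}")
    stratify = not (y.value_counts() < k).any()
    if not stratify:
        warnings.warn("a class has fewer members than folds; "
                      "stratifying as evenly as possible")
    X = features.z.to_numpy(float).T
    y_arr = y.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if stratify:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        oof = np.empty(n, dtype=object)
        for train_idx, test_idx in splitter.split(X, y_arr):
            model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            model.fit(X[train_idx], y_arr[train_idx])
            oof[test_idx] = model.predict(X[test_idx])
    y_pred = pd.Series(oof, index=y.index, name="predicted_label")
    return report_from_predictions(y, y_pred, seed=seed)
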