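"""Cross-validated binary emotion classification on gait feature tables.

Four classifier families are wrapped (not reimplemented): Gaussian naive
Bayes, random forest (100 trees), RBF-kernel SVM (C=1, gamma=1/d) and
linear SVM (C=1).  Evaluation is seeded stratified 10-fold
cross-validation; inside every fold the z-score normalization and PCA
are fitted on the training portion only, so no statistic of the held-out
instances leaks into the model (a ``global_fit`` switch fits them once
on the whole table instead).  Accuracy is pooled over folds: the
proportion of correctly classified instances across all test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError
from .features import (
    pca_apply_array,
    pca_fit_array,
    zscore_apply_array,
    zscore_fit_array,
)
from .skeleton_io import FeatureTable

CLASSIFIER_NAMES: tuple[str, ...] = (
    "naive_bayes",
    "random_forest",
    "svm_rbf",
    "svm_linear",
)


@dataclass
class CVReport:
    """Result of one cross-validated binary task."""

    task: tuple[str, str]
    classifier: str
    fold_accuracies: list[float]
    accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, label order = task
    seed: int
    n_instances: int

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (2, 2):
            raise ValidationError("confusion matrix must be 2x2")
        if int(self.confusion.sum()) != self.n_instances:
            raise ValidationError("confusion counts must sum to n_instances")

    def to_dict(self) -> dict:
        return {
            "task": list(self.task),
            "classifier": self.classifier,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "accuracy": float(self.accuracy),
            "confusion": self.confusion.tolist(),
            "seed": int(self.seed),
            "n_instances": int(self.n_instances),
        }


def make_binary_task(
    table: FeatureTable,
    label_a: str,
    label_b: str,
    camera: str | None = None,
    merge_cameras: bool = False,
) -> FeatureTable:
    """Restrict a table to two classes (and, by default, one camera).

    Records from different cameras are never mixed in one task unless
    ``merge_cameras`` is set, since the two sensors are processed
    independently.
    """
    if label_a == label_b:
        raise ValidationError("task labels must differ")
    for lab in (label_a, label_b):
        if lab not in table.labels:
            raise ValidationError(f"label {lab!r} not present in table")
    keep = [
        i
        for i, (lab, (_, _, cam)) in enumerate(
            zip(table.labels, table.instance_ids)
        )
        if lab in (label_a, label_b) and (camera is None or cam == camera)
    ]
    ids = [table.instance_ids[i] for i in keep]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate (subject, condition, camera) instance")
    if not merge_cameras and camera is None:
        cams = {cam for _, _, cam in ids}
        if len(cams) > 1:
            raise ValidationError(
                f"task mixes cameras {sorted(cams)}; pass camera=... or "
                "merge_cameras=True"
            )
    sub = FeatureTable(
        instance_ids=ids,
        values=table.values[keep],
        feature_names=list(table.feature_names),
        labels=[table.labels[i] for i in keep],
    )
    for lab in (label_a, label_b):
        if lab not in sub.labels:
            raise ValidationError(
                f"label {lab!r} absent after camera restriction"
            )
    return sub


def _make_classifier(name: str, seed: int):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="auto")
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    raise ConfigError(
        f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
    )


def cross_validate(
    task: FeatureTable,
    classifier: str,
    k: int = 10,
    seed: int = 0,
    variance_threshold: float = 0.95,
    global_fit: bool = False,
    stratified: bool = True,
) -> CVReport:
    """Seeded k-fold cross-validation of one binary task.

    Per fold: z-score fit -> PCA fit (both on the training portion only,
    unless ``global_fit``) -> classifier fit -> evaluate on the held-out
    portion.  Returns pooled accuracy, per-fold accuracies and the 2x2
    confusion matrix (label order sorted alphabetically).
    """
    y = np.asarray(task.labels)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if stratified and min(counts.values()) < k:
        raise ValidationError(
            f"stratified {k}-fold CV needs >= {k} instances per class, "
            f"got {counts}"
        )
    if task.n_instances < k:
        raise ValidationError("fewer instances than folds")
    _make_classifier(classifier, 0)  # validate the name early

    X = task.values
    if global_fit:
        means, sds = zscore_fit_array(X)
        Z = zscore_apply_array(X, means, sds)
        model = pca_fit_array(Z, variance_threshold)
        X = pca_apply_array(Z, model)

    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    y_pred = np.empty_like(y)
    fold_accuracies: list[float] = []
    for train, test in splitter.split(X, y):
        Xtr, Xte = X[train], X[test]
        if not global_fit:
            means, sds = zscore_fit_array(Xtr)
            Ztr = zscore_apply_array(Xtr, means, sds)
            Zte = zscore_apply_array(Xte, means, sds)
            model = pca_fit_array(Ztr, variance_threshold)
            Xtr = pca_apply_array(Ztr, model)
            Xte = pca_apply_array(Zte, model)
        clf = _make_classifier(classifier, seed)
        clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        y_pred[test] = pred
        fold_accuracies.append(float(np.mean(pred == y[test])))

    accuracy = float(np.mean(y_pred == y))
    confusion = confusion_matrix(y, y_pred, labels=classes)
    return CVReport(
        task=(classes[0], classes[1]),
        classifier=classifier,
        fold_accuracies=fold_accuracies,
        accuracy=accuracy,
        confusion=confusion,
        seed=seed,
        n_instances=task.n_instances,
    )


def evaluate_all(
    task: FeatureTable,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict[str, CVReport]:
    """Cross-validate every named classifier on the same task and seed."""
    return {
        name: cross_validate(task, name, k=k, seed=seed, **kwargs)
        for name in classifiers
    }
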