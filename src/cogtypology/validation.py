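"""Subgroup stability via RBF-SVM cross-validation.

Community detection assigns every participant to a subgroup but says
nothing about how reliably a *new* individual could be placed. Stability
is quantified by training a multi-class support vector machine with a
radial basis function kernel on the same eight oriented z-scores used
for clustering, with the detected community as the class label, under
two schemes:

* leave-one-out cross-validation (LOOCV): each participant is predicted
  once from a model trained on all others;
* data partitioning (half split): each subgroup is split into two
  near-equal halves, the larger half trains a single model that is
  evaluated on the other half.

Per subgroup, sensitivity = true positives / subgroup size and
specificity = true negatives / number of non-members, both in percent.
SVM hyperparameters (cost C and kernel width gamma) are chosen by an
inner stratified 5-fold grid search on the training data only, over a
logarithmic grid C in 2^{-5..15}, gamma in 2^{-15..3}.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "train_classifier",
    "loocv",
    "half_split",
    "report_from_confusion",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

# Logarithmic LIBSVM-style grids, exponent step 2.
DEFAULT_C_GRID: np.ndarray = 2.0 ** np.arange(-5, 16, 2)
DEFAULT_GAMMA_GRID: np.ndarray = 2.0 ** np.arange(-15, 4, 2)


@dataclasses.dataclass
class ValidationReport:
    """Accuracy, per-class sensitivity/specificity and the confusion matrix."""

    scheme: str
    overall_accuracy: float                 # percent
    per_class: dict                         # class -> {size, sensitivity, specificity}
    confusion: np.ndarray                   # rows = true classes, cols = predicted
    classes: list
    hyperparameters: dict

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "overall_accuracy": self.overall_accuracy,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.classes],
            "hyperparameters": self.hyperparameters,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion,
                            index=pd.Index(self.classes, name="true"),
                            columns=pd.Index(self.classes, name="predicted"))


def train_classifier(
    features: np.ndarray,
    labels: Sequence,
    seed: int = 0,
    c_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    n_folds: int = 5,
    fixed_params: dict | None = None,
):
    """Fit a multi-class RBF-SVM with inner stratified grid search.

    *fixed_params* (e.g. ``{"C": 1.0, "gamma": "scale"}``) bypasses the
    search. A training class with a single member cannot be stratified;
    it triggers a logged warning and mid-grid defaults are used.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; nothing to separate")
    if fixed_params is not None:
        return SVC(kernel="rbf", **fixed_params).fit(X, y)
    min_count = int(counts.min())
    if min_count < 2:
        logger.warning("class(es) with a single training member: %s; "
                       "skipping grid search, using C=1, gamma='scale'",
                       [str(c) for c, n in zip(classes, counts) if n < 2])
        return SVC(kernel="rbf", C=1.0, gamma="scale").fit(X, y)
    folds = min(n_folds, min_count)
    if folds < n_folds:
        logger.warning("smallest training class has %d members; inner CV uses %d folds",
                       min_count, folds)
    grid = {
        "C": list(DEFAULT_C_GRID if c_grid is None else c_grid),
        "gamma": list(DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid),
    }
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


def report_from_confusion(confusion: np.ndarray, classes: Sequence, scheme: str = "confusion",
                          hyperparameters: dict | None = None) -> ValidationReport:
    """Accuracy and per-class sensitivity/specificity from a confusion matrix.

    Rows are true classes, columns predictions. Sensitivity of class c is
    TP_c over the true class size; specificity is TN_c over the number of
    evaluated non-members of c. All in percent.
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, cls in enumerate(classes):
        size = C[i, :].sum()
        tp = C[i, i]
        fp = C[:, i].sum() - tp
        tn = total - size - fp
        per_class[cls] = {
            "size": int(size),
            "sensitivity": float(100.0 * tp / size) if size else float("nan"),
            "specificity": float(100.0 * tn / (total - size)) if total > size else float("nan"),
        }
    return ValidationReport(
        scheme=scheme,
        overall_accuracy=float(100.0 * np.trace(C) / total),
        per_class=per_class,
        confusion=np.asarray(confusion),
        classes=list(classes),
        hyperparameters=hyperparameters or {},
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[index[t], index[p]] += 1
    return C


def loocv(features: np.ndarray, labels: Sequence, seed: int = 0, **svm_kwargs) -> ValidationReport:
    """Leave-one-out cross-validation of subgroup membership."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    classes = np.unique(y)
    if n < len(classes) + 1:
        raise ValueError("need more participants than classes for LOOCV")
    preds = np.empty(n, dtype=y.dtype)
    hyper: dict = {}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_classifier(X[mask], y[mask], seed=seed, **svm_kwargs)
        preds[i] = model.predict(X[i: i + 1])[0]
        hyper = {"C": float(model.C), "gamma": model.gamma if isinstance(model.gamma, str)
                 else float(model.gamma)}
    confusion = _confusion(y, preds, classes)
    return report_from_confusion(confusion, list(classes), scheme="loocv",
                                 hyperparameters={"last_round": hyper})


def half_split(features: np.ndarray, labels: Sequence, seed: int = 0, **svm_kwargs) -> ValidationReport:
    """Stratified half-split validation (data partitioning).

    Each class of size s contributes ceil(s/2) members to training and
    floor(s/2) to testing, drawn at random within class given *seed*;
    a single model is trained and evaluated on the held-out halves.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in classes:
        members = np.where(y == cls)[0]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot half-split")
        members = rng.permutation(members)
        n_train = int(np.ceil(len(members) / 2))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)
    model = train_classifier(X[train_idx], y[train_idx], seed=seed, **svm_kwargs)
    preds = model.predict(X[test_idx])
    confusion = _confusion(y[test_idx], preds, classes)
    hyper = {"C": float(model.C),
             "gamma": model.gamma if isinstance(model.gamma, str) else float(model.gamma),
             "n_train": len(train_idx), "n_test": len(test_idx)}
    return report_from_confusion(confusion, list(classes), scheme="half_split",
                                 hyperparameters=hyper)
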