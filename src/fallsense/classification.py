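"""Normalization, the five classifier families, grid search and crossvalidation.

Families: RBF-kernel SVM (one-vs-one multiclass), sparse multinomial
logistic regression (L1-penalized, the penalty acting as embedded feature
selection), Gaussian naive Bayes, a Gini decision tree grown to purity, and
Euclidean k-nearest neighbours.  Features are normalized to zero mean and
unit variance with statistics computed from training folds only, so no test
information leaks into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("svm-rbf", "smlr", "naive-bayes", "decision-tree", "knn")

#: hyperparameter grid exponents, 10^x for integer x in [-5, 5]
GRID_EXPONENTS = tuple(range(-5, 6))
#: neighbour counts searched for kNN (an integer count, not a 10^x scale)
KNN_GRID = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus the hyperparameters it uses.

    Defaults are the values reported to maximize 10-fold CV accuracy:
    C = 10 and γ = 0.1 for the SVM, λ = 1e-4 for SMLR, k = 3 for kNN.
    """

    family: str
    C: float = 10.0
    gamma: float = 0.1
    lam: float = 1e-4
    k: int = 3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        if self.C <= 0 or self.gamma <= 0 or self.lam < 0 or self.k < 1:
            raise ValueError("require C>0, gamma>0, lambda>=0, k>=1")


@dataclass
class Normalizer:
    """Per-feature centre/scale learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray


def fit_normalizer(X: np.ndarray) -> Normalizer:
    """Learn per-feature mean and sd; zero-variance features get scale 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return Normalizer(mean=mean, scale=scale)


def apply_normalizer(norm: Normalizer, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - norm.mean) / norm.scale


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object


def _make_estimator(spec: ClassifierSpec, n_train: int):
    if spec.family == "svm-rbf":
        return SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")  # ovo multiclass
    if spec.family == "smlr":
        if spec.lam == 0:
            return LogisticRegression(C=np.inf, solver="lbfgs",
                                      tol=1e-6, max_iter=2000)
        # objective: mean NLL + lam * ||w||_1  <=>  sklearn C = 1/(n * lam)
        return LogisticRegression(l1_ratio=1.0, solver="saga",
                                  C=1.0 / (n_train * spec.lam),
                                  tol=1e-6, max_iter=2000)
    if spec.family == "naive-bayes":
        return GaussianNB(var_smoothing=1e-9)
    if spec.family == "decision-tree":
        return DecisionTreeClassifier(criterion="gini", random_state=0)
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    raise ValueError(spec.family)


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one classifier on (already normalized) feature rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes in y")
    est = _make_estimator(spec, n_train=X.shape[0])
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.estimator.predict(np.asarray(X, dtype=float))


def kfold_split(y: np.ndarray, k: int = 10, seed: int = 0):
    """Stratified, shuffled k-fold split; returns (train_idx, test_idx) pairs."""
    y = np.asarray(y)
    if k > y.size:
        raise ValueError("k cannot exceed the number of rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((y.size, 1)), y))


def subjectwise_split(subjects: np.ndarray):
    """Leave-one-subject-out folds: each test fold is one subject's rows."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("subject-wise crossvalidation needs at least 2 subjects")
    folds = []
    for s in uniq:
        test = np.flatnonzero(subjects == s)
        train_idx = np.flatnonzero(subjects != s)
        folds.append((train_idx, test))
    return folds


@dataclass
class EvalResult:
    """Crossvalidated predictions, aggregated confusion matrix and accuracy."""

    scheme: str
    labels: list[str]
    fold_true: list[np.ndarray]
    fold_pred: list[np.ndarray]
    confusion_matrix: np.ndarray = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        y_true = np.concatenate(self.fold_true)
        y_pred = np.concatenate(self.fold_pred)
        self.confusion_matrix = _sk_confusion(y_true, y_pred, labels=self.labels)
        self.accuracy = float(np.mean(y_true == y_pred))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "labels": list(self.labels),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "fold_accuracies": [float(np.mean(t == p))
                                for t, p in zip(self.fold_true, self.fold_pred)],
        }


def evaluate(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
             subjects: np.ndarray | None = None, scheme: str = "kfold-10",
             seed: int = 0) -> EvalResult:
    """Crossvalidate one classifier under the pooled or subject-wise scheme.

    Per fold the normalizer is fitted on the training rows alone, the model
    trained on the normalized training rows and scored on the normalized
    test rows; the confusion matrix and accuracy aggregate over all folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme == "kfold-10":
        folds = kfold_split(y, k=10, seed=seed)
    elif scheme == "subject-wise":
        if subjects is None:
            raise ValueError("subject-wise scheme requires subject ids")
        folds = subjectwise_split(subjects)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = [str(v) for v in np.unique(y)]
    fold_true, fold_pred = [], []
    for tr, te in folds:
        norm = fit_normalizer(X[tr])
        model = train(spec, apply_normalizer(norm, X[tr]), y[tr])
        fold_true.append(y[te])
        fold_pred.append(predict(model, apply_normalizer(norm, X[te])))
    return EvalResult(scheme=scheme, labels=labels,
                      fold_true=fold_true, fold_pred=fold_pred)


def _grid_for(family: str) -> list[dict]:
    vals = [10.0**x for x in GRID_EXPONENTS]
    if family == "svm-rbf":
        return [{"C": c, "gamma": g} for c, g in product(vals, vals)]
    if family == "smlr":
        return [{"lam": v} for v in vals]
    if family == "knn":
        return [{"k": k} for k in KNN_GRID]
    raise ValueError(
        f"family {family!r} has no hyperparameters to search; train it directly")


def grid_search(family: str, X: np.ndarray, y: np.ndarray, folds: int = 10,
                seed: int = 0, trace: list | None = None) -> ClassifierSpec:
    """Pick the hyperparameters maximizing k-fold CV accuracy over the grid.

    C, γ and λ are searched over 10^x for integer x in [−5, 5]; k over small
    odd integers.  Ties keep the first candidate in ascending order of the
    hyperparameter values.  Pass a list as ``trace`` to record every
    (params, accuracy) pair evaluated.
    """
    best_spec, best_acc = None, -1.0
    split_seed = seed
    for params in _grid_for(family):
        spec = ClassifierSpec(family=family, **params)
        res = _evaluate_kfold(spec, X, y, k=folds, seed=split_seed)
        if trace is not None:
            trace.append((params, res.accuracy))
        if res.accuracy > best_acc:
            best_spec, best_acc = spec, res.accuracy
    return best_spec


def _evaluate_kfold(spec, X, y, k, seed):
    y = np.asarray(y)
    folds = kfold_split(y, k=k, seed=seed)
    labels = [str(v) for v in np.unique(y)]
    fold_true, fold_pred = [], []
    for tr, te in folds:
        norm = fit_normalizer(X[tr])
        model = train(spec, apply_normalizer(norm, X[tr]), y[tr])
        fold_true.append(y[te])
        fold_pred.append(predict(model, apply_normalizer(norm, X[te])))
    return EvalResult(scheme=f"kfold-{k}", labels=labels,
                      fold_true=fold_true, fold_pred=fold_pred)
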