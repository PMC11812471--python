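"""Mondrian cross-conformal prediction of disease status.

Binary classification from (PRS, age, sex) with per-class conformal
p-values. The Mondrian taxonomy is the class label itself, which gives
class-conditional validity: for each true class, the probability that
the prediction set at significance ``eps`` excludes the true label is at
most ``eps`` (up to cross-fold aggregation).

The underlying classifier is an L2-regularised logistic model on
standardised features; the nonconformity of an example under a
hypothesised label ``y`` is ``1 - P(y | x)`` (or the probability margin,
by configuration). Per-fold p-values follow the standard conservative
counting rule ``(#{calibration scores >= score} + 1) / (n_cal + 1)`` and
are combined by their arithmetic mean across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LABELS",
    "CASE",
    "CONTROL",
    "UNDECIDED",
    "FeatureVector",
    "FoldModel",
    "MCCPModel",
    "ConformalPrediction",
    "fit_mccp",
    "conformal_p",
    "conformal_p_many",
    "predict",
    "predict_many",
    "save_model",
    "load_model",
]

CASE = "case"
CONTROL = "control"
UNDECIDED = "undecided"
LABELS = (CONTROL, CASE)

Nonconformity = Literal["prob", "margin"]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FeatureVector:
    """Predictors for one individual: score, age in years, binary sex."""

    prs: float
    age: float
    sex: float  # 1.0 for the designated sex, 0.0 otherwise

    def as_array(self) -> np.ndarray:
        return np.array([self.prs, self.age, self.sex], dtype=float)


@dataclass(frozen=True)
class FoldModel:
    """Logistic coefficients of one fold plus its per-class calibration scores."""

    coef: np.ndarray  # shape (3,), on standardised features
    intercept: float
    calib_scores: dict[str, np.ndarray]  # label -> sorted nonconformity scores

    def prob_case(self, x_std: np.ndarray) -> np.ndarray:
        return expit(x_std @ self.coef + self.intercept)


@dataclass(frozen=True)
class MCCPModel:
    k: int
    fold_models: tuple[FoldModel, ...]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    nonconformity: Nonconformity
    seed: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.fold_models) != self.k:
            raise ValueError("fold_models must have length k")

    def standardise(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def calibration_sizes(self) -> dict[str, int]:
        return {
            label: sum(fm.calib_scores[label].size for fm in self.fold_models)
            for label in LABELS
        }


@dataclass(frozen=True)
class ConformalPrediction:
    p_case: float
    p_control: float
    label_set: frozenset[str]
    point_label: str
    prob_affected: float
    epsilon: float


def _score(prob_y: np.ndarray, nonconformity: Nonconformity) -> np.ndarray:
    # prob_y = estimated probability of the hypothesised label.
    if nonconformity == "prob":
        return 1.0 - prob_y
    # margin: probability of the other label minus probability of y
    return (1.0 - prob_y) - prob_y


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        return X.reshape(1, -1) if X.ndim == 1 else X
    return np.stack([f.as_array() for f in features])


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    unknown = set(arr.tolist()) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}; expected {LABELS}")
    return (arr == CASE).astype(int)


def fit_mccp(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
    nonconformity: Nonconformity = "prob",
    C: float = 1.0,
) -> MCCPModel:
    """Fit a k-fold Mondrian cross-conformal model.

    The data are split into ``k`` stratified folds; for each fold the
    underlying classifier is fitted on the remaining folds and the
    held-out fold provides calibration nonconformity scores, stored per
    true class. Every class must appear in every calibration fold,
    otherwise the class-conditional guarantee breaks and fitting fails.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _as_matrix(features)
    y = _as_binary(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present in the training data")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    folds = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, cal_idx in skf.split(Xs, y):
        if len(np.unique(y[cal_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a class is absent from a fold; class-conditional validity "
                "requires both classes in every calibration part"
            )
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        clf.fit(Xs[train_idx], y[train_idx])
        p_case_cal = expit(Xs[cal_idx] @ clf.coef_.ravel() + float(clf.intercept_[0]))
        calib: dict[str, np.ndarray] = {}
        for label, y_val in ((CONTROL, 0), (CASE, 1)):
            p_y = p_case_cal[y[cal_idx] == y_val] if y_val == 1 else 1.0 - p_case_cal[y[cal_idx] == y_val]
            calib[label] = np.sort(_score(p_y, nonconformity))
        folds.append(
            FoldModel(coef=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]), calib_scores=calib)
        )
    return MCCPModel(
        k=k,
        fold_models=tuple(folds),
        feature_mean=mean,
        feature_scale=scale,
        nonconformity=nonconformity,
        seed=seed,
    )


def conformal_p_many(model: MCCPModel, features, label: str) -> np.ndarray:
    """Cross-conformal p-values of many examples under a hypothesised label.

    Per fold: ``p = (#{calibration scores of that class >= score} + 1)
    / (n_cal + 1)``; the returned p-value is the arithmetic mean across
    folds and always lies in (0, 1].
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    X = model.standardise(_as_matrix(features))
    p_folds = np.empty((model.k, X.shape[0]))
    for i, fm in enumerate(model.fold_models):
        prob_case = fm.prob_case(X)
        prob_y = prob_case if label == CASE else 1.0 - prob_case
        alpha = _score(prob_y, model.nonconformity)
        cal = fm.calib_scores[label]
        n_ge = cal.size - np.searchsorted(cal, alpha, side="left")
        p_folds[i] = (n_ge + 1) / (cal.size + 1)
    return p_folds.mean(axis=0)


def conformal_p(model: MCCPModel, x: FeatureVector, y: str) -> float:
    """Conformal p-value of a single example under hypothesised label ``y``."""
    return float(conformal_p_many(model, [x], y)[0])


def prob_affected_many(model: MCCPModel, features) -> np.ndarray:
    """Mean across folds of the underlying classifier's P(case | x)."""
    X = model.standardise(_as_matrix(features))
    return np.mean([fm.prob_case(X) for fm in model.fold_models], axis=0)


def predict_many(model: MCCPModel, features, epsilon: float = 0.2):
    """Vectorised prediction: returns (p_case, p_control, point_labels, prob_affected).

    ``point_labels`` is an object array over {case, control, undecided};
    ties between the two p-values are reported as undecided, never broken.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie strictly inside (0, 1)")
    p_case = conformal_p_many(model, features, CASE)
    p_control = conformal_p_many(model, features, CONTROL)
    point = np.where(p_case > p_control, CASE, np.where(p_case < p_control, CONTROL, UNDECIDED))
    prob = prob_affected_many(model, features)
    return p_case, p_control, point, prob


def predict(model: MCCPModel, x: FeatureVector, epsilon: float = 0.2) -> ConformalPrediction:
    """Full conformal output for one example at significance ``epsilon``."""
    p_case, p_control, point, prob = predict_many(model, [x], epsilon)
    label_set = frozenset(
        label for label, p in ((CASE, p_case[0]), (CONTROL, p_control[0])) if p > epsilon
    )
    return ConformalPrediction(
        p_case=float(p_case[0]),
        p_control=float(p_control[0]),
        label_set=label_set,
        point_label=str(point[0]),
        prob_affected=float(prob[0]),
        epsilon=epsilon,
    )


def save_model(model: MCCPModel, path) -> None:
    """Serialise the model to a versioned JSON document."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "seed": model.seed,
        "nonconformity": model.nonconformity,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "folds": [
            {
                "coef": fm.coef.tolist(),
                "intercept": fm.intercept,
                "calib_scores": {lbl: s.tolist() for lbl, s in fm.calib_scores.items()},
            }
            for fm in model.fold_models
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MCCPModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {doc.get('format_version')}")
    folds = tuple(
        FoldModel(
            coef=np.asarray(f["coef"], dtype=float),
            intercept=float(f["intercept"]),
            calib_scores={lbl: np.asarray(s, dtype=float) for lbl, s in f["calib_scores"].items()},
        )
        for f in doc["folds"]
    )
    return MCCPModel(
        k=int(doc["k"]),
        fold_models=folds,
        feature_mean=np.asarray(doc["feature_mean"], dtype=float),
        feature_scale=np.asarray(doc["feature_scale"], dtype=float),
        nonconformity=doc["nonconformity"],
        seed=int(doc["seed"]),
    )
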