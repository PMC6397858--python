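"""Normalisation, SVM training and parameter tuning.

Features are scaled per column to the open interval (-1, 1) with a
MATLAB-``mapminmax``-style linear map fitted on the training set, then fed to
an RBF-kernel support vector machine (libsvm, via scikit-learn's ``SVC``).
The default operating point is C = 65536, gamma = 1e-4, found by grid search
over a log-2 grid under 10-fold cross-validation.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

DEFAULT_C = 65536.0
DEFAULT_GAMMA = 1e-4
DEFAULT_KERNEL = "rbf"

#: log-2 grid covering the default operating point
DEFAULT_C_GRID = [2.0**k for k in range(-5, 18, 2)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-17, 4, 2)]


class MapMinMaxScaler(TransformerMixin, BaseEstimator):
    """Column-wise linear rescaling to [-1, 1] from training min/max.

    ``y = 2 (x - min) / (max - min) - 1``; a constant column (max == min)
    maps to 0 everywhere. Values outside the training range map outside
    [-1, 1] — no clipping, the map stays linear.
    """

    def fit(self, X, y=None) -> "MapMinMaxScaler":
        X = self._validate(X)
        if X.shape[0] < 1:
            raise ValueError("cannot fit normalisation on an empty matrix")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; scaler was fitted on {self.n_features_in_}"
            )
        span = self.data_max_ - self.data_min_
        out = np.zeros_like(X)
        nz = span != 0
        out[:, nz] = 2.0 * (X[:, nz] - self.data_min_[nz]) / span[nz] - 1.0
        return out

    def inverse_transform(self, Y) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        Y = self._validate(Y)
        span = self.data_max_ - self.data_min_
        out = np.tile(self.data_min_, (Y.shape[0], 1))
        nz = span != 0
        out[:, nz] = (Y[:, nz] + 1.0) / 2.0 * span[nz] + self.data_min_[nz]
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={X.ndim}")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains NaN or Inf")
        return X


def fit_normalizer(X) -> MapMinMaxScaler:
    """Fit a mapminmax scaler on ``X`` (thin functional wrapper)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("normalisation needs a 2-D matrix with >= 2 rows")
    return MapMinMaxScaler().fit(X)


def apply_normalizer(scaler: MapMinMaxScaler, X) -> np.ndarray:
    return scaler.transform(X)


def _layout_hash(n_features: int, feature_names: Sequence[str] | None) -> str:
    payload = f"{n_features}|" + "|".join(feature_names or [])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class HairpinClassifier(ClassifierMixin, BaseEstimator):
    """Mapminmax normalisation + SVM, as one sklearn estimator.

    Parameters
    ----------
    kernel : {"linear", "poly", "rbf", "sigmoid"}, default "rbf"
    C : float, default 65536
        SVM penalty parameter.
    gamma : float, default 1e-4
        RBF/poly/sigmoid kernel coefficient.
    class_weight : None or "balanced", default None
        Pass "balanced" for heavily imbalanced training sets.
    normalize : bool, default True
        Fit the (-1, 1) scaler on the training features. Disable if the
        caller normalises externally (e.g. whole-dataset scaling).

    Attributes
    ----------
    pipeline_ : fitted sklearn Pipeline (scaler + SVC)
    classes_ : array of class labels
    layout_hash_ : hash of the feature layout seen in ``fit``; ``predict``
        and ``decision_function`` refuse matrices with a different layout.
    """

    def __init__(
        self,
        kernel: str = DEFAULT_KERNEL,
        C: float = DEFAULT_C,
        gamma: float = DEFAULT_GAMMA,
        degree: int = 3,
        coef0: float = 0.0,
        class_weight=None,
        normalize: bool = True,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.class_weight = class_weight
        self.normalize = normalize

    def _build(self) -> Pipeline:
        svc = SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            degree=self.degree,
            coef0=self.coef0,
            class_weight=self.class_weight,
        )
        steps = [("scale", MapMinMaxScaler())] if self.normalize else []
        return Pipeline(steps + [("svm", svc)])

    def fit(self, X, y, feature_names: Sequence[str] | None = None) -> "HairpinClassifier":
        X = MapMinMaxScaler._validate(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.pipeline_ = self._build().fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self.layout_hash_ = _layout_hash(X.shape[1], self.feature_names_)
        return self

    def _check_layout(self, X, feature_names: Sequence[str] | None) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        X = MapMinMaxScaler._validate(X)
        names = list(feature_names) if feature_names is not None else self.feature_names_
        if _layout_hash(X.shape[1], names) != self.layout_hash_:
            raise ValueError(
                "feature layout differs from the one seen at fit time "
                f"({X.shape[1]} columns vs {self.n_features_in_})"
            )
        return X

    def predict(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        return self.pipeline_.predict(self._check_layout(X, feature_names))

    def decision_function(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        return self.pipeline_.decision_function(self._check_layout(X, feature_names))

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "pipeline_")
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "HairpinClassifier":
        obj = joblib.load(Path(path))
        if not isinstance(obj, cls):
            raise TypeError(f"{path}: not a saved {cls.__name__}")
        return obj


def train(
    X,
    y,
    kernel: str = DEFAULT_KERNEL,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    class_weight=None,
    feature_names: Sequence[str] | None = None,
) -> HairpinClassifier:
    """Train a classifier at a fixed operating point (thin wrapper)."""
    clf = HairpinClassifier(kernel=kernel, C=C, gamma=gamma, class_weight=class_weight)
    return clf.fit(X, y, feature_names=feature_names)


def predict(model: HairpinClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus decision scores (higher = more positive)."""
    return model.predict(X), model.decision_function(X)


def grid_search(
    X,
    y,
    c_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    kernel: str = DEFAULT_KERNEL,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (C, gamma) maximising mean stratified-CV accuracy.

    Candidates are scanned in ascending (C, gamma) order and a new optimum
    must be strictly better, so ties resolve to the smaller C, then the
    smaller gamma. Fold assignment is derived from ``seed``.

    Returns ``(C, gamma, best_mean_accuracy)``.
    """
    X = MapMinMaxScaler._validate(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes present")
    c_grid = sorted(c_grid if c_grid is not None else DEFAULT_C_GRID)
    gamma_grid = sorted(gamma_grid if gamma_grid is not None else DEFAULT_GAMMA_GRID)
    if not c_grid or not gamma_grid:
        raise ValueError("empty parameter grid")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    best: tuple[float, float, float] | None = None
    for C in c_grid:
        for gamma in gamma_grid:
            accs = []
            for train_idx, test_idx in splits:
                clf = HairpinClassifier(kernel=kernel, C=C, gamma=gamma)
                clf.fit(X[train_idx], y[train_idx])
                accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[2]:
                best = (C, gamma, mean_acc)
    return best
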