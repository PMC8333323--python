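"""Comparison classifiers behind the same train/predict contract as GMDH.

Linear discriminant analysis (the linear-boundary reference), an RBF-kernel
soft-margin SVM with grid-tuned hyperparameters, and a single-hidden-layer
perceptron (10 logistic units) with validation-based early stopping.  All are
thin wrappers over scikit-learn; each exposes ``fit``, ``predict`` and
``decision_scores`` (a continuous score per subject — discriminant value,
margin, or output activation — so AUCs are never computed from hard labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gmdh import mcc_from_counts

__all__ = [
    "BaselineConfig",
    "LDABaseline",
    "SVMBaseline",
    "MLPBaseline",
    "make_baseline",
    "train_baseline",
    "predict_baseline",
]


@dataclass(frozen=True)
class BaselineConfig:
    kind: str = "LDA"                      # LDA | SVM | MLP
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    mlp_hidden_units: int = 10
    mlp_max_iter: int = 500
    seed: int = 0


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class _Base:
    def fit(self, X, y):
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        raise NotImplementedError

    def decision_scores(self, X) -> np.ndarray:
        raise NotImplementedError


class LDABaseline(_Base):
    """Closed-form linear discriminant; score = signed discriminant value."""

    def __init__(self, config: BaselineConfig = BaselineConfig(kind="LDA")):
        self.config = config
        self._model = LinearDiscriminantAnalysis()

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("LDA requires both classes in training data")
        self._model.fit(_as_array(X), y)
        return self

    def predict(self, X):
        return self._model.predict(_as_array(X))

    def decision_scores(self, X):
        return self._model.decision_function(_as_array(X))


class SVMBaseline(_Base):
    """RBF-kernel SVM; kernel radius and soft margin grid-tuned by
    validation MCC on an internal 75/25 stratified split, then refitted on
    the full training data.  Score = signed margin."""

    def __init__(self, config: BaselineConfig = BaselineConfig(kind="SVM")):
        self.config = config
        self._model: SVC | None = None
        self._scaler = StandardScaler()
        self.best_params_: tuple[float, float] | None = None

    def fit(self, X, y):
        X = _as_array(X)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("SVM requires both classes in training data")
        X = self._scaler.fit_transform(X)
        rng = np.random.default_rng([self.config.seed, 41])
        est_idx, val_idx = [], []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_est = min(max(int(round(0.75 * idx.size)), 1), idx.size - 1)
            est_idx.append(idx[:n_est])
            val_idx.append(idx[n_est:])
        est = np.concatenate(est_idx)
        val = np.concatenate(val_idx)
        best = None
        for C in self.config.svm_c_grid:
            for gamma in self.config.svm_gamma_grid:
                m = SVC(C=C, gamma=gamma, kernel="rbf")
                m.fit(X[est], y[est])
                pred = m.predict(X[val])
                tp = np.sum((y[val] == 1) & (pred == 1))
                tn = np.sum((y[val] == 0) & (pred == 0))
                fp = np.sum((y[val] == 0) & (pred == 1))
                fn = np.sum((y[val] == 1) & (pred == 0))
                fit_val = mcc_from_counts(tp, tn, fp, fn)
                if best is None or fit_val > best[0]:
                    best = (fit_val, C, gamma)
        _, C, gamma = best
        self.best_params_ = (C, gamma)
        self._model = SVC(C=C, gamma=gamma, kernel="rbf")
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(self._scaler.transform(_as_array(X)))

    def decision_scores(self, X):
        return self._model.decision_function(self._scaler.transform(_as_array(X)))


class MLPBaseline(_Base):
    """One hidden layer of 10 sigmoid units, plain cross-entropy loss,
    early stopping on a 25% validation split.  Score = positive-class
    output activation."""

    def __init__(self, config: BaselineConfig = BaselineConfig(kind="MLP")):
        self.config = config
        self._scaler = StandardScaler()
        self._model = MLPClassifier(
            hidden_layer_sizes=(config.mlp_hidden_units,),
            activation="logistic",
            early_stopping=True,
            validation_fraction=0.25,
            max_iter=config.mlp_max_iter,
            random_state=config.seed,
        )

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("MLP requires both classes in training data")
        self._model.fit(self._scaler.fit_transform(_as_array(X)), y)
        return self

    def predict(self, X):
        return self._model.predict(self._scaler.transform(_as_array(X)))

    def decision_scores(self, X):
        proba = self._model.predict_proba(self._scaler.transform(_as_array(X)))
        return proba[:, list(self._model.classes_).index(1)]


_KINDS = {"LDA": LDABaseline, "SVM": SVMBaseline, "MLP": MLPBaseline}


def make_baseline(config: BaselineConfig) -> _Base:
    try:
        cls = _KINDS[config.kind.upper()]
    except KeyError:
        raise ValueError(f"unknown baseline kind {config.kind!r}") from None
    return cls(config)


def train_baseline(config: BaselineConfig, covariates, outcome) -> _Base:
    return make_baseline(config).fit(covariates, outcome)


def predict_baseline(model: _Base, covariates) -> tuple[np.ndarray, np.ndarray]:
    X = _as_array(covariates)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    return model.predict(X), model.decision_scores(X)
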