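"""Classifier training and evaluation for the five outcome problems.

The modelling surface follows the fit/results convention of statistical
packages: :class:`OutcomeModel` is built from a feature table with a label
column; :meth:`OutcomeModel.fit` tunes one classifier family's
hyperparameters by stratified 10-fold cross-validated MCC on the training
split only, evaluates once on the held-out test split, and returns an
:class:`OutcomeResults` carrying confusion counts, accuracy, ROC area, MCC,
the Zero-R baseline, the per-feature information-gain ranking and a
``summary()`` table.  Classifier internals delegate to scikit-learn; the
metrics, baseline, cross-validation protocol and MDL discretisation are the
in-house implementations of :mod:`navvar.metrics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics
from .ep import split_train_test
from .features import one_hot

METHODS = ("naive_bayes", "random_forest", "knn", "svm", "mlp")

#: hyperparameter grids searched by cross-validated MCC (kept deliberately
#: small; configurable by passing ``grid=`` to fit)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "naive_bayes": [{"alpha": 1.0}, {"alpha": 0.25}],
    "random_forest": [
        {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1},
        {"n_estimators": 100, "class_weight": "balanced"},
        {"n_estimators": 200, "max_depth": 4, "max_features": None,
         "class_weight": "balanced"},
    ],
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 9)],
    "svm": [{"C": c, "gamma": "scale", "class_weight": w}
            for c in (1.0, 10.0) for w in (None, "balanced")],
    "mlp": [{"hidden_layer_sizes": h, "alpha": 1e-3, "max_iter": 400}
            for h in ((16,), (32,))],
}


class ModelError(ValueError):
    pass


class MixedNB:
    """Naive Bayes over mixed feature types: categorical attributes get
    Laplace-smoothed multinomial likelihoods (nominal attributes modelled
    natively, not one-hot), numeric attributes a per-class Gaussian with a
    pooled variance floor."""

    def __init__(self, alpha: float = 1.0, var_smoothing: float = 1e-9):
        self.alpha = alpha
        self.var_smoothing = var_smoothing

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(list(y))
        self.classes_ = sorted(y.unique())
        self.cat_cols_ = [c for c in X.columns
                          if X[c].dtype == object or str(X[c].dtype) == "category"]
        self.num_cols_ = [c for c in X.columns if c not in self.cat_cols_]
        self.log_prior_ = {c: np.log((y == c).mean()) for c in self.classes_}
        self.cat_loglik_: dict = {}
        self.gauss_: dict = {}
        if self.num_cols_:
            pooled = float(X[self.num_cols_].var(ddof=0).max())
            floor = max(self.var_smoothing * pooled, 1e-12)
        else:
            floor = 1e-12
        for cls in self.classes_:
            sub = X[(y == cls).values]
            for col in self.cat_cols_:
                levels = sorted(map(str, X[col].astype(str).unique()))
                counts = sub[col].astype(str).value_counts()
                denom = len(sub) + self.alpha * len(levels)
                table = {lvl: np.log((counts.get(lvl, 0) + self.alpha) / denom)
                         for lvl in levels}
                self.cat_loglik_[(cls, col)] = (table, np.log(self.alpha / denom))
            for col in self.num_cols_:
                v = sub[col].astype(float)
                self.gauss_[(cls, col)] = (
                    float(v.mean()), max(float(v.var(ddof=0)), floor))
        return self

    def _joint_log_likelihood(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros((len(X), len(self.classes_)))
        for j, cls in enumerate(self.classes_):
            ll = np.full(len(X), self.log_prior_[cls])
            for col in self.cat_cols_:
                table, unseen = self.cat_loglik_[(cls, col)]
                ll += X[col].astype(str).map(
                    lambda v: table.get(v, unseen)).to_numpy(float)
            for col in self.num_cols_:
                mu, var = self.gauss_[(cls, col)]
                v = X[col].to_numpy(float)
                ll += -0.5 * np.log(2 * np.pi * var) - 0.5 * (v - mu) ** 2 / var
            out[:, j] = ll
        return out

    def predict_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        jll = self._joint_log_likelihood(X)
        return np.array(self.classes_, dtype=object)[np.argmax(jll, axis=1)]


class _FrameWrapper:
    """Adapt an sklearn estimator to raw feature frames: one-hot encodes
    categoricals with the training columns frozen."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X: pd.DataFrame, y):
        encoded = one_hot(X)
        self.columns_ = encoded.columns
        self.estimator.fit(encoded.astype(float), y)
        self.classes_ = self.estimator.classes_
        return self

    def _encode(self, X: pd.DataFrame) -> pd.DataFrame:
        return one_hot(X).reindex(columns=self.columns_,
                                  fill_value=0.0).astype(float)

    def predict(self, X):
        return self.estimator.predict(self._encode(X))

    def predict_proba(self, X):
        return self.estimator.predict_proba(self._encode(X))

    def decision_function(self, X):
        return self.estimator.decision_function(self._encode(X))


def _build_estimator(method: str, params: dict, seed: int):
    if method == "naive_bayes":
        return MixedNB(**params)
    if method == "random_forest":
        est = RandomForestClassifier(random_state=seed, **params)
    elif method == "knn":
        est = make_pipeline(StandardScaler(), KNeighborsClassifier(**params))
    elif method == "svm":
        est = make_pipeline(StandardScaler(), SVC(random_state=seed, **params))
    elif method == "mlp":
        est = make_pipeline(StandardScaler(),
                            MLPClassifier(random_state=seed, **params))
    else:
        raise ModelError(f"unknown method {method!r}; choose from {METHODS}")
    return _FrameWrapper(est)


def _scores(estimator, X, classes) -> np.ndarray:
    """Per-class score matrix (probabilities or scaled decision values)."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        est_classes = list(estimator.classes_)
    else:
        dec = estimator.decision_function(X)
        est_classes = list(estimator.classes_)
        if dec.ndim == 1:
            proba = np.column_stack([-dec, dec])
        else:
            proba = dec
    out = np.zeros((len(X), len(classes)))
    for j, cls in enumerate(classes):
        if cls in est_classes:
            out[:, j] = proba[:, est_classes.index(cls)]
    return out


@dataclass
class OutcomeResults:
    """Fitted evaluation of one method on one classification problem."""

    problem: str
    method: str
    params: dict
    classes: list
    confusion: np.ndarray
    accuracy: float
    auc: float
    mcc: float
    baseline: dict
    info_gain: pd.Series
    cv_mcc: float
    n_train: int
    n_test: int
    seed: int
    roc: np.ndarray | None = None
    multiclass: bool = False

    def summary(self) -> str:
        lines = [
            f"Problem: {self.problem}",
            f"Method:  {self.method}  {self.params}",
            f"Train/test sizes: {self.n_train}/{self.n_test}   seed: {self.seed}",
            f"CV MCC (train, 10-fold): {self.cv_mcc:+.3f}",
            "",
            f"{'metric':<12}{'model':>10}{'Zero-R':>10}",
            f"{'accuracy':<12}{self.accuracy:>10.3f}{self.baseline['accuracy']:>10.3f}",
            f"{'AUC':<12}{self.auc:>10.3f}{self.baseline['auc']:>10.3f}",
            f"{'MCC':<12}{self.mcc:>+10.3f}{self.baseline['mcc']:>+10.3f}",
            "",
            "Confusion matrix (rows = true " + "/".join(map(str, self.classes)) + "):",
        ]
        for i, cls in enumerate(self.classes):
            lines.append(f"  {str(cls):<12}" +
                         "".join(f"{self.confusion[i, j]:>7d}"
                                 for j in range(len(self.classes))))
        lines += ["", "Information gain per feature (bits, train set):"]
        for name, gain in self.info_gain.items():
            lines.append(f"  {name:<22}{gain:8.4f}")
        return "\n".join(lines)

    def metrics_dict(self) -> dict:
        return {
            "problem": self.problem, "method": self.method,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.params.items()},
            "accuracy": round(self.accuracy, 6), "auc": round(self.auc, 6),
            "mcc": round(self.mcc, 6), "cv_mcc": round(self.cv_mcc, 6),
            "baseline": {k: round(v, 6) for k, v in self.baseline.items()},
            "confusion": self.confusion.tolist(),
            "n_train": self.n_train, "n_test": self.n_test, "seed": self.seed,
            "info_gain": {k: round(float(v), 6)
                          for k, v in self.info_gain.items()},
        }


class OutcomeModel:
    """One classification problem: a feature table plus binary or ternary
    labels, split once into train and test."""

    def __init__(self, data: pd.DataFrame, problem: str = "outcome",
                 label_col: str = "label", test_fraction: float = 1 / 3,
                 seed: int = 0):
        if label_col not in data.columns:
            raise ModelError(f"no {label_col!r} column in data")
        self.problem = problem
        self.label_col = label_col
        self.seed = seed
        self.data = data.reset_index(drop=True)
        self.train, self.test = split_train_test(
            self.data.rename(columns={label_col: "label"}),
            train_fraction=1 - test_fraction, seed=seed)
        self.classes = sorted(self.data[label_col].unique())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "OutcomeModel":
        return cls(data, **kwargs)

    # -- internals --------------------------------------------------------

    def _matrices(self):
        """Raw feature frames; missing numerics imputed by train median
        (estimators one-hot encode categoricals themselves as needed)."""
        train_X = self.train.drop(columns=["label"])
        test_X = self.test.drop(columns=["label"])
        med = train_X.median(numeric_only=True)
        return train_X.fillna(med).fillna(0.0), test_X.fillna(med).fillna(0.0)

    def _cv_mcc(self, method, params, X, y, folds, seed) -> float:
        """Pooled out-of-fold MCC under stratified K-fold CV."""
        min_class = y.value_counts().min()
        n_splits = min(folds, int(min_class), len(y))
        if n_splits < folds:
            warnings.warn(f"reducing CV folds {folds} -> {n_splits} "
                          "(smallest class too small)")
        if n_splits < 2:
            return 0.0
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        pooled_true, pooled_pred = [], []
        for train_idx, val_idx in cv.split(X, y):
            est = _build_estimator(method, params, seed)
            est.fit(X.iloc[train_idx], y.iloc[train_idx])
            pooled_pred.extend(est.predict(X.iloc[val_idx]))
            pooled_true.extend(y.iloc[val_idx])
        return metrics.mcc(pooled_true, pooled_pred)

    # -- fitting ----------------------------------------------------------

    def fit(self, method: str = "naive_bayes", seed: int | None = None,
            cv_folds: int = 10, grid: list[dict] | None = None) -> OutcomeResults:
        """Tune ``method`` by CV MCC on the training split, then evaluate
        once on the untouched test split."""
        seed = self.seed if seed is None else seed
        if method not in DEFAULT_GRIDS:
            raise ModelError(f"unknown method {method!r}; choose from {METHODS}")
        if grid is None:
            grid = DEFAULT_GRIDS[method]
        train_X, test_X = self._matrices()
        y_train = self.train["label"]
        y_test = self.test["label"]
        best_params, best_cv = None, -np.inf
        for params in grid:
            cv_score = self._cv_mcc(method, params, train_X, y_train,
                                    cv_folds, seed)
            if cv_score > best_cv:
                best_params, best_cv = params, cv_score
        est = _build_estimator(method, best_params, seed)
        est.fit(train_X, y_train)
        y_pred = est.predict(test_X)
        scores = _scores(est, test_X, self.classes)
        confusion, classes = metrics.confusion_matrix(
            y_test, y_pred, classes=self.classes)
        accuracy = float(np.trace(confusion) / confusion.sum())
        mcc_val = metrics.mcc(list(y_test), list(y_pred))
        multiclass = len(self.classes) > 2
        roc = None
        if multiclass:
            auc = metrics.macro_ovr_auc(scores, list(y_test), self.classes)
        else:
            positive = self.classes[0] if self.classes[0] == "affected" \
                else self.classes[-1]
            pos_scores = scores[:, self.classes.index(positive)]
            auc = metrics.roc_auc(pos_scores, list(y_test), positive=positive)
            roc = metrics.roc_curve(pos_scores, list(y_test), positive)
        zero_r = metrics.ZeroR().fit(None, list(y_train))
        baseline = {"accuracy": zero_r.accuracy(list(y_test)),
                    "auc": 0.5, "mcc": 0.0}
        info_gain = pd.Series(
            {col: metrics.information_gain(self.train[col], y_train)
             for col in self.train.columns if col != "label"},
            dtype=float).sort_values(ascending=False)
        return OutcomeResults(
            problem=self.problem, method=method, params=best_params,
            classes=classes, confusion=confusion, accuracy=accuracy,
            auc=auc, mcc=mcc_val, baseline=baseline, info_gain=info_gain,
            cv_mcc=float(best_cv), n_train=len(y_train), n_test=len(y_test),
            seed=seed, roc=roc, multiclass=multiclass)

    def fit_all(self, methods=("naive_bayes", "random_forest"),
                seed: int | None = None, cv_folds: int = 10) -> dict:
        """Fit several methods; ``best`` is the one with highest CV MCC
        (selection uses training data only)."""
        results = {m: self.fit(m, seed=seed, cv_folds=cv_folds) for m in methods}
        best = max(results.values(), key=lambda r: r.cv_mcc)
        return {"results": results, "best": best}


def tune_and_evaluate(dataset: pd.DataFrame, method: str, seed: int = 0,
                      problem: str = "outcome", cv_folds: int = 10) -> OutcomeResults:
    """Functional wrapper: split, tune by CV MCC, evaluate on test."""
    model = OutcomeModel(dataset, problem=problem, seed=seed)
    return model.fit(method, seed=seed, cv_folds=cv_folds)


def evaluate_shift_problem(dataset: pd.DataFrame, method: str,
                           seed: int = 0) -> OutcomeResults:
    """Three-bin (neg/mid/pos) midpoint-shift problem: accuracy, macro
    one-vs-rest AUC and generalised multiclass MCC."""
    labels = set(dataset["label"])
    if not labels <= {"neg", "mid", "pos"}:
        raise ModelError(f"shift labels must be neg/mid/pos, got {sorted(labels)}")
    if len(labels) < 3:
        warnings.warn(f"shift dataset is missing classes: only {sorted(labels)}")
    model = OutcomeModel(dataset, problem="shift", seed=seed)
    return model.fit(method, seed=seed)
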