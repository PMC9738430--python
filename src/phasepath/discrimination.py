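"""Eight-classifier healthy/tumoral benchmark with FP/FN error decomposition.

The bench trains, on the five phase parameters, the eight classifier families
used in the reference workflow — linear and quadratic discriminant analysis
(LDA, QDA), Gaussian and kernel naive Bayes (NB, kNB), k-nearest neighbors
(kNN, k = 5, Euclidean), a linear support vector machine (SVM; with two
classes the one-vs-one coding collapses to a single binary machine), a Gini
decision tree with minimum parent size 10 (DT), and a small feed-forward
neural network (ANN, one hidden layer of 10 units) — and evaluates each with
two protocols:

* **re-substitution** — train on all data, predict the same data (optimistic);
* **cross-validation** — repeated stratified k-fold (default 10 folds x 5
  repeats); held-out predictions are pooled within each repeat and the FP/FN
  rates averaged over repeats.

Errors are decomposed by true class with *tumoral as the positive class*:
``fp_rate`` is the fraction of healthy samples called tumoral, ``fn_rate`` the
fraction of tumoral samples called healthy, and the reported ``total`` is
their sum (so chance-level performance on balanced classes sits near 1.0, not
0.5).  Features are z-scored with statistics of the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .reference import PARAMETERS

ALGORITHMS = ("LDA", "QDA", "NB", "kNB", "kNN", "SVM", "DT", "ANN")

POSITIVE_CLASS = "tumoral"

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LDA": {},
    "QDA": {"reg_param": 1e-3},  # regularized covariance: survives degenerate features
    "NB": {},
    "kNB": {},
    "kNN": {"n_neighbors": 5},
    "SVM": {"kernel": "linear"},
    "DT": {"min_parent_size": 10},
    "ANN": {"hidden_units": 10, "deep": False, "max_iter": 500},
}


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel-density class conditionals.

    Each feature's class-conditional density is a kernel smoothing density
    estimate with a normal-reference (Silverman) bandwidth computed per
    feature per class; class priors are the empirical relative frequencies.
    Implemented here because the scikit-learn naive Bayes family offers only
    parametric conditionals.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.log_priors_ = np.log(counts / counts.sum())
        self.train_: list[np.ndarray] = []
        self.bandwidths_: list[np.ndarray] = []
        for c in self.classes_:
            xc = X[y == c]
            n = len(xc)
            sd = xc.std(axis=0, ddof=1) if n > 1 else np.zeros(xc.shape[1])
            iqr = np.subtract(*np.percentile(xc, [75, 25], axis=0))
            spread = np.minimum(sd, iqr / 1.34, out=sd.copy(), where=iqr > 0)
            h = 0.9 * spread * n ** (-0.2)
            h = np.where(h > 0, h, 1e-9)  # degenerate (constant) features
            self.train_.append(xc)
            self.bandwidths_.append(h)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((len(X), len(self.classes_)))
        for ci in range(len(self.classes_)):
            xc, h = self.train_[ci], self.bandwidths_[ci]
            # (n_test, n_train, n_features) standardized distances
            z = (X[:, None, :] - xc[None, :, :]) / h
            log_k = -0.5 * z**2 - np.log(h) - 0.5 * np.log(2 * np.pi)
            feat_ll = logsumexp(log_k, axis=1) - np.log(len(xc))
            jll[:, ci] = self.log_priors_[ci] + feat_ll.sum(axis=1)
        return jll

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """One configured classifier of the bench."""

    algorithm: str
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def resolved(self) -> dict:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(self.hyperparameters)
        return merged


@dataclass(frozen=True)
class ErrorRates:
    """FP/FN decomposition of a two-class evaluation (positive = tumoral)."""

    fp_rate: float  # healthy called tumoral
    fn_rate: float  # tumoral called healthy

    @property
    def total(self) -> float:
        return self.fp_rate + self.fn_rate

    @property
    def sensitivity(self) -> float:
        return 1.0 - self.fn_rate

    @property
    def specificity(self) -> float:
        return 1.0 - self.fp_rate


def build_estimator(spec: ClassifierSpec) -> Pipeline:
    """Assemble the scaler + classifier pipeline for one spec."""
    hp = spec.resolved()
    alg = spec.algorithm
    if alg == "LDA":
        est = LinearDiscriminantAnalysis(**hp)
    elif alg == "QDA":
        est = QuadraticDiscriminantAnalysis(**hp)
    elif alg == "NB":
        est = GaussianNB(**hp)
    elif alg == "kNB":
        est = KernelNaiveBayes(**hp)
    elif alg == "kNN":
        est = KNeighborsClassifier(metric="euclidean", **hp)
    elif alg == "SVM":
        est = SVC(random_state=spec.seed, **hp)
    elif alg == "DT":
        est = DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=hp.get("min_parent_size", 10),
            random_state=spec.seed,
        )
    elif alg == "ANN":
        width = hp.get("hidden_units", 10)
        layers = (width,) * 10 if hp.get("deep", False) else (width,)
        est = MLPClassifier(
            hidden_layer_sizes=layers,
            solver="lbfgs",
            max_iter=hp.get("max_iter", 500),
            random_state=spec.seed,
        )
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(alg)
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _design_matrix(
    cohort: pd.DataFrame, features: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    X = cohort.loc[:, list(features)].to_numpy(dtype=float)
    y = cohort["state"].to_numpy()
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} rows with non-finite features", stacklevel=3
        )
        X, y = X[finite], y[finite]
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both healthy and tumoral samples")
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant feature columns {[f for f, c in zip(features, constant) if c]}; "
            "classifiers fall back to regularized covariances",
            stacklevel=3,
        )
    return X, y


def train_classifier(
    spec: ClassifierSpec,
    cohort: pd.DataFrame,
    features: tuple[str, ...] = PARAMETERS,
) -> Pipeline:
    """Fit one classifier on the full cohort (z-scored features)."""
    X, y = _design_matrix(cohort, features)
    model = build_estimator(spec)
    model.fit(X, y)
    return model


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> ErrorRates:
    healthy = y_true != POSITIVE_CLASS
    tumoral = y_true == POSITIVE_CLASS
    fp = float(np.mean(y_pred[healthy] == POSITIVE_CLASS)) if healthy.any() else 0.0
    fn = float(np.mean(y_pred[tumoral] != POSITIVE_CLASS)) if tumoral.any() else 0.0
    return ErrorRates(fp_rate=fp, fn_rate=fn)


def resubstitution_errors(
    spec: ClassifierSpec,
    cohort: pd.DataFrame,
    features: tuple[str, ...] = PARAMETERS,
) -> ErrorRates:
    """Train on all data, predict the same data, decompose errors by class."""
    X, y = _design_matrix(cohort, features)
    model = build_estimator(spec)
    model.fit(X, y)
    return _rates(y, model.predict(X))


def cross_validation_errors(
    spec: ClassifierSpec,
    cohort: pd.DataFrame,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    features: tuple[str, ...] = PARAMETERS,
) -> ErrorRates:
    """Repeated stratified k-fold cross-validation error.

    Held-out predictions are pooled over the folds of one repeat; the FP/FN
    rates of the repeats are then averaged.  The fold assignment is controlled
    by ``seed`` (one reshuffle per repeat) and the scaler is re-fit inside each
    training fold, so no test-fold statistics leak into training.
    """
    X, y = _design_matrix(cohort, features)
    min_class = int(np.bincount(pd.factorize(y)[0]).min())
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds from {folds}",
            stacklevel=2,
        )
        folds = max(2, min_class)

    fp_list, fn_list = [], []
    for rep in range(repeats):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        pred = np.empty(len(y), dtype=y.dtype)
        for train_idx, test_idx in cv.split(X, y):
            model = build_estimator(spec)
            model.fit(X[train_idx], y[train_idx])
            pred[test_idx] = model.predict(X[test_idx])
        rates = _rates(y, pred)
        fp_list.append(rates.fp_rate)
        fn_list.append(rates.fn_rate)
    return ErrorRates(fp_rate=float(np.mean(fp_list)), fn_rate=float(np.mean(fn_list)))


def default_bench(seed: int = 0) -> list[ClassifierSpec]:
    """The eight-classifier bench with its default hyperparameters."""
    return [ClassifierSpec(algorithm=a, seed=seed) for a in ALGORITHMS]


def error_report(
    cohort: pd.DataFrame,
    specs: list[ClassifierSpec] | None = None,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    features: tuple[str, ...] = PARAMETERS,
    flag_threshold: float = 0.1,
) -> pd.DataFrame:
    """Full evaluation per classifier x tissue x magnification.

    One row per (classifier, tissue, magnification, protocol) with columns
    ``fp, fn, total, sensitivity, specificity, flagged``; a cell is flagged
    when its total error (FP + FN) is below ``flag_threshold``.  Cells with a
    missing class are reported blank with a warning column entry.
    """
    if specs is None:
        specs = default_bench(seed=seed)
    rows = []
    for (tissue, mag), grp in sorted(cohort.groupby(["tissue", "magnification"]), key=lambda kv: kv[0]):
        for spec in specs:
            for protocol in ("resub", "cv"):
                row = {
                    "classifier": spec.algorithm,
                    "tissue": tissue,
                    "magnification": mag,
                    "error_type": protocol,
                    "warning": "",
                }
                try:
                    if protocol == "resub":
                        rates = resubstitution_errors(spec, grp, features=features)
                    else:
                        rates = cross_validation_errors(
                            spec, grp, folds=folds, repeats=repeats, seed=seed, features=features
                        )
                    row.update(
                        fp=rates.fp_rate,
                        fn=rates.fn_rate,
                        total=rates.total,
                        sensitivity=rates.sensitivity,
                        specificity=rates.specificity,
                        flagged=rates.total < flag_threshold,
                    )
                except ValueError as exc:
                    row.update(
                        fp=np.nan, fn=np.nan, total=np.nan,
                        sensitivity=np.nan, specificity=np.nan,
                        flagged=False, warning=str(exc),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "ALGORITHMS",
    "POSITIVE_CLASS",
    "ClassifierSpec",
    "ErrorRates",
    "KernelNaiveBayes",
    "build_estimator",
    "train_classifier",
    "resubstitution_errors",
    "cross_validation_errors",
    "default_bench",
    "error_report",
]
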