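"""Classifiers for discriminating CI from HC participants.

Four procedures are provided:

1. fixed literature thresholds on the CDT (cutoff 6) and Phototest
   (cutoff 29), classifying CI when the score falls strictly below the
   cutoff;
2. the sequential rule (CDT first; Phototest only for CDT passers);
3. a global-AM threshold learned by maximising training accuracy, evaluated
   under leave-one-out cross-validation ("RSVP (AM)");
4. grid-searched regularised logistic regression on the 14-dimensional
   AB/AM feature matrix under leave-one-out cross-validation ("RSVP (LR)").

Logistic fits use scikit-learn with solvers that leave the intercept
unpenalised (lbfgs for l2, saga for l1), tolerance 1e-8 and an iteration
budget of 10000.  Features are z-scored with training-fold statistics by
default; per-fold fitting keeps the held-out participant out of both the
scaler and the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import ConvergenceError, SingleClassError, ConfigError

CI, HC = "CI", "HC"

#: Literature screening cutoffs: score strictly below => CI.
CDT_CUTOFF = 6.0
PHOTOTEST_CUTOFF = 29.0

#: Default hyperparameter grid: both penalties x C = 10^-7 .. 10^7.
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0 ** e for e in range(-7, 8))
DEFAULT_PENALTIES: tuple[str, ...] = ("l1", "l2")


@dataclass(frozen=True)
class ThresholdRule:
    """Classify CI when the score is strictly below ``cutoff``."""

    cutoff: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ConfigError("threshold cutoff must be finite")


@dataclass(frozen=True)
class LogisticSpec:
    """Penalty type and inverse regularisation strength for a logistic fit."""

    penalty: str = "l2"
    c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2"):
            raise ConfigError(f"penalty {self.penalty!r} not in ('l1', 'l2')")
        if not self.c > 0:
            raise ConfigError("c must be > 0")


@dataclass(frozen=True)
class LoocvPredictions:
    """Leave-one-out predictions: one label per participant, in input order,
    plus a per-fold summary of the fitted artifact (threshold value or
    hyperparameters)."""

    predicted: tuple[str, ...]
    fold_artifacts: tuple[object, ...]

    def accuracy(self, true_labels: Sequence[str]) -> float:
        t = np.asarray(true_labels, dtype=object)
        p = np.asarray(self.predicted, dtype=object)
        if len(t) != len(p):
            raise ConfigError("label/prediction length mismatch")
        return float(np.mean(t == p))


def threshold_predict(score: float, rule: ThresholdRule) -> str:
    """CI iff score < cutoff (a boundary score classifies HC)."""
    return CI if score < rule.cutoff else HC


def sequential_predict(cdt_score: float, phototest_score: float) -> str:
    """CDT gate first, then the Phototest gate for CDT passers."""
    if cdt_score < CDT_CUTOFF:
        return CI
    if phototest_score < PHOTOTEST_CUTOFF:
        return CI
    return HC


def fit_optimal_threshold(scores, labels) -> ThresholdRule:
    """Learn the cutoff maximising training accuracy of the strict-below rule.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    scores plus one sentinel below the minimum and one above the maximum
    (classify-none / classify-all).  Ties break toward the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise SingleClassError("training data must contain both CI and HC")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best_cut, best_acc = None, -1.0
    for c in candidates:
        pred = np.where(scores < c, CI, HC)
        acc = float(np.mean(pred == labels))
        if acc > best_acc:  # strict: first (= smallest) candidate wins ties
            best_cut, best_acc = float(c), acc
    return ThresholdRule(cutoff=best_cut)


def loocv_threshold(scores, labels) -> LoocvPredictions:
    """Leave-one-out evaluation of the learned-threshold classifier."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(scores)
    if n < 3:
        raise ConfigError("LOOCV needs at least 3 participants")
    preds, artifacts = [], []
    for i in range(n):
        mask = np.arange(n) != i
        rule = fit_optimal_threshold(scores[mask], labels[mask])
        preds.append(threshold_predict(float(scores[i]), rule))
        artifacts.append(rule.cutoff)
    return LoocvPredictions(predicted=tuple(preds), fold_artifacts=tuple(artifacts))


@dataclass(frozen=True)
class FittedLogistic:
    """Fitted penalised logistic model (coefficients live in standardised
    space when the LogisticSpec requests standardisation)."""

    spec: LogisticSpec
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray | None
    scaler_scale: np.ndarray | None
    n_iter: int

    def predict_proba_ci(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, features: np.ndarray) -> np.ndarray:
        p = self.predict_proba_ci(features)
        return np.where(p > 0.5, CI, HC).astype(object)


def fit_logistic(
    features, labels, spec: LogisticSpec, *, strict: bool = True
) -> FittedLogistic:
    """Penalised maximum-likelihood logistic fit (CI encoded as 1).

    The penalty never touches the intercept.  With ``strict`` the fit
    raises :class:`ConvergenceError` (carrying the iteration count) if the
    solver exhausts its 10000-iteration budget; with ``strict=False`` the
    max-iteration solution is returned, which is how the grid search
    traverses extreme C values.
    """
    X = np.asarray(features, dtype=float)
    y_lab = np.asarray(labels, dtype=object)
    if len(set(y_lab)) < 2:
        raise SingleClassError("logistic fit needs both classes present")
    if np.isnan(X).any():
        raise ConfigError("feature matrix contains undefined values")
    y = (y_lab == CI).astype(int)

    scaler_mean = scaler_scale = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        scaler_scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        scaler_mean = scaler.mean_
        X = (X - scaler_mean) / scaler_scale

    solver = "saga" if spec.penalty == "l1" else "lbfgs"
    model = LogisticRegression(
        penalty=spec.penalty,
        C=spec.c,
        solver=solver,
        tol=1e-8,
        max_iter=10_000,
        random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    n_iter = int(np.max(model.n_iter_))
    if strict and any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise ConvergenceError(
            f"logistic fit did not converge within {n_iter} iterations "
            f"(penalty={spec.penalty}, C={spec.c:g})",
            n_iter=n_iter,
        )
    return FittedLogistic(
        spec=spec,
        coef=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
        n_iter=n_iter,
    )


def loocv_logistic(features, labels, spec: LogisticSpec) -> LoocvPredictions:
    """Leave-one-out predictions for one hyperparameter combination."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    n = len(y)
    preds, artifacts = [], []
    for i in range(n):
        mask = np.arange(n) != i
        model = fit_logistic(X[mask], y[mask], spec, strict=False)
        preds.append(str(model.predict(X[i : i + 1])[0]))
        artifacts.append((spec.penalty, spec.c))
    return LoocvPredictions(predicted=tuple(preds), fold_artifacts=tuple(artifacts))


@dataclass(frozen=True)
class GridSearchResult:
    best_spec: LogisticSpec
    predictions: LoocvPredictions
    accuracy: float
    grid_accuracies: dict[tuple[str, float], float]


def grid_search_loocv(
    features,
    labels,
    *,
    penalties: Sequence[str] = DEFAULT_PENALTIES,
    c_values: Sequence[float] = DEFAULT_C_GRID,
    standardize: bool = True,
) -> GridSearchResult:
    """LOOCV accuracy over the full penalty x C grid; return the best point.

    Ties break toward the stronger penalty (smaller C), then l2 before l1.
    """
    if len(penalties) == 0 or len(c_values) == 0:
        raise ConfigError("grid must be non-empty")
    y = np.asarray(labels, dtype=object)
    results: dict[tuple[str, float], tuple[float, LoocvPredictions]] = {}
    for pen in penalties:
        for c in c_values:
            spec = LogisticSpec(penalty=pen, c=float(c), standardize=standardize)
            preds = loocv_logistic(features, y, spec)
            results[(pen, float(c))] = (preds.accuracy(y), preds)

    def sort_key(item):
        (pen, c), (acc, _) = item
        return (-acc, c, 0 if pen == "l2" else 1)

    (best_pen, best_c), (best_acc, best_preds) = min(results.items(), key=sort_key)
    return GridSearchResult(
        best_spec=LogisticSpec(penalty=best_pen, c=best_c, standardize=standardize),
        predictions=best_preds,
        accuracy=best_acc,
        grid_accuracies={k: v[0] for k, v in results.items()},
    )
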