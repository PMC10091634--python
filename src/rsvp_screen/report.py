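"""Evaluation reports: confusion matrices, macro metrics, Wilson intervals,
and assembly of the full study report.

CI is the positive class throughout.  Precision and recall are *macro*
averages — the mean of the per-class value over the two classes, weighting
the classes equally.  The confidence interval around an accuracy treats the
n predictions as a series of Bernoulli trials and inverts the score test
(the Wilson interval), computed through statsmodels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import classification as clf
from . import group_stats
from .classification import CI, HC
from .cohort import ParticipantRecord
from .errors import LabelError, MissingInputError, RsvpScreenError
from .performance import build_feature_matrix, compute_curve, compute_global_imputed


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with CI as the positive class."""

    tp: int  # CI predicted CI
    fn: int  # CI predicted HC
    fp: int  # HC predicted CI
    tn: int  # HC predicted HC

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise LabelError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassificationReport:
    """Macro precision/recall, accuracy, and its 95% Wilson interval."""

    method: str
    precision_macro: float
    recall_macro: float
    accuracy: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.accuracy <= self.ci_high:
            raise ValueError("accuracy must lie inside its confidence interval")


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Count the four outcomes of a CI/HC prediction run."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise LabelError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    foreign = {lbl for lbl in t + p if lbl not in (CI, HC)}
    if foreign:
        raise LabelError(f"foreign labels {sorted(foreign)}; expected CI/HC")
    tp = sum(1 for a, b in zip(t, p) if a == CI and b == CI)
    fn = sum(1 for a, b in zip(t, p) if a == CI and b == HC)
    fp = sum(1 for a, b in zip(t, p) if a == HC and b == CI)
    tn = sum(1 for a, b in zip(t, p) if a == HC and b == HC)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise RsvpScreenError("n must be >= 1")
    if not 0 <= successes <= n:
        raise RsvpScreenError(f"successes {successes} outside [0, {n}]")
    if not 0.0 < confidence < 1.0:
        raise RsvpScreenError("confidence must lie in (0, 1)")
    low, high = proportion_confint(successes, n, alpha=1.0 - confidence, method="wilson")
    return float(low), float(high)


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has an empty denominator; contributing 0", stacklevel=3)
        return 0.0
    return num / den


def summarize(cm: ConfusionMatrix, method: str = "", confidence: float = 0.95) -> ClassificationReport:
    """Macro precision/recall, accuracy and Wilson CI from a confusion matrix."""
    if cm.n == 0:
        raise RsvpScreenError("empty confusion matrix")
    prec_ci = _safe_ratio(cm.tp, cm.tp + cm.fp, "CI precision")
    prec_hc = _safe_ratio(cm.tn, cm.tn + cm.fn, "HC precision")
    rec_ci = _safe_ratio(cm.tp, cm.tp + cm.fn, "CI recall")
    rec_hc = _safe_ratio(cm.tn, cm.tn + cm.fp, "HC recall")
    accuracy = (cm.tp + cm.tn) / cm.n
    low, high = wilson_interval(cm.tp + cm.tn, cm.n, confidence)
    return ClassificationReport(
        method=method,
        precision_macro=(prec_ci + prec_hc) / 2.0,
        recall_macro=(rec_ci + rec_hc) / 2.0,
        accuracy=accuracy,
        ci_low=low,
        ci_high=high,
    )


# ---------------------------------------------------------------------------
# full study report


def _group_values(cohort, getter):
    ci = [getter(r) for r in cohort if r.group == CI]
    hc = [getter(r) for r in cohort if r.group == HC]
    return ci, hc


def _table1_row(name: str, ci_vals, hc_vals) -> dict:
    res = group_stats.mann_whitney(ci_vals, hc_vals)
    return {
        "test": name,
        "mean_ci": float(np.mean(ci_vals)),
        "sem_ci": group_stats.sem(ci_vals),
        "mean_hc": float(np.mean(hc_vals)),
        "sem_hc": group_stats.sem(hc_vals),
        "p_value": res.p_two_sided,
        "u_value": res.u_reported,
        "effect_size": res.effect_size,
        "significant": res.p_two_sided <= 0.05,
        "method": res.method,
    }


def build_report(cohort: Sequence[ParticipantRecord]) -> dict:
    """Run the complete analysis on one cohort.

    Returns a nested dict with four blocks: ``group_comparison`` (one row
    per test: group means +/- SEM, U, p, effect size), ``classification``
    (per-method macro precision/recall/accuracy with 95% Wilson CI),
    ``confusion_matrices`` and ``hyperparameters`` (the logistic grid and
    the selected combination).  Deterministic given the cohort.
    """
    if len(cohort) == 0:
        raise MissingInputError("empty cohort")
    groups = {r.group for r in cohort}
    if groups != {CI, HC}:
        raise MissingInputError(f"cohort must contain both CI and HC, found {sorted(groups)}")

    globals_ = {}
    for r in cohort:
        globals_[r.participant_id] = compute_global_imputed(
            compute_curve(r.outcomes), participant_id=r.participant_id
        )

    true_labels = [r.group for r in cohort]

    # --- group comparison (Table-1 analogue) ---
    cdt_ci, cdt_hc = _group_values(cohort, lambda r: r.cdt_score)
    photo_ci, photo_hc = _group_values(cohort, lambda r: r.phototest_score)
    am_ci, am_hc = _group_values(cohort, lambda r: globals_[r.participant_id].global_am)
    ab_ci, ab_hc = _group_values(cohort, lambda r: globals_[r.participant_id].global_ab)
    table1 = [
        _table1_row("CDT", cdt_ci, cdt_hc),
        _table1_row("Phototest", photo_ci, photo_hc),
        _table1_row("RSVP (global AM)", am_ci, am_hc),
        _table1_row("RSVP (global AB)", ab_ci, ab_hc),
    ]

    # --- classifiers ---
    cdt_rule = clf.ThresholdRule(cutoff=clf.CDT_CUTOFF)
    photo_rule = clf.ThresholdRule(cutoff=clf.PHOTOTEST_CUTOFF)
    preds: dict[str, list[str]] = {
        "CDT": [clf.threshold_predict(r.cdt_score, cdt_rule) for r in cohort],
        "Phototest": [clf.threshold_predict(r.phototest_score, photo_rule) for r in cohort],
        "Sequential": [
            clf.sequential_predict(r.cdt_score, r.phototest_score) for r in cohort
        ],
    }
    am_scores = [globals_[r.participant_id].global_am for r in cohort]
    preds["RSVP (AM)"] = list(clf.loocv_threshold(am_scores, true_labels).predicted)

    X, y = build_feature_matrix(cohort)
    grid = clf.grid_search_loocv(X, y)
    preds["RSVP (LR)"] = list(grid.predictions.predicted)

    table2, table3 = [], {}
    for method, p in preds.items():
        cm = confusion(true_labels, p)
        table3[method] = asdict(cm)
        table2.append(asdict(summarize(cm, method=method)))

    table4 = {
        "penalties": list(clf.DEFAULT_PENALTIES),
        "c_values": list(clf.DEFAULT_C_GRID),
        "best_penalty": grid.best_spec.penalty,
        "best_c": grid.best_spec.c,
        "best_loocv_accuracy": grid.accuracy,
        "grid_accuracies": {
            f"{pen},{c:g}": acc for (pen, c), acc in sorted(grid.grid_accuracies.items())
        },
    }

    return {
        "n_ci": sum(1 for r in cohort if r.group == CI),
        "n_hc": sum(1 for r in cohort if r.group == HC),
        "group_comparison": table1,
        "classification": table2,
        "confusion_matrices": table3,
        "hyperparameters": table4,
        "predictions": {
            m: {r.participant_id: p for r, p in zip(cohort, pl)} for m, pl in preds.items()
        },
    }


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def report_tables(report: dict) -> dict[str, pd.DataFrame]:
    """The report's four blocks as DataFrames, rounded to 2 decimals for
    display; raw precision is preserved in the JSON report."""
    t1 = pd.DataFrame(report["group_comparison"])
    t2 = pd.DataFrame(report["classification"])
    t3 = pd.DataFrame(report["confusion_matrices"]).T
    for df in (t1, t2):
        for col in df.select_dtypes(include=[float]).columns:
            df[col] = df[col].round(2)
    return {"group_comparison": t1, "classification": t2, "confusion_matrices": t3}
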