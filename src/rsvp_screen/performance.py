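"""Attentional blink / attentional masking performance metrics.

For each separation ``s`` the two conditional accuracies are

* attentional blink   AB(s) = P(T2 correct | T1 correct) = n_both / n_t1
* attentional masking AM(s) = P(T1 correct | T2 correct) = n_both / n_t2

estimated from the trial counts at that separation.  The *global* AB and AM
summarise the short separations where the two effects are strongest: each is
the mean of the per-separation value over separations 0, 1 and 2, expressed
as a percentage (0-100) to match how group summaries are conventionally
reported.  Per-separation values stay on the 0-1 scale internally.

A conditional with a zero denominator is undefined and stored as ``None``;
when a complete feature vector is required, undefined cells are imputed as 0
(worst performance) with a warning — a participant who never reports T1
correctly has no measurable blink but is maximally impaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyOutcomesError, UndefinedMetricError
from .task_design import SEPARATIONS, TrialOutcome

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ParticipantRecord

#: Separations entering the global metrics.
GLOBAL_SEPARATIONS: tuple[int, ...] = (0, 1, 2)

#: Fixed feature ordering: all AB then all AM, ascending separation.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"ab_sep{s}" for s in SEPARATIONS] + [f"am_sep{s}" for s in SEPARATIONS]
)


@dataclass(frozen=True)
class SeparationCounts:
    """Raw counts at one separation."""

    n_trials: int
    n_t1: int
    n_t2: int
    n_both: int

    def __post_init__(self) -> None:
        ok = 0 <= self.n_both <= min(self.n_t1, self.n_t2) and (
            max(self.n_t1, self.n_t2) <= self.n_trials
        )
        if not ok:
            raise ValueError(f"inconsistent counts {self}")

    @property
    def ab(self) -> float | None:
        """P(T2 | T1), or None when no trial had T1 correct."""
        return self.n_both / self.n_t1 if self.n_t1 > 0 else None

    @property
    def am(self) -> float | None:
        """P(T1 | T2), or None when no trial had T2 correct."""
        return self.n_both / self.n_t2 if self.n_t2 > 0 else None


@dataclass(frozen=True)
class PerformanceCurve:
    """Per-separation counts and conditional accuracies for one participant."""

    counts: dict[int, SeparationCounts]

    def ab(self, separation: int) -> float | None:
        return self.counts[separation].ab if separation in self.counts else None

    def am(self, separation: int) -> float | None:
        return self.counts[separation].am if separation in self.counts else None

    @property
    def separations(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))


@dataclass(frozen=True)
class GlobalMetrics:
    """Global AB and AM on the 0-100 percentage scale."""

    global_ab: float
    global_am: float

    def __post_init__(self) -> None:
        for v in (self.global_ab, self.global_am):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"global metric {v} outside [0, 100]")


def compute_curve(outcomes: Sequence[TrialOutcome]) -> PerformanceCurve:
    """Tabulate trial outcomes into a per-separation performance curve."""
    if len(outcomes) == 0:
        raise EmptyOutcomesError("cannot compute a performance curve from zero trials")
    counts: dict[int, SeparationCounts] = {}
    seps = sorted({o.separation for o in outcomes})
    for s in seps:
        trials = [o for o in outcomes if o.separation == s]
        counts[s] = SeparationCounts(
            n_trials=len(trials),
            n_t1=sum(o.t1_correct for o in trials),
            n_t2=sum(o.t2_correct for o in trials),
            n_both=sum(o.t1_correct and o.t2_correct for o in trials),
        )
    return PerformanceCurve(counts=counts)


def compute_global(curve: PerformanceCurve) -> GlobalMetrics:
    """Average AB and AM over separations 0, 1, 2, as percentages.

    Raises :class:`UndefinedMetricError` naming the offending separation if
    any of the six entering conditionals is undefined.
    """
    abs_, ams = [], []
    for s in GLOBAL_SEPARATIONS:
        a, m = curve.ab(s), curve.am(s)
        if a is None:
            raise UndefinedMetricError(f"AB undefined at separation {s} (no T1-correct trial)")
        if m is None:
            raise UndefinedMetricError(f"AM undefined at separation {s} (no T2-correct trial)")
        abs_.append(a)
        ams.append(m)
    return GlobalMetrics(
        global_ab=100.0 * float(np.mean(abs_)),
        global_am=100.0 * float(np.mean(ams)),
    )


def compute_global_imputed(
    curve: PerformanceCurve, *, participant_id: str | None = None
) -> GlobalMetrics:
    """Like :func:`compute_global`, but an undefined conditional is imputed
    as 0 (worst performance) with a warning instead of raising.

    This mirrors the feature-matrix imputation rule and is what the cohort
    analysis uses when every participant must receive a numeric score.
    """
    abs_, ams = [], []
    for s in GLOBAL_SEPARATIONS:
        for name, vals, v in (("AB", abs_, curve.ab(s)), ("AM", ams, curve.am(s))):
            if v is None:
                who = f" for participant {participant_id}" if participant_id else ""
                warnings.warn(
                    f"{name} undefined at separation {s}{who}; imputing 0",
                    stacklevel=2,
                )
                v = 0.0
            vals.append(v)
    return GlobalMetrics(
        global_ab=100.0 * float(np.mean(abs_)),
        global_am=100.0 * float(np.mean(ams)),
    )


def feature_vector(
    curve: PerformanceCurve, *, participant_id: str | None = None
) -> np.ndarray:
    """The 14-element feature vector: AB then AM at each separation.

    Undefined cells are imputed as 0 with a warning.
    """
    values: list[float] = []
    for name, getter in (("AB", curve.ab), ("AM", curve.am)):
        for s in SEPARATIONS:
            v = getter(s)
            if v is None:
                who = f" for participant {participant_id}" if participant_id else ""
                warnings.warn(
                    f"{name} undefined at separation {s}{who}; imputing 0 (worst performance)",
                    stacklevel=2,
                )
                v = 0.0
            values.append(float(v))
    return np.asarray(values)


def build_feature_matrix(
    cohort: "Sequence[ParticipantRecord]",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-participant feature vectors into an (n, 14) matrix.

    Returns the matrix and the aligned group-label array.
    """
    rows = []
    labels = []
    for rec in cohort:
        curve = compute_curve(rec.outcomes)
        rows.append(feature_vector(curve, participant_id=rec.participant_id))
        labels.append(rec.group)
    return np.vstack(rows), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# tabular output


def curve_frame(participant_id: str, curve: PerformanceCurve) -> pd.DataFrame:
    """One row per separation: counts plus AB/AM fractions (NaN if undefined)."""
    rows = []
    for s in curve.separations:
        c = curve.counts[s]
        rows.append(
            {
                "participant_id": participant_id,
                "sep": s,
                "n_trials": c.n_trials,
                "n_t1": c.n_t1,
                "n_t2": c.n_t2,
                "n_both": c.n_both,
                "ab": np.nan if c.ab is None else c.ab,
                "am": np.nan if c.am is None else c.am,
            }
        )
    return pd.DataFrame(rows)


def feature_frame(cohort: "Sequence[ParticipantRecord]") -> pd.DataFrame:
    """Feature matrix as a DataFrame with the 14 named columns plus labels."""
    X, y = build_feature_matrix(cohort)
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df.insert(0, "participant_id", [r.participant_id for r in cohort])
    df["group"] = y
    return df
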