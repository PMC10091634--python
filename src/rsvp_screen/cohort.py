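"""Synthetic CI/HC cohort generator.

The study cohort is unavailable, so every downstream stage is exercised on a
generative stand-in with the same statistical structure: 13 cognitively
impaired (CI) and 9 healthy control (HC) participants, each completing 70
RSVP trials (10 per separation), plus integer Clock-drawing test (CDT,
support 0-7) and Phototest (support >= 0) scores.

Published group summaries report only the conditional accuracies (AB, AM)
and their global means — conditionals alone do not identify a sampling
model — so the generator is parameterised by the per-(group, separation)
*joint* distribution of the four (T1 correct, T2 correct) outcomes.  The
default model sets the conditionals at separations 0-2 flat at the published
group means (global AB 55.88 / AM 47.32 for CI; 88.61 / 69.89 for HC) and
gives separations 4-8 a qualitative recovery shape: rising for CI, uniformly
high for HC.  The remaining free parameter p11 is fixed at 0.9 of its
feasibility maximum (see docs/methods.md).

CDT and Phototest scores are rounded normals clamped to their supports, with
standard deviations recovered from the published standard errors
(sd = SEM * sqrt(n)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidGroupError
from .task_design import SEPARATIONS, TrialOutcome

GROUPS = ("CI", "HC")

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class JointOutcome:
    """Joint probabilities of (T1 correct, T2 correct) at one separation.

    ``p11`` = both correct, ``p10`` = T1 only, ``p01`` = T2 only,
    ``p00`` = neither.
    """

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        ps = (self.p11, self.p10, self.p01, self.p00)
        if any(p < -_PROB_TOL for p in ps):
            raise ConfigError(f"negative joint probability in {ps}")
        if abs(sum(ps) - 1.0) > 1e-6:
            raise ConfigError(f"joint probabilities {ps} do not sum to 1")

    @property
    def ab(self) -> float | None:
        """Analytic AB = P(T2 | T1) = p11 / (p11 + p10)."""
        d = self.p11 + self.p10
        return self.p11 / d if d > 0 else None

    @property
    def am(self) -> float | None:
        """Analytic AM = P(T1 | T2) = p11 / (p11 + p01)."""
        d = self.p11 + self.p01
        return self.p11 / d if d > 0 else None

    def as_array(self) -> np.ndarray:
        a = np.array([self.p11, self.p10, self.p01, self.p00])
        a = np.clip(a, 0.0, None)
        return a / a.sum()


def joint_from_conditionals(ab: float, am: float, p11_frac: float = 0.9) -> JointOutcome:
    """Build a joint distribution with prescribed conditionals AB and AM.

    The conditionals pin down the ratios p10/p11 and p01/p11; the scale p11
    remains free up to the feasibility bound p11 * (1/ab + 1/am - 1) <= 1.
    ``p11_frac`` places p11 at that fraction of the bound.
    """
    if not (0 < ab <= 1 and 0 < am <= 1):
        raise ConfigError("conditionals must lie in (0, 1]")
    if not (0 < p11_frac <= 1):
        raise ConfigError("p11_frac must lie in (0, 1]")
    p11_max = 1.0 / (1.0 / ab + 1.0 / am - 1.0)
    p11 = p11_frac * p11_max
    p10 = p11 * (1.0 - ab) / ab
    p01 = p11 * (1.0 - am) / am
    p00 = 1.0 - p11 - p10 - p01
    return JointOutcome(p11=p11, p10=p10, p01=p01, p00=max(p00, 0.0))


@dataclass(frozen=True)
class ScoreDistribution:
    """Rounded normal clamped to an integer support."""

    mean: float
    sd: float
    lower: int = 0
    upper: int | None = None

    def draw(self, rng: np.random.Generator) -> int:
        x = int(round(rng.normal(self.mean, self.sd)))
        x = max(x, self.lower)
        if self.upper is not None:
            x = min(x, self.upper)
        return x


@dataclass(frozen=True)
class OutcomeModel:
    """Per-group generative model: joint trial outcomes plus test scores."""

    joint: dict[str, dict[int, JointOutcome]]
    cdt: dict[str, ScoreDistribution]
    phototest: dict[str, ScoreDistribution]

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.joint or g not in self.cdt or g not in self.phototest:
                raise ConfigError(f"model missing group {g}")
            missing = set(SEPARATIONS) - set(self.joint[g])
            if missing:
                raise ConfigError(f"model group {g} missing separations {sorted(missing)}")
            for dist in (self.cdt[g], self.phototest[g]):
                if dist.upper is not None and dist.upper < dist.lower:
                    raise ConfigError("score support is empty")

    def analytic_global(self, group: str) -> tuple[float, float]:
        """Analytic (global_ab, global_am) percentages implied by the model."""
        js = [self.joint[group][s] for s in (0, 1, 2)]
        ab = 100.0 * float(np.mean([j.ab for j in js]))
        am = 100.0 * float(np.mean([j.am for j in js]))
        return ab, am


# Published group summaries the default model is calibrated to:
# global AB / AM means, and test-score means with sd = SEM * sqrt(n).
TABLE_MEANS = {
    "CI": {"global_ab": 55.88, "global_am": 47.32, "cdt": 5.69, "phototest": 33.08},
    "HC": {"global_ab": 88.61, "global_am": 69.89, "cdt": 6.56, "phototest": 41.56},
}
TABLE_SEMS = {
    "CI": {"global_ab": 8.77, "global_am": 8.77, "cdt": 0.49, "phototest": 1.63},
    "HC": {"global_ab": 2.62, "global_am": 4.68, "cdt": 0.32, "phototest": 1.07},
}
GROUP_SIZES = {"CI": 13, "HC": 9}

# Qualitative recovery shape at the long separations (not calibrated to any
# published number): CI climbs back toward ceiling, HC stays high.
_RECOVERY = {
    "CI": {4: (0.70, 0.58), 5: (0.74, 0.62), 6: (0.78, 0.66), 8: (0.84, 0.72)},
    "HC": {4: (0.91, 0.82), 5: (0.92, 0.84), 6: (0.93, 0.86), 8: (0.94, 0.88)},
}


def default_model(p11_frac: float = 0.9) -> OutcomeModel:
    """The calibrated default generative model (see module docstring)."""
    joint: dict[str, dict[int, JointOutcome]] = {}
    for g in GROUPS:
        ab = TABLE_MEANS[g]["global_ab"] / 100.0
        am = TABLE_MEANS[g]["global_am"] / 100.0
        per_sep = {s: joint_from_conditionals(ab, am, p11_frac) for s in (0, 1, 2)}
        for s, (ab_s, am_s) in _RECOVERY[g].items():
            per_sep[s] = joint_from_conditionals(ab_s, am_s, p11_frac)
        joint[g] = per_sep
    n = GROUP_SIZES
    cdt = {
        g: ScoreDistribution(
            mean=TABLE_MEANS[g]["cdt"],
            sd=TABLE_SEMS[g]["cdt"] * np.sqrt(n[g]),
            lower=0,
            upper=7,
        )
        for g in GROUPS
    }
    phototest = {
        g: ScoreDistribution(
            mean=TABLE_MEANS[g]["phototest"],
            sd=TABLE_SEMS[g]["phototest"] * np.sqrt(n[g]),
            lower=0,
            upper=None,
        )
        for g in GROUPS
    }
    return OutcomeModel(joint=joint, cdt=cdt, phototest=phototest)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and trial design."""

    n_ci: int = 13
    n_hc: int = 9
    trials_per_separation: int = 10
    model: OutcomeModel = field(default_factory=default_model)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_ci < 1 or self.n_hc < 1:
            raise ConfigError("both groups need at least one participant")
        if self.trials_per_separation < 1:
            raise ConfigError("trials_per_separation must be >= 1")


@dataclass(frozen=True)
class ParticipantRecord:
    """One synthetic participant: group, test scores, and scored RSVP trials."""

    participant_id: str
    group: str
    cdt_score: int
    phototest_score: int
    outcomes: tuple[TrialOutcome, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidGroupError(f"group {self.group!r} not in {GROUPS}")


def simulate_participant(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "P000",
) -> ParticipantRecord:
    """Draw one participant: trial outcomes from the group's joint model at
    each separation (session order randomised), and clamped integer test
    scores."""
    if group not in GROUPS:
        raise InvalidGroupError(f"group {group!r} not in {GROUPS}")
    model = config.model
    seps = np.repeat(SEPARATIONS, config.trials_per_separation)
    seps = seps[rng.permutation(len(seps))]
    # one vectorised categorical draw per separation (outcome order: p11, p10, p01, p00)
    cats = np.empty(len(seps), dtype=np.int64)
    for s in SEPARATIONS:
        idx = np.nonzero(seps == s)[0]
        cats[idx] = rng.choice(4, size=len(idx), p=model.joint[group][s].as_array())
    outcomes = []
    for tid, (s, k) in enumerate(zip(seps, cats)):
        outcomes.append(
            TrialOutcome(
                trial_id=tid,
                separation=int(s),
                t1_correct=k in (0, 1),
                t2_correct=k in (0, 2),
            )
        )
    return ParticipantRecord(
        participant_id=participant_id,
        group=group,
        cdt_score=model.cdt[group].draw(rng),
        phototest_score=model.phototest[group].draw(rng),
        outcomes=tuple(outcomes),
    )


def simulate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[ParticipantRecord]:
    """Simulate the full cohort (CI participants first, then HC)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_ci):
        records.append(
            simulate_participant("CI", config, rng, participant_id=f"CI{i:03d}")
        )
    for i in range(config.n_hc):
        records.append(
            simulate_participant("HC", config, rng, participant_id=f"HC{i:03d}")
        )
    return records


# ---------------------------------------------------------------------------
# file I/O: a cohort is a participants CSV plus a trial-outcome CSV


def write_cohort(cohort: Sequence[ParticipantRecord], directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in cohort],
            "group": [r.group for r in cohort],
            "cdt_score": [r.cdt_score for r in cohort],
            "phototest_score": [r.phototest_score for r in cohort],
        }
    ).to_csv(d / "participants.csv", index=False)
    rows = []
    for r in cohort:
        for o in r.outcomes:
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "trial_id": o.trial_id,
                    "separation": o.separation,
                    "t1_correct": int(o.t1_correct),
                    "t2_correct": int(o.t2_correct),
                }
            )
    pd.DataFrame(rows).to_csv(d / "outcomes.csv", index=False)


def read_cohort(directory: str | Path) -> list[ParticipantRecord]:
    d = Path(directory)
    participants = pd.read_csv(d / "participants.csv")
    outcomes = pd.read_csv(d / "outcomes.csv")
    records = []
    for _, row in participants.iterrows():
        sub = outcomes[outcomes["participant_id"] == row["participant_id"]]
        trial_outcomes = tuple(
            TrialOutcome(
                trial_id=int(t.trial_id),
                separation=int(t.separation),
                t1_correct=bool(t.t1_correct),
                t2_correct=bool(t.t2_correct),
            )
            for t in sub.itertuples(index=False)
        )
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                cdt_score=int(row["cdt_score"]),
                phototest_score=int(row["phototest_score"]),
                outcomes=trial_outcomes,
            )
        )
    return records


# ---------------------------------------------------------------------------
# model JSON round-trip


def model_to_json(model: OutcomeModel, path: str | Path) -> None:
    payload = {
        "joint": {
            g: {
                str(s): {"p11": j.p11, "p10": j.p10, "p01": j.p01, "p00": j.p00}
                for s, j in model.joint[g].items()
            }
            for g in GROUPS
        },
        "cdt": {
            g: {
                "mean": d.mean,
                "sd": d.sd,
                "lower": d.lower,
                "upper": d.upper,
            }
            for g, d in model.cdt.items()
        },
        "phototest": {
            g: {
                "mean": d.mean,
                "sd": d.sd,
                "lower": d.lower,
                "upper": d.upper,
            }
            for g, d in model.phototest.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def model_from_json(path: str | Path) -> OutcomeModel:
    payload = json.loads(Path(path).read_text())
    joint = {
        g: {int(s): JointOutcome(**j) for s, j in per_sep.items()}
        for g, per_sep in payload["joint"].items()
    }
    cdt = {g: ScoreDistribution(**d) for g, d in payload["cdt"].items()}
    phototest = {g: ScoreDistribution(**d) for g, d in payload["phototest"].items()}
    return OutcomeModel(joint=joint, cdt=cdt, phototest=phototest)
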