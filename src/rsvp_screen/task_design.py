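"""RSVP trial design: character pools, trial/session generation, and scoring.

The task presents a rapid stream of characters (digits as distractors, two
letters as targets T1 and T2) and the participant reports both letters.  A
trial is parameterised by its *separation*: the number of digit distractors
strictly between T1 and T2.  The seven task conditions use separations
{0, 1, 2, 4, 5, 6, 8}; a full session is 70 trials, 10 per separation, in
randomised order.

Only the schedule and the scoring live here — no stimulus is ever rendered.
Timing constants (150 ms per character, 9 frames at 60 Hz) are carried as
metadata on each trial.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidSeparationError, StreamLengthError

#: The seven separation conditions (digits strictly between T1 and T2).
SEPARATIONS: tuple[int, ...] = (0, 1, 2, 4, 5, 6, 8)

#: Letters excluded from the target pool because they are visually
#: confusable with digits or with each other.
EXCLUDED_LETTERS = frozenset("IOQSUVWXZ")

#: Digits retained as distractors for the same confusability reason.
DIGITS = frozenset("346789")

TRIALS_PER_SEPARATION_DEFAULT = 10


def build_character_pools() -> tuple[frozenset[str], frozenset[str]]:
    """Return (letter_pool, digit_pool) for targets and distractors.

    The letter pool is the 26-letter Latin alphabet minus the nine
    confusable letters I, O, Q, S, U, V, W, X, Z (17 letters); the digit
    pool is {3, 4, 6, 7, 8, 9}.
    """
    alphabet = frozenset(chr(c) for c in range(ord("A"), ord("Z") + 1))
    return alphabet - EXCLUDED_LETTERS, DIGITS


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled RSVP trial.

    ``stream`` is the full character sequence; ``t1_pos``/``t2_pos`` are
    0-based indices of the two letter targets, with
    ``t2_pos - t1_pos == separation + 1``.
    """

    trial_id: int
    separation: int
    stream: str
    t1_pos: int
    t2_pos: int
    t1: str
    t2: str
    char_duration_ms: float = 150.0
    frames_per_char: int = 9

    def __post_init__(self) -> None:
        if self.separation not in SEPARATIONS:
            raise InvalidSeparationError(
                f"separation {self.separation} not in {SEPARATIONS}"
            )
        if self.t2_pos - self.t1_pos != self.separation + 1:
            raise ValueError("target positions inconsistent with separation")
        if self.stream[self.t1_pos] != self.t1 or self.stream[self.t2_pos] != self.t2:
            raise ValueError("targets do not match stream contents")


@dataclass(frozen=True)
class TrialOutcome:
    """Scored result of one trial: whether each target was reported correctly."""

    trial_id: int
    separation: int
    t1_correct: bool
    t2_correct: bool

    def __post_init__(self) -> None:
        if self.separation not in SEPARATIONS:
            raise InvalidSeparationError(
                f"separation {self.separation} not in {SEPARATIONS}"
            )


def _draw_distractors(n: int, rng: np.random.Generator, forbid_first: str | None) -> list[str]:
    """Draw ``n`` digits with no two consecutive identical digits.

    ``forbid_first`` prevents the first drawn digit from fusing with a
    digit immediately preceding it in the stream.
    """
    pool = sorted(DIGITS)
    out: list[str] = []
    prev = forbid_first
    for _ in range(n):
        choices = [d for d in pool if d != prev]
        d = choices[rng.integers(len(choices))]
        out.append(d)
        prev = d
    return out


def generate_trial(
    separation: int,
    rng: np.random.Generator,
    *,
    trial_id: int = 0,
    stream_length: int | None = None,
    pre_t1_range: tuple[int, int] = (5, 10),
    post_t2: int = 3,
) -> TrialSpec:
    """Generate one trial at the given separation.

    The number of leading distractors before T1 is drawn uniformly from
    ``pre_t1_range`` (inclusive) unless ``stream_length`` pins it down;
    ``post_t2`` trailing distractors follow T2 so it is never the final
    character (T2 must remain maskable).  Deterministic given ``rng`` state.
    """
    if separation not in SEPARATIONS:
        raise InvalidSeparationError(f"separation {separation} not in {SEPARATIONS}")
    if stream_length is not None:
        pre_t1 = stream_length - post_t2 - (separation + 2)
        if pre_t1 < 1:
            raise StreamLengthError(
                f"stream_length {stream_length} cannot hold separation {separation} "
                f"plus 2 targets, {post_t2} trailing distractors and >=1 leading"
            )
    else:
        lo, hi = pre_t1_range
        pre_t1 = int(rng.integers(lo, hi + 1))

    letters = sorted(build_character_pools()[0])
    t1, t2 = (letters[i] for i in rng.choice(len(letters), size=2, replace=False))

    head = _draw_distractors(pre_t1, rng, forbid_first=None)
    between = _draw_distractors(separation, rng, forbid_first=None)
    tail = _draw_distractors(post_t2, rng, forbid_first=None)
    stream = "".join(head) + t1 + "".join(between) + t2 + "".join(tail)
    t1_pos = pre_t1
    t2_pos = pre_t1 + separation + 1
    return TrialSpec(
        trial_id=trial_id,
        separation=separation,
        stream=stream,
        t1_pos=t1_pos,
        t2_pos=t2_pos,
        t1=t1,
        t2=t2,
    )


def generate_session(
    rng: np.random.Generator,
    *,
    trials_per_separation: int = TRIALS_PER_SEPARATION_DEFAULT,
    **trial_kwargs,
) -> list[TrialSpec]:
    """Generate a full session: ``trials_per_separation`` trials per
    separation (70 total at the default), in randomised order.

    Trial ids are assigned by final presentation order.
    """
    seps = [s for s in SEPARATIONS for _ in range(trials_per_separation)]
    order = rng.permutation(len(seps))
    return [
        generate_trial(seps[j], rng, trial_id=i, **trial_kwargs)
        for i, j in enumerate(order)
    ]


def score_trial(
    spec: TrialSpec,
    reported_t1: str | None,
    reported_t2: str | None,
) -> TrialOutcome:
    """Score verbal reports against the trial's targets.

    Matching is case-insensitive (the reports are transcribed by a
    technician, so letter case carries no information); a missing report
    scores as incorrect.
    """

    def _match(target: str, reported: str | None) -> bool:
        return reported is not None and reported.upper() == target.upper()

    return TrialOutcome(
        trial_id=spec.trial_id,
        separation=spec.separation,
        t1_correct=_match(spec.t1, reported_t1),
        t2_correct=_match(spec.t2, reported_t2),
    )


# ---------------------------------------------------------------------------
# serialization


def session_to_json(trials: Sequence[TrialSpec], path: str | Path) -> None:
    """Write a session schedule as a JSON list (one object per trial)."""
    payload = [asdict(t) for t in trials]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def session_from_json(path: str | Path) -> list[TrialSpec]:
    payload = json.loads(Path(path).read_text())
    return [TrialSpec(**obj) for obj in payload]


OUTCOME_CSV_HEADER = ["participant_id", "trial_id", "separation", "t1_correct", "t2_correct"]


def outcomes_to_csv(
    rows: Iterable[tuple[str, TrialOutcome]], path: str | Path
) -> None:
    """Write (participant_id, outcome) pairs as the trial-outcome CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OUTCOME_CSV_HEADER)
        for pid, o in rows:
            w.writerow([pid, o.trial_id, o.separation, int(o.t1_correct), int(o.t2_correct)])


def outcomes_from_csv(path: str | Path) -> list[tuple[str, TrialOutcome]]:
    out: list[tuple[str, TrialOutcome]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                (
                    row["participant_id"],
                    TrialOutcome(
                        trial_id=int(row["trial_id"]),
                        separation=int(row["separation"]),
                        t1_correct=bool(int(row["t1_correct"])),
                        t2_correct=bool(int(row["t2_correct"])),
                    ),
                )
            )
    return out
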