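"""Data-quality screening and trial-table assembly.

Two eligibility rules are applied to raw online-survey response streams:

* completeness — complete questionnaires and at least 75% of the 48-trial
  emotional experience task;
* long-string screening — careless responding flagged when more than 50
  identical answers occur consecutively ("more than" is strict: a run of
  exactly 50 passes).

"Similar answers" is operationalized as identical raw answer values counted
over the concatenated stream (questionnaire items in presentation order,
then task ratings in rating order); run counting across the questionnaire /
task boundary can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .affect_scoring import RATING_MAX, RATING_MIN, ValidationError

CATEGORIES = ("pleasant", "neutral", "unpleasant")

TRIAL_COLUMNS = [
    "participant_id",
    "stimulus_id",
    "category",
    "social",
    "positivity",
    "negativity",
    "arousal",
]


@dataclass
class RawResponseStream:
    """One participant's ordered raw answers.

    ``questionnaire_answers`` holds item responses in presentation order
    (``None`` marks a missing answer); ``task_ratings`` holds, per trial, a
    tuple of the three ratings (entries may be ``None`` for missing).
    """

    participant_id: str
    questionnaire_answers: list = field(default_factory=list)
    task_ratings: list = field(default_factory=list)
    n_trials: int = 48

    @property
    def task_completion(self) -> float:
        """Fraction of trials with all three ratings present."""
        done = sum(
            1
            for t in self.task_ratings
            if t is not None and all(r is not None for r in t)
        )
        return done / self.n_trials

    @property
    def questionnaire_complete(self) -> bool:
        return all(a is not None for a in self.questionnaire_answers)

    def answer_stream(self, span_boundary: bool = True) -> list:
        """Concatenated non-missing answer values in presentation order.

        With ``span_boundary=False`` a sentinel break is inserted between the
        questionnaire and the task so identical-value runs cannot cross it.
        """
        stream = [a for a in self.questionnaire_answers if a is not None]
        if not span_boundary:
            stream.append(object())  # unique sentinel, never equal to an answer
        for t in self.task_ratings:
            if t is not None:
                stream.extend(r for r in t if r is not None)
        return stream


def longest_run(values: Sequence) -> int:
    """Length of the longest run of consecutive identical values."""
    best = run = 0
    prev = object()
    for v in values:
        run = run + 1 if v == prev else 1
        prev = v
        best = max(best, run)
    return best


def long_string_flag(
    stream: RawResponseStream, threshold: int = 50, span_boundary: bool = True
) -> bool:
    """True iff the longest identical-answer run strictly exceeds ``threshold``."""
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    values = stream.answer_stream(span_boundary=span_boundary)
    if not values:
        raise ValidationError(f"participant {stream.participant_id}: empty answer stream")
    return longest_run(values) > threshold


def eligibility_filter(
    streams: Iterable[RawResponseStream],
    min_completion: float = 0.75,
    long_string_threshold: int = 50,
    span_boundary: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Apply completeness and long-string rules; return kept ids + exclusion log.

    Rules are checked in study order: questionnaire completeness, then task
    completion (>= ``min_completion``, inclusive), then long-string screening.
    The log has one row per excluded participant with the first failing reason.
    """
    if not (0 < min_completion <= 1):
        raise ValidationError(f"min_completion must be in (0, 1], got {min_completion}")
    kept: list[str] = []
    log_rows: list[dict] = []
    for s in streams:
        if not s.questionnaire_complete:
            log_rows.append({"participant_id": s.participant_id, "reason": "incomplete_questionnaire"})
        elif s.task_completion < min_completion:
            log_rows.append(
                {
                    "participant_id": s.participant_id,
                    "reason": f"task_completion<{min_completion:g}",
                }
            )
        elif long_string_flag(s, long_string_threshold, span_boundary):
            log_rows.append({"participant_id": s.participant_id, "reason": "long_string"})
        else:
            kept.append(s.participant_id)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return kept, log


def assemble_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a long trial table (one row per participant × stimulus).

    Rejects ratings outside the 0-8 integer scale, unknown categories, and
    duplicate (participant, stimulus) pairs, naming the offending rows.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table lacks columns: {missing}")
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    for col in ("positivity", "negativity", "arousal"):
        vals = out[col].to_numpy(dtype=float)
        bad = (
            ~np.isfinite(vals)
            | (vals < RATING_MIN)
            | (vals > RATING_MAX)
            | (vals != np.round(vals))
        )
        if bad.any():
            idx = out.index[bad][:5].tolist()
            raise ValidationError(
                f"{col}: {int(bad.sum())} rating(s) outside integer [0, 8], e.g. rows {idx}"
            )
        out[col] = vals.astype(int)
    bad_cat = ~out["category"].isin(CATEGORIES)
    if bad_cat.any():
        raise ValidationError(
            f"unknown stimulus category in rows {out.index[bad_cat][:5].tolist()}"
        )
    dup = out.duplicated(subset=["participant_id", "stimulus_id"], keep=False)
    if dup.any():
        pairs = out.loc[dup, ["participant_id", "stimulus_id"]].head(5).to_records(index=False)
        raise ValidationError(f"duplicate participant × stimulus pairs, e.g. {list(pairs)}")
    out["category"] = pd.Categorical(out["category"], categories=list(CATEGORIES))
    out["social"] = out["social"].astype(bool)
    return out.reset_index(drop=True)


def read_trials_csv(path) -> pd.DataFrame:
    return assemble_trial_table(pd.read_csv(path))


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def write_exclusion_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)
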