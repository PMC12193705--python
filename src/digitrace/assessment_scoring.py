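"""Scoring of the reading assessments.

Covers the letter/syllable list with its five-consecutive-error
discontinuation rule and 85-item maximum, the timed meaningless and
meaningful text readings (accuracy = percent of items correctly read,
fluency = items correctly read per minute), pre/post change scores, and
the good/poor median split on decoding scores.

The real test instruments are copyrighted; only their scoring structure
(item counts, time limits, discontinuation) is modelled here, and all
fixtures are synthetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MAX_LIST_ITEMS, STOP_RUN

TEST_LABELS = ("letters_syllables", "meaningless_text", "meaningful_text",
               "pseudowords")

#: structural parameters of the study's instruments (synthetic stand-ins)
TEST_STRUCTURE = {
    "letters_syllables": {"max_items": 85, "time_limit_s": None},
    "meaningless_text": {"max_items": 265, "time_limit_s": 180},
    "meaningful_text": {"max_items": 200, "time_limit_s": 60},
    "pseudowords": {"max_items": 45, "time_limit_s": 180},
}


@dataclass(frozen=True)
class ItemResponse:
    item: int            # 1-based item index
    correct: bool
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        if self.item < 1:
            raise ValueError("item index must be >= 1")


@dataclass
class AssessmentResult:
    test: str
    items_administered: int
    items_correct: int
    accuracy: float               # percent
    fluency: float | None         # items correct per minute; None if untimed
    time_limit_s: float | None
    discontinued: bool = False

    @property
    def score(self) -> int:
        return self.items_correct


@dataclass(frozen=True)
class ChangeScore:
    subject_id: str
    test: str
    pre: float
    post: float

    @property
    def gain(self) -> float:
        return self.post - self.pre


def score_discontinuing_list(responses: Sequence[ItemResponse],
                             max_items: int = MAX_LIST_ITEMS,
                             stop_run: int = STOP_RUN) -> AssessmentResult:
    """Score an item list that is discontinued after ``stop_run``
    consecutive errors (default 5), with at most ``max_items`` items.

    Responses recorded beyond the stop point are trimmed with a warning and
    never change the score.
    """
    responses = sorted(responses, key=lambda r: r.item)
    run = 0
    administered = 0
    correct = 0
    discontinued = False
    for r in responses:
        if administered >= max_items:
            break
        administered += 1
        if r.correct:
            correct += 1
            run = 0
        else:
            run += 1
            if run >= stop_run:
                discontinued = True
                break
    if discontinued and administered < len(responses):
        warnings.warn(
            f"{len(responses) - administered} responses beyond the "
            "discontinuation point were ignored")
    accuracy = 100.0 * correct / administered if administered else 0.0
    return AssessmentResult(test="letters_syllables",
                            items_administered=administered,
                            items_correct=correct, accuracy=accuracy,
                            fluency=None, time_limit_s=None,
                            discontinued=discontinued)


def timed_reading_result(responses: Sequence[ItemResponse],
                         time_limit_s: float,
                         test: str = "meaningless_text") -> AssessmentResult:
    """Accuracy and fluency for a timed reading: fluency = items correct
    per minute, accuracy = percent correct of items attempted."""
    if time_limit_s <= 0:
        raise ValueError("time_limit_s must be positive")
    administered = len(responses)
    if administered == 0:
        raise ValueError("no items administered")
    correct = sum(1 for r in responses if r.correct)
    return AssessmentResult(
        test=test, items_administered=administered, items_correct=correct,
        accuracy=100.0 * correct / administered,
        fluency=correct / (time_limit_s / 60.0), time_limit_s=time_limit_s)


def change_score(subject_id: str, pre: AssessmentResult,
                 post: AssessmentResult, measure: str = "score") -> ChangeScore:
    """Gain between pre- and post-test on the test's native scale
    (``measure``: 'score', 'accuracy' or 'fluency')."""
    if pre.test != post.test:
        raise ValueError(f"test labels differ: {pre.test!r} vs {post.test!r}")
    pre_v = getattr(pre, measure)
    post_v = getattr(post, measure)
    if pre_v is None or post_v is None:
        raise ValueError(f"measure {measure!r} undefined for {pre.test}")
    return ChangeScore(subject_id=subject_id, test=pre.test,
                       pre=float(pre_v), post=float(post_v))


def median_split(scores: Mapping[str, float],
                 tie_rule: str = "poor") -> dict[str, str]:
    """Label each subject 'good' (strictly above the median) or 'poor'
    (strictly below); scores at the median follow ``tie_rule``."""
    if len(scores) < 2:
        raise ValueError("median split needs >= 2 subjects")
    if tie_rule not in ("good", "poor"):
        raise ValueError("tie_rule must be 'good' or 'poor'")
    values = np.asarray(list(scores.values()), dtype=float)
    if np.unique(values).size == 1:
        raise ValueError("all scores identical: median split undefined")
    med = float(np.median(values))
    out = {}
    for subject, v in scores.items():
        if v > med:
            out[subject] = "good"
        elif v < med:
            out[subject] = "poor"
        else:
            out[subject] = tie_rule
    return out


def results_to_frame(results: Mapping[str, Sequence[AssessmentResult]]) -> pd.DataFrame:
    """subject -> results, flattened to the results CSV schema."""
    rows = []
    for subject, rs in results.items():
        for r in rs:
            rows.append({"subject_id": subject, "test": r.test,
                         "administered": r.items_administered,
                         "correct": r.items_correct,
                         "accuracy_pct": r.accuracy,
                         "fluency_per_min": r.fluency})
    return pd.DataFrame(rows)
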