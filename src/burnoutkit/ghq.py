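"""Bimodal GHQ-12 scoring and distress classification.

Under bimodal scoring each 4-option item collapses to a binary symptom
indicator: the first two (more positive) options score 0, the last two
(more negative) options score 1, so the total ranges over 0-12.  The
conventional interpretation places possible distress at a total >= 4 and
stress-related disorders at >= 8; the screening engine additionally flags
*distress* at a configurable threshold whose default of 3 deliberately
errs on the side of not missing symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .instruments import (
    Instrument,
    Item,
    ResponseRecord,
    ValidationError,
    Violation,
    load_builtin_instruments,
    validate_response,
)

__all__ = ["StandardBand", "GhqResult", "code_ghq_answer", "score_ghq", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 3

#: Conventional GHQ-12 cut-offs, reported alongside the configurable flag.
POSSIBLE_DISTRESS_CUTOFF = 4
STRESS_DISORDERS_CUTOFF = 8


class StandardBand(str, Enum):
    NONE = "none"
    POSSIBLE_DISTRESS = "possible_distress"
    STRESS_DISORDERS = "stress_disorders"


@dataclass(frozen=True)
class GhqResult:
    score: int  # bimodal total, 0-12
    threshold: int
    distress: bool
    standard_band: StandardBand

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 12:
            raise ValueError(f"GHQ score {self.score} outside 0-12")
        if self.distress != (self.score >= self.threshold):
            raise ValueError("distress flag inconsistent with threshold")


def code_ghq_answer(item: Item, code: int) -> int:
    """Bimodal coding of one answer: first two options 0, last two 1."""
    if item.instrument != "GHQ12":
        raise ValidationError([Violation("malformed", item.id, f"{item.id} is not a GHQ-12 item")])
    if code not in item.option_codes():
        raise ValidationError(
            [Violation("malformed", item.id, f"{item.id}: option code {code!r} invalid")]
        )
    return 0 if code <= 1 else 1


def _standard_band(score: int) -> StandardBand:
    if score >= STRESS_DISORDERS_CUTOFF:
        return StandardBand.STRESS_DISORDERS
    if score >= POSSIBLE_DISTRESS_CUTOFF:
        return StandardBand.POSSIBLE_DISTRESS
    return StandardBand.NONE


def score_ghq(
    response: ResponseRecord,
    threshold: int = DEFAULT_THRESHOLD,
    *,
    instrument: Instrument | None = None,
) -> GhqResult:
    """Score a complete GHQ-12 response.

    Parameters
    ----------
    response
        A validated, complete GHQ-12 response (it is re-validated here).
    threshold
        Distress cut-off in points, 0-12.  The default of 3 matches a
        deliberately sensitive screening posture; the conventional 4/8
        interpretation is always reported via ``standard_band``.
    instrument
        The GHQ-12 bank; defaults to the built-in one.
    """
    if not 0 <= threshold <= 12:
        raise ValueError(f"threshold {threshold} outside 0-12")
    if instrument is None:
        instrument = load_builtin_instruments()["GHQ12"]
    validate_response(instrument, response)
    score = sum(code_ghq_answer(instrument.item(i), c) for i, c in response.answers.items())
    return GhqResult(
        score=score,
        threshold=threshold,
        distress=score >= threshold,
        standard_band=_standard_band(score),
    )
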