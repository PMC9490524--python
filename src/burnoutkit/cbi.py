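"""Copenhagen Burnout Inventory scoring.

Each CBI answer maps to points on a 0-100 scale (option codes 0..4 ->
100, 75, 50, 25, 0; the single reverse-scored item maps the other way),
a dimension's score is the arithmetic mean of its items, dimensions are
levelled low (<50) / moderate (50-<75) / high (>=75), and the three
levels combine into an overall burnout risk:

* high       — at least two high dimensions;
* moderate   — exactly one high dimension, or at least two moderates;
* low        — otherwise (all low, or a single moderate).

The moderate rule is deliberately conservative: one high subscale never
yields an all-clear.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .instruments import (
    Dimension,
    Instrument,
    Item,
    ResponseRecord,
    ValidationError,
    Violation,
    load_builtin_instruments,
    validate_response,
)

__all__ = [
    "Level",
    "DimensionScore",
    "CbiResult",
    "code_cbi_answer",
    "score_dimension",
    "classify_level",
    "combine_risk",
    "score_cbi",
]

#: Points for option codes 0..4 of a forward-scored item.
FORWARD_POINTS = (100, 75, 50, 25, 0)


class Level(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return ("low", "moderate", "high").index(self.value)


@dataclass(frozen=True)
class DimensionScore:
    dimension: Dimension
    score: float  # mean points, 0-100
    level: Level


@dataclass(frozen=True)
class CbiResult:
    personal: DimensionScore
    work: DimensionScore
    client: DimensionScore
    overall_risk: Level

    @property
    def dimension_scores(self) -> tuple[DimensionScore, DimensionScore, DimensionScore]:
        return (self.personal, self.work, self.client)


def code_cbi_answer(item: Item, code: int) -> int:
    """Points (0-100) for one CBI answer; the reverse item inverts the scale."""
    if item.instrument != "CBI":
        raise ValidationError([Violation("malformed", item.id, f"{item.id} is not a CBI item")])
    if code not in item.option_codes():
        raise ValidationError(
            [Violation("malformed", item.id, f"{item.id}: option code {code!r} invalid")]
        )
    points = FORWARD_POINTS[code]
    return 100 - points if item.reverse else points


def classify_level(score: float) -> Level:
    """Level for a dimension score: low <50, moderate 50-<75, high >=75."""
    if not 0 <= score <= 100:
        raise ValueError(f"dimension score {score} outside 0-100")
    if score >= 75:
        return Level.HIGH
    if score >= 50:
        return Level.MODERATE
    return Level.LOW


def combine_risk(levels: tuple[Level, Level, Level]) -> Level:
    """Overall burnout risk from the three dimension levels."""
    if len(levels) != 3:
        raise ValueError("exactly three dimension levels expected")
    levels = tuple(Level(lv) for lv in levels)
    n_high = sum(lv is Level.HIGH for lv in levels)
    n_mod = sum(lv is Level.MODERATE for lv in levels)
    if n_high >= 2:
        return Level.HIGH
    if n_high == 1 or n_mod >= 2:
        return Level.MODERATE
    return Level.LOW


def score_dimension(
    response: ResponseRecord,
    dimension: Dimension | str,
    *,
    instrument: Instrument | None = None,
) -> DimensionScore:
    """Mean points (0-100) and level for one CBI subscale."""
    if instrument is None:
        instrument = load_builtin_instruments()["CBI"]
    validate_response(instrument, response)
    dimension = Dimension(dimension)
    items = instrument.dimension_items(dimension)
    points = [code_cbi_answer(item, response.answers[item.id]) for item in items]
    score = sum(points) / len(points)
    return DimensionScore(dimension=dimension, score=score, level=classify_level(score))


def score_cbi(response: ResponseRecord, *, instrument: Instrument | None = None) -> CbiResult:
    """Score all three CBI subscales and combine them into an overall risk."""
    if instrument is None:
        instrument = load_builtin_instruments()["CBI"]
    validate_response(instrument, response)
    per, wrk, cli = (
        score_dimension(response, d, instrument=instrument)
        for d in (Dimension.PERSONAL, Dimension.WORK, Dimension.CLIENT)
    )
    return CbiResult(
        personal=per,
        work=wrk,
        client=cli,
        overall_risk=combine_risk((per.level, wrk.level, cli.level)),
    )
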