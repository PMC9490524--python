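"""Longitudinal tracking of repeated GHQ+CBI sittings.

Covers the app-style monitoring features: the recent-diagnosis chart
series (last four sittings by default), per-dimension deltas between the
two most recent sittings (lower burnout scores are better), the
alert / congratulations status message, and the three-month retest
schedule with calendar-month arithmetic.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from typing import Iterable

from .cbi import Level
from .diagnosis import Category, TestRecord
from .instruments import Dimension

__all__ = [
    "History",
    "Trend",
    "DimensionDelta",
    "DeltaReport",
    "ChartPoint",
    "StatusMessage",
    "InsufficientHistoryError",
    "append_record",
    "recent_diagnoses",
    "dimension_deltas",
    "status_message",
    "next_due",
    "add_months",
]

DEFAULT_RETEST_INTERVAL_MONTHS = 3


class Trend(str, Enum):
    IMPROVED = "improved"
    UNCHANGED = "unchanged"
    WORSENED = "worsened"


class StatusMessage(str, Enum):
    ALERT = "alert"
    CONGRATULATIONS = "congratulations"
    NONE = "none"


class InsufficientHistoryError(ValueError):
    pass


@dataclass(frozen=True)
class History:
    respondent_id: str
    records: tuple[TestRecord, ...] = ()

    def __post_init__(self) -> None:
        stamps = [r.timestamp for r in self.records]
        if stamps != sorted(stamps):
            raise ValueError("history records must be sorted by timestamp")
        if any(r.respondent_id != self.respondent_id for r in self.records):
            raise ValueError("all history records must share the respondent id")


@dataclass(frozen=True)
class DimensionDelta:
    dimension: Dimension
    previous: float
    current: float
    trend: Trend


@dataclass(frozen=True)
class DeltaReport:
    deltas: tuple[DimensionDelta, ...]

    def __getitem__(self, dimension: Dimension | str) -> DimensionDelta:
        dimension = Dimension(dimension)
        for d in self.deltas:
            if d.dimension is dimension:
                return d
        raise KeyError(dimension)


@dataclass(frozen=True)
class ChartPoint:
    timestamp: datetime
    overall_risk: Level
    category: Category


def append_record(history: History, record: TestRecord) -> History:
    """Insert a record preserving chronological order; duplicates rejected."""
    if record.respondent_id != history.respondent_id:
        raise ValueError(
            f"record for {record.respondent_id!r} cannot join history of {history.respondent_id!r}"
        )
    if any(r.timestamp == record.timestamp for r in history.records):
        raise ValueError(f"duplicate timestamp {record.timestamp.isoformat()}")
    records = sorted((*history.records, record), key=lambda r: r.timestamp)
    return replace(history, records=tuple(records))


def recent_diagnoses(history: History, n: int = 4) -> list[ChartPoint]:
    """Chart series for the last ``n`` sittings, oldest first."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        ChartPoint(r.timestamp, r.cbi.overall_risk, r.diagnosis.category)
        for r in history.records[-n:]
    ]


def dimension_deltas(history: History) -> DeltaReport:
    """Per-dimension comparison of the last two sittings.

    ``improved`` means the burnout score went *down* — all CBI subscales
    are symptom-positive.
    """
    if len(history.records) < 2:
        raise InsufficientHistoryError(
            f"need at least 2 records, have {len(history.records)}"
        )
    prev, cur = history.records[-2], history.records[-1]
    deltas = []
    for p, c in zip(prev.cbi.dimension_scores, cur.cbi.dimension_scores):
        if c.score < p.score:
            trend = Trend.IMPROVED
        elif c.score == p.score:
            trend = Trend.UNCHANGED
        else:
            trend = Trend.WORSENED
        deltas.append(DimensionDelta(p.dimension, p.score, c.score, trend))
    return DeltaReport(tuple(deltas))


def status_message(record: TestRecord) -> StatusMessage:
    """Alert on GHQ distress; congratulations on an all-zero CBI.

    The alert strictly dominates: distress marks a critical state even if
    every burnout subscale reads zero.
    """
    if record.ghq.distress:
        return StatusMessage.ALERT
    if all(d.score == 0 for d in record.cbi.dimension_scores):
        return StatusMessage.CONGRATULATIONS
    return StatusMessage.NONE


def add_months(day: date, months: int) -> date:
    """Calendar-month addition with end-of-month clamping."""
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    return date(year, month, min(day.day, calendar.monthrange(year, month)[1]))


def next_due(record: TestRecord, interval_months: int = DEFAULT_RETEST_INTERVAL_MONTHS) -> date:
    """Date the respondent should retake the tests (default: 3 months on)."""
    return add_months(record.timestamp.date(), interval_months)
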