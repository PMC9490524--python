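"""System Usability Scale (SUS) scoring and interpretation.

The SUS is a 10-item questionnaire answered on a 1-5 agreement scale,
alternating positively worded (odd) and negatively worded (even) items.
A respondent's score is

    SUS = 2.5 * [ sum_odd (x_i - 1) + sum_even (5 - x_i) ]

which ranges over 0-100 with each item contributing up to 10 points.
Cohort results reported only as per-item answer counts can be scored
exactly via linearity of the mean: the mean SUS over respondents equals
the sum over items of the mean per-item contribution, for *any*
disaggregation consistent with the counts.

Interpretation bands: >80.3 excellent, (68, 80.3] good, exactly 68 okay,
[51, 68) poor, <51 awful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "SusResponse",
    "SusCountTable",
    "SusBand",
    "SusReport",
    "score_sus",
    "mean_sus_from_counts",
    "interpret_sus",
    "sus_report",
    "aggregate_responses",
    "load_builtin_survey_counts",
]

N_ITEMS = 10
_ODD = tuple(range(0, N_ITEMS, 2))  # 0-based positions of items 1,3,5,7,9
_EVEN = tuple(range(1, N_ITEMS, 2))


class SusBand(str, Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    OKAY = "okay"
    POOR = "poor"
    AWFUL = "awful"


@dataclass(frozen=True)
class SusResponse:
    """One respondent's ten answers, positionally items 1..10, each 1-5."""

    answers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.answers) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} answers, got {len(self.answers)}")
        bad = [a for a in self.answers if not (isinstance(a, int) and 1 <= a <= 5)]
        if bad:
            raise ValueError(f"answers must be integers 1-5, got {bad}")


@dataclass(frozen=True)
class SusCountTable:
    """Aggregated survey: per item 1..10, counts of answers 1..5."""

    counts: tuple[tuple[int, ...], ...]  # counts[item][answer-1]
    n: int

    def __post_init__(self) -> None:
        if len(self.counts) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} count rows, got {len(self.counts)}")
        for i, row in enumerate(self.counts, start=1):
            if len(row) != 5 or any(c < 0 for c in row):
                raise ValueError(f"item {i}: need 5 nonnegative counts, got {row}")
            if sum(row) != self.n:
                raise ValueError(f"item {i}: counts sum to {sum(row)}, expected n={self.n}")


@dataclass(frozen=True)
class SusReport:
    score: float  # 0-100
    band: SusBand


def score_sus(response: SusResponse) -> float:
    """Score one respondent: odd items (x-1)*2.5, even items (5-x)*2.5."""
    a = response.answers
    return 2.5 * (sum(a[i] - 1 for i in _ODD) + sum(5 - a[i] for i in _EVEN))


def mean_sus_from_counts(table: SusCountTable) -> float:
    """Exact mean SUS of a cohort given only per-item answer counts.

    Uses linearity of the mean, so it equals ``mean(score_sus(r))`` over
    any set of individual respondents consistent with the table.
    """
    if table.n == 0:
        raise ValueError("empty survey: n=0")
    total = 0.0
    for i, row in enumerate(table.counts):
        mean_answer = sum(count * (ans + 1) for ans, count in enumerate(row)) / table.n
        contribution = (mean_answer - 1) if i in _ODD else (5 - mean_answer)
        total += 2.5 * contribution
    return total


def interpret_sus(score: float) -> SusBand:
    """Interpretation band for a SUS score on the 0-100 scale."""
    if not 0 <= score <= 100:
        raise ValueError(f"SUS score {score} outside 0-100")
    if score > 80.3:
        return SusBand.EXCELLENT
    if score > 68:
        return SusBand.GOOD
    if score == 68:
        return SusBand.OKAY
    if score >= 51:
        return SusBand.POOR
    return SusBand.AWFUL


def sus_report(score: float) -> SusReport:
    return SusReport(score=score, band=interpret_sus(score))


def aggregate_responses(responses: Iterable[SusResponse]) -> SusCountTable:
    """Collapse individual responses into a per-item count table."""
    rows = [[0] * 5 for _ in range(N_ITEMS)]
    n = 0
    for resp in responses:
        n += 1
        for i, a in enumerate(resp.answers):
            rows[i][a - 1] += 1
    return SusCountTable(counts=tuple(tuple(r) for r in rows), n=n)


def counts_from_rows(rows: Sequence[Sequence[int]]) -> SusCountTable:
    """Build a count table from 10 rows of 5 counts, inferring n."""
    if not rows:
        raise ValueError("no count rows")
    n = sum(rows[0])
    return SusCountTable(counts=tuple(tuple(int(c) for c in r) for r in rows), n=n)


def load_builtin_survey_counts() -> SusCountTable:
    """The bundled 40-user field survey of the screening app, as counts.

    Shipped so the package's own usability evaluation can be recomputed
    from the raw answer counts.
    """
    text = resources.files("burnoutkit.data").joinpath("sus_survey_counts.csv").read_text("utf-8")
    reader = csv.DictReader(text.splitlines())
    rows = [[int(rec[f"n{v}"]) for v in range(1, 6)] for rec in reader]
    return counts_from_rows(rows)
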