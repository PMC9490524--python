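"""Four-outcome burnout diagnosis combining the GHQ and CBI results.

The screening outcome is one of four categories:

* **critical** — GHQ distress together with high CBI burnout risk;
* **moderate** — moderate CBI risk, whatever the GHQ says;
* **great** — no GHQ distress and low CBI risk;
* **contradictory** — the two instruments disagree (distress with low
  risk, or no distress with high risk); a retest is recommended.

The result is a screening aid, not a medical diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

from .cbi import CbiResult, Level, score_cbi
from .ghq import GhqResult, score_ghq
from .instruments import Instrument, ResponseRecord, load_builtin_instruments

__all__ = ["Category", "Diagnosis", "TestRecord", "diagnose", "make_record"]

from enum import Enum


class Category(str, Enum):
    CRITICAL = "critical"
    MODERATE = "moderate"
    GREAT = "great"
    CONTRADICTORY = "contradictory"


@dataclass(frozen=True)
class Diagnosis:
    category: Category
    rationale: str


@dataclass(frozen=True)
class TestRecord:
    """A GHQ+CBI sitting: both results plus the combined diagnosis."""

    respondent_id: str
    timestamp: datetime
    ghq: GhqResult
    cbi: CbiResult
    diagnosis: Diagnosis


def diagnose(ghq: GhqResult, cbi: CbiResult) -> Diagnosis:
    """Total mapping of (distress flag, overall risk) to a category."""
    risk = cbi.overall_risk
    if risk is Level.MODERATE:
        return Diagnosis(
            Category.MODERATE,
            "moderate burnout risk on the CBI, independently of the GHQ result",
        )
    if ghq.distress and risk is Level.HIGH:
        return Diagnosis(Category.CRITICAL, "GHQ distress together with high CBI burnout risk")
    if not ghq.distress and risk is Level.LOW:
        return Diagnosis(Category.GREAT, "no GHQ distress and low CBI burnout risk")
    return Diagnosis(
        Category.CONTRADICTORY,
        f"GHQ distress={ghq.distress} disagrees with CBI risk={risk.value}; repeat the tests",
    )


def make_record(
    ghq_response: ResponseRecord,
    cbi_response: ResponseRecord,
    now: datetime | None = None,
    *,
    ghq_threshold: int | None = None,
    instruments: dict[str, Instrument] | None = None,
) -> TestRecord:
    """Score both instruments for one respondent and bundle the diagnosis."""
    if ghq_response.respondent_id != cbi_response.respondent_id:
        raise ValueError(
            f"respondent mismatch: GHQ response is for {ghq_response.respondent_id!r}, "
            f"CBI response for {cbi_response.respondent_id!r}"
        )
    if instruments is None:
        instruments = load_builtin_instruments()
    kwargs = {} if ghq_threshold is None else {"threshold": ghq_threshold}
    ghq = score_ghq(ghq_response, instrument=instruments["GHQ12"], **kwargs)
    cbi = score_cbi(cbi_response, instrument=instruments["CBI"])
    if now is None:
        now = datetime.now(timezone.utc)
    return TestRecord(
        respondent_id=ghq_response.respondent_id,
        timestamp=now,
        ghq=ghq,
        cbi=cbi,
        diagnosis=diagnose(ghq, cbi),
    )
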