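"""Questionnaire data model and the built-in GHQ-12 / CBI item banks.

The two screening instruments at the heart of the package are shipped as a
versioned JSON document (``data/instruments.json``):

* **GHQ-12** — the 12-item General Health Questionnaire, a screen for
  psychological distress.  Each item offers four ordered answer options,
  from the most positive ("Better than usual") to the most negative
  ("Much less than usual"); the exact wording varies per question.
* **CBI** — the 19-item Copenhagen Burnout Inventory, with three
  subscales: personal (6 items), work-related (7 items) and
  client-related (6 items) burnout.  Each item offers five frequency /
  intensity options from highest ("Always" / "To a very high degree") to
  lowest ("Never or almost never" / "To a very low degree").  Exactly one
  item — the work-dimension "enough energy for family and friends"
  question — is positively worded and therefore reverse-scored.

Option *codes* are 0-based positions in the printed option order; all
scoring modules work on codes, so records may carry either CBI label pack.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "AnswerOption",
    "Item",
    "Instrument",
    "ResponseRecord",
    "LifestyleProfile",
    "Violation",
    "ValidationError",
    "load_builtin_instruments",
    "validate_response",
    "presentation_order",
    "CBI_PACK_2_LABELS",
]

#: Alternative CBI label pack ("To a very high degree" ... "To a very low
#: degree"), accepted everywhere as a synonym for the same ordinal codes.
CBI_PACK_2_LABELS = (
    "To a very high degree",
    "To a high degree",
    "Somewhat",
    "To a low degree",
    "To a very low degree",
)


class Dimension(str, Enum):
    """CBI burnout subscale (GHQ items carry ``NONE``)."""

    NONE = "none"
    PERSONAL = "personal"
    WORK = "work"
    CLIENT = "client"


@dataclass(frozen=True)
class AnswerOption:
    label: str
    code: int  # 0-based position in the printed option order


@dataclass(frozen=True)
class Item:
    id: str
    text: str
    instrument: str  # "GHQ12" | "CBI"
    dimension: Dimension
    reverse: bool
    options: tuple[AnswerOption, ...]
    answer_pack: str

    def option_codes(self) -> tuple[int, ...]:
        return tuple(o.code for o in self.options)

    def code_for_label(self, label: str) -> int:
        """Resolve an answer label to its option code.

        CBI items additionally accept the second printed label pack; the
        two packs are synonymous label sets for the same five codes.
        """
        for opt in self.options:
            if opt.label == label:
                return opt.code
        if self.instrument == "CBI":
            try:
                return CBI_PACK_2_LABELS.index(label)
            except ValueError:
                pass
        raise KeyError(f"{self.id}: unknown answer label {label!r}")


@dataclass(frozen=True)
class Instrument:
    id: str
    items: tuple[Item, ...]

    def item(self, item_id: str) -> Item:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"{self.id}: unknown item {item_id!r}") from None

    def item_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.items)

    def dimension_items(self, dimension: Dimension | str) -> tuple[Item, ...]:
        dimension = Dimension(dimension)
        return tuple(i for i in self.items if i.dimension is dimension)

    @property
    def _index(self) -> dict[str, Item]:
        # Built lazily; object.__setattr__ because the dataclass is frozen.
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {i.id: i for i in self.items}
            object.__setattr__(self, "_index_cache", idx)
        return idx


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent's answers to one instrument at one time point."""

    instrument_id: str
    respondent_id: str
    timestamp: datetime
    answers: Mapping[str, int]  # item id -> option code

    def with_answers(self, answers: Mapping[str, int]) -> "ResponseRecord":
        return replace(self, answers=dict(answers))


@dataclass(frozen=True)
class LifestyleProfile:
    """Sign-up lifestyle questionnaire: stored for context, never scored."""

    meal_frequency: int = 0  # meals/day
    fruit_veg_servings: int = 0  # servings/day
    walking_frequency: int = 0  # sessions/week
    activity_minutes: int = 0  # minutes/session
    activity_intensity: str = "none"  # none | moderate | intensive
    substance_use: Mapping[str, Mapping[str, int | bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("meal_frequency", "fruit_veg_servings", "walking_frequency", "activity_minutes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.activity_intensity not in ("none", "moderate", "intensive"):
            raise ValueError(f"unknown activity intensity {self.activity_intensity!r}")
        for substance, usage in self.substance_use.items():
            days = int(usage.get("days_used", 0))
            if not 0 <= days <= 30:
                raise ValueError(f"{substance}: days_used must be within 0-30")


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    kind: str  # "incomplete" | "malformed"
    item_id: str
    message: str


class ValidationError(ValueError):
    """Raised when a response record fails validation.

    Carries every violation found in one pass, each tagged ``incomplete``
    (an item of the instrument was left unanswered) or ``malformed`` (an
    unknown item id, or an option code outside the item's option list).
    """

    def __init__(self, violations: Iterable[Violation]):
        self.violations = tuple(violations)
        self.kinds = frozenset(v.kind for v in self.violations)
        super().__init__("; ".join(v.message for v in self.violations))


def validate_response(instrument: Instrument, raw: ResponseRecord) -> ResponseRecord:
    """Return ``raw`` unchanged iff it is a complete, well-formed response.

    Every violation is collected before raising, so a caller sees all
    missing items, unknown items and out-of-range codes at once.
    """
    if raw.instrument_id != instrument.id:
        raise ValidationError([
            Violation("malformed", "", f"record is for {raw.instrument_id!r}, not {instrument.id!r}")
        ])
    violations: list[Violation] = []
    known = set(instrument.item_ids())
    for item_id, code in raw.answers.items():
        if item_id not in known:
            violations.append(Violation("malformed", item_id, f"unknown item {item_id!r}"))
            continue
        item = instrument.item(item_id)
        if not isinstance(code, int) or isinstance(code, bool) or code not in item.option_codes():
            violations.append(
                Violation(
                    "malformed",
                    item_id,
                    f"{item_id}: option code {code!r} not in {item.option_codes()}",
                )
            )
    for item_id in instrument.item_ids():
        if item_id not in raw.answers:
            violations.append(Violation("incomplete", item_id, f"missing answer for {item_id}"))
    if violations:
        raise ValidationError(violations)
    return raw


# ---------------------------------------------------------------------------
# Built-in banks


def _parse_item(payload: dict) -> Item:
    return Item(
        id=payload["id"],
        text=payload["text"],
        instrument=payload["instrument"],
        dimension=Dimension(payload["dimension"]),
        reverse=bool(payload["reverse"]),
        options=tuple(AnswerOption(o["label"], int(o["code"])) for o in payload["options"]),
        answer_pack=payload["answer_pack"],
    )


def parse_instrument_bank(payload: dict) -> dict[str, Instrument]:
    """Parse a bank document (the ``instruments.json`` schema) and check it."""
    banks = {
        inst["id"]: Instrument(id=inst["id"], items=tuple(_parse_item(i) for i in inst["items"]))
        for inst in payload["instruments"]
    }
    _check_bank_invariants(banks)
    return banks


def _check_bank_invariants(banks: dict[str, Instrument]) -> None:
    ghq = banks["GHQ12"]
    cbi = banks["CBI"]
    assert len(ghq.items) == 12
    assert all(i.dimension is Dimension.NONE and len(i.options) == 4 for i in ghq.items)
    assert len(cbi.items) == 19
    counts = {d: len(cbi.dimension_items(d)) for d in (Dimension.PERSONAL, Dimension.WORK, Dimension.CLIENT)}
    assert counts == {Dimension.PERSONAL: 6, Dimension.WORK: 7, Dimension.CLIENT: 6}
    reverse = [i for i in cbi.items if i.reverse]
    assert len(reverse) == 1 and reverse[0].dimension is Dimension.WORK
    for inst in banks.values():
        ids = inst.item_ids()
        assert len(set(ids)) == len(ids)
        for item in inst.items:
            assert item.option_codes() == tuple(range(len(item.options)))
            assert all(o.label for o in item.options)


def load_builtin_instruments() -> dict[str, Instrument]:
    """Load the shipped GHQ-12 and CBI banks, keyed by instrument id."""
    text = resources.files("burnoutkit.data").joinpath("instruments.json").read_text("utf-8")
    return parse_instrument_bank(json.loads(text))


def instrument_bank_document() -> dict:
    """The raw, versioned JSON document the built-in banks are parsed from."""
    text = resources.files("burnoutkit.data").joinpath("instruments.json").read_text("utf-8")
    return json.loads(text)


# ---------------------------------------------------------------------------
# Presentation order

_MAX_RUN = 3  # longest tolerated run of same-dimension CBI items


def presentation_order(instrument: Instrument, seed: int) -> list[str]:
    """Seeded shuffle of the instrument's item ids for on-screen display.

    Presenting CBI subscales in printed blocks invites stereotypical
    response patterns, so for the CBI the permutation additionally avoids
    runs of more than three same-dimension items (always feasible for the
    6/7/6 subscale sizes).  Deterministic for a given seed.
    """
    ids = list(instrument.item_ids())
    dim_of = {i.id: i.dimension for i in instrument.items}
    rng = random.Random(seed)
    for _ in range(1000):
        rng.shuffle(ids)
        if instrument.id != "CBI" or _max_dimension_run(ids, dim_of) <= _MAX_RUN:
            return list(ids)
    raise RuntimeError("could not find an interleaved order")  # pragma: no cover


def _max_dimension_run(ids: list[str], dim_of: Mapping[str, Dimension]) -> int:
    longest = run = 0
    prev = None
    for item_id in ids:
        d = dim_of[item_id]
        run = run + 1 if d == prev else 1
        prev = d
        longest = max(longest, run)
    return longest
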