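"""Seeded synthetic-respondent generator.

Every pipeline stage — scoring, diagnosis, monitoring, usability — can be
exercised without real data by drawing respondents from a
:class:`RespondentProfile` with controllable severity:

* ``ghq_negativity`` — per-item probability of answering in the
  symptom-positive (1-coded) half of a GHQ item; the bimodal total is
  then Binomial(12, negativity).
* ``cbi_target`` — intended mean (0-100 points) per CBI dimension.  At
  ``cbi_noise=0`` the generator deterministically realizes the attainable
  dimension mean nearest the target, nudged one option step if plain
  rounding would cross a low/moderate/high boundary, so the classified
  level always recovers ``classify_level(target)`` (targets off the
  boundaries themselves).
* ``cbi_noise`` — probability (0-1) that an item's chosen option is
  displaced one step, symmetrically up or down, clamped at the scale ends.
* ``sus_positivity`` — probability a usability item gets its optimal
  answer; otherwise the answer is uniform over 1-5.

All draws flow from a single integer seed, so emitted records are
bit-reproducible fixtures; every record passes ``validate_response``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timezone
from typing import Mapping, Sequence

import numpy as np

from .cbi import classify_level
from .diagnosis import make_record
from .instruments import Dimension, Instrument, ResponseRecord, load_builtin_instruments
from .monitoring import DEFAULT_RETEST_INTERVAL_MONTHS, History, add_months, append_record
from .sus import N_ITEMS as SUS_N_ITEMS
from .sus import SusResponse

__all__ = [
    "RespondentProfile",
    "simulate_ghq",
    "simulate_cbi",
    "simulate_sus",
    "simulate_history",
]

_DEFAULT_STAMP = datetime(2022, 1, 1, 12, 0, tzinfo=timezone.utc)
_SEED_BOUND = 2**31 - 1


@dataclass(frozen=True)
class RespondentProfile:
    ghq_negativity: float = 0.0
    cbi_target: Mapping[str, float] = field(
        default_factory=lambda: {"personal": 0.0, "work": 0.0, "client": 0.0}
    )
    cbi_noise: float = 0.0
    sus_positivity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ghq_negativity", "cbi_noise", "sus_positivity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for dim, target in self.cbi_target.items():
            Dimension(dim)
            if not 0 <= target <= 100:
                raise ValueError(f"cbi_target[{dim}] must lie in [0, 100]")


def simulate_ghq(
    profile: RespondentProfile,
    seed: int,
    *,
    respondent_id: str | None = None,
    timestamp: datetime = _DEFAULT_STAMP,
    instrument: Instrument | None = None,
) -> ResponseRecord:
    """Draw one GHQ-12 response: each item lands in the 1-coded option
    pair with probability ``ghq_negativity``, uniformly within the pair."""
    if instrument is None:
        instrument = load_builtin_instruments()["GHQ12"]
    rng = np.random.default_rng(seed)
    answers = {}
    for item in instrument.items:
        negative = rng.random() < profile.ghq_negativity
        answers[item.id] = int(rng.integers(2, 4)) if negative else int(rng.integers(0, 2))
    return ResponseRecord(
        instrument_id="GHQ12",
        respondent_id=respondent_id or f"sim-{seed}",
        timestamp=timestamp,
        answers=answers,
    )


def _target_units(target: float, n_items: int) -> int:
    """Total option units (25-point steps) realizing the attainable mean
    nearest ``target`` without crossing its level boundary."""
    q = int(round(target * n_items / 25))
    q = max(0, min(4 * n_items, q))
    want = classify_level(target)
    got = classify_level(25 * q / n_items)
    if got.rank > want.rank:
        q -= 1
    elif got.rank < want.rank:
        q += 1
    return q


def simulate_cbi(
    profile: RespondentProfile,
    seed: int,
    *,
    respondent_id: str | None = None,
    timestamp: datetime = _DEFAULT_STAMP,
    instrument: Instrument | None = None,
) -> ResponseRecord:
    """Draw one CBI response around the per-dimension targets.

    Items are assigned in *coded* point units (the reverse item is handled
    in coded space, so its raw option runs opposite to its points), then
    jittered one option step with probability ``cbi_noise``.
    """
    if instrument is None:
        instrument = load_builtin_instruments()["CBI"]
    rng = np.random.default_rng(seed)
    answers: dict[str, int] = {}
    for dim in (Dimension.PERSONAL, Dimension.WORK, Dimension.CLIENT):
        items = instrument.dimension_items(dim)
        n = len(items)
        q = _target_units(float(profile.cbi_target.get(dim.value, 0.0)), n)
        base, rem = divmod(q, n)
        units = np.full(n, base)
        units[rng.permutation(n)[:rem]] += 1
        for item, u in zip(items, units):
            u = int(u)
            r = rng.random()
            if r < profile.cbi_noise / 2:
                u += 1
            elif r < profile.cbi_noise:
                u -= 1
            u = max(0, min(4, u))
            # coded points = 25*u; forward options are printed most-intense
            # first, so forward code = 4-u while the reverse item's code = u.
            answers[item.id] = u if item.reverse else 4 - u
    return ResponseRecord(
        instrument_id="CBI",
        respondent_id=respondent_id or f"sim-{seed}",
        timestamp=timestamp,
        answers=answers,
    )


def simulate_sus(profile: RespondentProfile, seed: int) -> SusResponse:
    """Draw one usability response; optimal answers with probability
    ``sus_positivity`` (5 on odd items, 1 on even), else uniform 1-5."""
    rng = np.random.default_rng(seed)
    answers = []
    for i in range(SUS_N_ITEMS):
        optimal = 5 if i % 2 == 0 else 1
        if rng.random() < profile.sus_positivity:
            answers.append(optimal)
        else:
            answers.append(int(rng.integers(1, 6)))
    return SusResponse(answers=tuple(answers))


def simulate_history(
    profiles: Sequence[RespondentProfile],
    start: date,
    interval_months: int = DEFAULT_RETEST_INTERVAL_MONTHS,
    seed: int = 0,
    *,
    respondent_id: str = "sim",
) -> History:
    """One full GHQ+CBI sitting per profile at successive retest due dates."""
    if not profiles:
        raise ValueError("need at least one profile")
    instruments = load_builtin_instruments()
    rng = np.random.default_rng(seed)
    history = History(respondent_id=respondent_id)
    for i, profile in enumerate(profiles):
        stamp = datetime.combine(
            add_months(start, i * interval_months), time(12, 0), tzinfo=timezone.utc
        )
        ghq_seed = int(rng.integers(0, _SEED_BOUND))
        cbi_seed = int(rng.integers(0, _SEED_BOUND))
        ghq_resp = simulate_ghq(
            profile, ghq_seed, respondent_id=respondent_id, timestamp=stamp,
            instrument=instruments["GHQ12"],
        )
        cbi_resp = simulate_cbi(
            profile, cbi_seed, respondent_id=respondent_id, timestamp=stamp,
            instrument=instruments["CBI"],
        )
        record = make_record(ghq_resp, cbi_resp, now=stamp, instruments=instruments)
        history = append_record(history, record)
    return history
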