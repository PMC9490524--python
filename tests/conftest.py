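from datetime import datetime, timezone

import pytest

from burnoutkit import load_builtin_instruments
from burnoutkit.cbi import CbiResult, DimensionScore, Level, classify_level, combine_risk
from burnoutkit.diagnosis import TestRecord, diagnose
from burnoutkit.ghq import GhqResult, StandardBand
from burnoutkit.instruments import Dimension, ResponseRecord

STAMP = datetime(2022, 1, 15, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def banks():
    return load_builtin_instruments()


@pytest.fixture(scope="session")
def ghq_bank(banks):
    return banks["GHQ12"]


@pytest.fixture(scope="session")
def cbi_bank(banks):
    return banks["CBI"]


def ghq_response(codes, respondent="r1", timestamp=STAMP, bank=None):
    """Build a GHQ response from a constant code or an item->code map."""
    if bank is None:
        bank = load_builtin_instruments()["GHQ12"]
    if isinstance(codes, int):
        codes = {i: codes for i in bank.item_ids()}
    return ResponseRecord("GHQ12", respondent, timestamp, dict(codes))


def cbi_response(codes, respondent="r1", timestamp=STAMP, bank=None):
    if bank is None:
        bank = load_builtin_instruments()["CBI"]
    if isinstance(codes, int):
        codes = {i: codes for i in bank.item_ids()}
    return ResponseRecord("CBI", respondent, timestamp, dict(codes))


def ghq_result(score, threshold=3):
    band = (
        StandardBand.STRESS_DISORDERS
        if score >= 8
        else StandardBand.POSSIBLE_DISTRESS if score >= 4 else StandardBand.NONE
    )
    return GhqResult(score=score, threshold=threshold, distress=score >= threshold, standard_band=band)


def cbi_result(personal, work, client):
    dims = {}
    for name, score in (("personal", personal), ("work", work), ("client", client)):
        dims[name] = DimensionScore(Dimension(name), float(score), classify_level(score))
    levels = tuple(d.level for d in dims.values())
    return CbiResult(**dims, overall_risk=combine_risk(levels))


def make_test_record(personal=0, work=0, client=0, ghq_score=0, timestamp=STAMP, respondent="r1"):
    ghq = ghq_result(ghq_score)
    cbi = cbi_result(personal, work, client)
    return TestRecord(
        respondent_id=respondent,
        timestamp=timestamp,
        ghq=ghq,
        cbi=cbi,
        diagnosis=diagnose(ghq, cbi),
    )
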