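"""File formats and configuration.

Interchange dialects, specified exactly because questionnaire data has no
bioinformatics-style standard container:

* **Responses** — JSON (a list of objects ``{instrument, respondent_id,
  timestamp, answers}``, answers mapping item id to option code or answer
  label) or long-format CSV with columns ``respondent_id, timestamp,
  instrument, item_id, answer`` where ``answer`` is a label or a code.
* **Test records / histories** — versioned JSON documents; JSON
  round-trips exactly.
* **Results CSV** — one row per scored record, floats at 2 decimals.
* **Config** — TOML, mirroring :class:`RunConfig`.
"""

from __future__ import annotations

import csv
import json
import logging
import tomllib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from .cbi import CbiResult, DimensionScore, Level
from .diagnosis import Category, Diagnosis, TestRecord
from .ghq import DEFAULT_THRESHOLD, GhqResult, StandardBand
from .instruments import (
    Dimension,
    Instrument,
    ResponseRecord,
    ValidationError,
    Violation,
    load_builtin_instruments,
    validate_response,
)
from .monitoring import DEFAULT_RETEST_INTERVAL_MONTHS, History
from .sus import SusResponse, counts_from_rows

__all__ = [
    "RunConfig",
    "load_config",
    "read_responses",
    "write_responses",
    "write_results",
    "read_test_records",
    "load_history",
    "save_history",
    "read_sus_responses",
    "read_sus_counts",
]

logger = logging.getLogger("burnoutkit")

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RunConfig:
    """Runtime knobs; the defaults reproduce the screening app's behavior."""

    ghq_threshold: int = DEFAULT_THRESHOLD
    retest_interval_months: int = DEFAULT_RETEST_INTERVAL_MONTHS
    output_format: str = "json"  # json | csv
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.output_format not in ("json", "csv"):
            raise ValueError(f"unknown output format {self.output_format!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        payload = tomllib.load(fh)
    return RunConfig(**payload)


# ---------------------------------------------------------------------------
# Timestamps


def _parse_timestamp(raw: str) -> datetime:
    stamp = datetime.fromisoformat(raw)
    if stamp.tzinfo is None:
        stamp = stamp.replace(tzinfo=timezone.utc)
    return stamp.astimezone(timezone.utc)


def _format_timestamp(stamp: datetime) -> str:
    return stamp.astimezone(timezone.utc).isoformat()


# ---------------------------------------------------------------------------
# Responses


def _resolve_answer(instrument: Instrument, item_id: str, answer: Any, where: str) -> int:
    item = instrument.item(item_id)  # KeyError surfaces with item id
    if isinstance(answer, bool):
        raise ValidationError([Violation("malformed", item_id, f"{where}: boolean answer")])
    if isinstance(answer, int):
        return answer
    text = str(answer).strip()
    if text.lstrip("-").isdigit():
        return int(text)
    return item.code_for_label(text)


def _response_from_dict(payload: dict, instruments: dict[str, Instrument], where: str) -> ResponseRecord:
    inst_id = payload.get("instrument") or payload.get("instrument_id")
    if inst_id not in instruments:
        raise ValidationError([Violation("malformed", "", f"{where}: unknown instrument {inst_id!r}")])
    instrument = instruments[inst_id]
    answers = {
        item_id: _resolve_answer(instrument, item_id, ans, where)
        for item_id, ans in payload["answers"].items()
    }
    record = ResponseRecord(
        instrument_id=inst_id,
        respondent_id=str(payload["respondent_id"]),
        timestamp=_parse_timestamp(payload["timestamp"]),
        answers=answers,
    )
    return validate_response(instrument, record)


def response_to_dict(record: ResponseRecord) -> dict:
    return {
        "instrument": record.instrument_id,
        "respondent_id": record.respondent_id,
        "timestamp": _format_timestamp(record.timestamp),
        "answers": dict(record.answers),
    }


def _read_responses_csv(path: Path, instruments: dict[str, Instrument]) -> list[ResponseRecord]:
    grouped: dict[tuple[str, str, str], dict[str, int]] = {}
    order: list[tuple[str, str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"respondent_id", "timestamp", "instrument", "item_id", "answer"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                [Violation("malformed", "", f"{path}: CSV must have columns {sorted(required)}")]
            )
        for row_no, row in enumerate(reader, start=2):  # header is row 1
            where = f"{path.name} row {row_no}"
            inst_id = row["instrument"]
            if inst_id not in instruments:
                raise ValidationError(
                    [Violation("malformed", "", f"{where}: unknown instrument {inst_id!r}")]
                )
            instrument = instruments[inst_id]
            try:
                code = _resolve_answer(instrument, row["item_id"], row["answer"], where)
            except KeyError as exc:
                raise ValidationError([Violation("malformed", row["item_id"], f"{where}: {exc}")]) from exc
            key = (row["respondent_id"], row["timestamp"], inst_id)
            if key not in grouped:
                grouped[key] = {}
                order.append(key)
            grouped[key][row["item_id"]] = code
    records = []
    for respondent_id, stamp, inst_id in order:
        record = ResponseRecord(
            instrument_id=inst_id,
            respondent_id=respondent_id,
            timestamp=_parse_timestamp(stamp),
            answers=grouped[(respondent_id, stamp, inst_id)],
        )
        records.append(validate_response(instruments[inst_id], record))
    return records


def read_responses(
    path: str | Path,
    format: str | None = None,
    *,
    instruments: dict[str, Instrument] | None = None,
) -> list[ResponseRecord]:
    """Read and validate response records from a JSON or CSV file.

    Format is inferred from the suffix unless given.  Every record is
    validated against its instrument; errors name the offending row or
    record index.
    """
    path = Path(path)
    if instruments is None:
        instruments = load_builtin_instruments()
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if path.stat().st_size == 0:
        logger.warning("%s: empty response file", path)
        return []
    if fmt == "csv":
        return _read_responses_csv(path, instruments)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    if not payload:
        logger.warning("%s: empty response file", path)
        return []
    return [
        _response_from_dict(rec, instruments, where=f"{path.name} record {i}")
        for i, rec in enumerate(payload)
    ]


def write_responses(records: Sequence[ResponseRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([response_to_dict(r) for r in records], fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Scored results


def ghq_result_to_dict(result: GhqResult) -> dict:
    return {
        "score": result.score,
        "threshold": result.threshold,
        "distress": result.distress,
        "standard_band": result.standard_band.value,
    }


def cbi_result_to_dict(result: CbiResult) -> dict:
    return {
        **{
            ds.dimension.value: {"score": ds.score, "level": ds.level.value}
            for ds in result.dimension_scores
        },
        "overall_risk": result.overall_risk.value,
    }


def record_to_dict(record: TestRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "respondent_id": record.respondent_id,
        "timestamp": _format_timestamp(record.timestamp),
        "ghq": ghq_result_to_dict(record.ghq),
        "cbi": cbi_result_to_dict(record.cbi),
        "diagnosis": {
            "category": record.diagnosis.category.value,
            "rationale": record.diagnosis.rationale,
        },
    }


def record_from_dict(payload: dict) -> TestRecord:
    ghq = GhqResult(
        score=int(payload["ghq"]["score"]),
        threshold=int(payload["ghq"]["threshold"]),
        distress=bool(payload["ghq"]["distress"]),
        standard_band=StandardBand(payload["ghq"]["standard_band"]),
    )
    dims = {}
    for dim in ("personal", "work", "client"):
        d = payload["cbi"][dim]
        dims[dim] = DimensionScore(
            dimension=Dimension(dim), score=float(d["score"]), level=Level(d["level"])
        )
    cbi = CbiResult(
        personal=dims["personal"],
        work=dims["work"],
        client=dims["client"],
        overall_risk=Level(payload["cbi"]["overall_risk"]),
    )
    return TestRecord(
        respondent_id=str(payload["respondent_id"]),
        timestamp=_parse_timestamp(payload["timestamp"]),
        ghq=ghq,
        cbi=cbi,
        diagnosis=Diagnosis(
            category=Category(payload["diagnosis"]["category"]),
            rationale=payload["diagnosis"]["rationale"],
        ),
    )


def _flatten_result(item: Any) -> dict:
    if isinstance(item, TestRecord):
        return {
            "respondent_id": item.respondent_id,
            "timestamp": _format_timestamp(item.timestamp),
            "ghq_score": item.ghq.score,
            "ghq_distress": item.ghq.distress,
            "ghq_standard_band": item.ghq.standard_band.value,
            "personal": f"{item.cbi.personal.score:.2f}",
            "work": f"{item.cbi.work.score:.2f}",
            "client": f"{item.cbi.client.score:.2f}",
            "overall_risk": item.cbi.overall_risk.value,
            "category": item.diagnosis.category.value,
        }
    if isinstance(item, CbiResult):
        return {
            "personal": f"{item.personal.score:.2f}",
            "work": f"{item.work.score:.2f}",
            "client": f"{item.client.score:.2f}",
            "personal_level": item.personal.level.value,
            "work_level": item.work.level.value,
            "client_level": item.client.level.value,
            "overall_risk": item.overall_risk.value,
        }
    if isinstance(item, GhqResult):
        return ghq_result_to_dict(item)
    if isinstance(item, dict):
        return item
    raise TypeError(f"cannot serialize {type(item).__name__} to a results row")


def _to_jsonable(item: Any) -> Any:
    if isinstance(item, TestRecord):
        return record_to_dict(item)
    if isinstance(item, CbiResult):
        return cbi_result_to_dict(item)
    if isinstance(item, GhqResult):
        return ghq_result_to_dict(item)
    return item


def write_results(records: Sequence[Any], path: str | Path, format: str | None = None) -> None:
    """Write scored results (TestRecord / GhqResult / CbiResult / dicts).

    JSON output round-trips; CSV flattens one row per record with CBI
    scores at 2 decimals.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "csv":
        rows = [_flatten_result(r) for r in records]
        fieldnames: list[str] = []
        for row in rows:
            fieldnames += [k for k in row if k not in fieldnames]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_to_jsonable(r) for r in records], fh, indent=1)
            fh.write("\n")


def read_test_records(path: str | Path) -> list[TestRecord]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [record_from_dict(rec) for rec in payload]


# ---------------------------------------------------------------------------
# History


def save_history(history: History, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "respondent_id": history.respondent_id,
        "records": [record_to_dict(r) for r in history.records],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_history(path: str | Path) -> History:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return History(
        respondent_id=str(doc["respondent_id"]),
        records=tuple(record_from_dict(r) for r in doc["records"]),
    )


# ---------------------------------------------------------------------------
# SUS


def read_sus_responses(path: str | Path) -> list[SusResponse]:
    """Per-respondent CSV: columns q1..q10, one row per respondent."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = [f"q{i}" for i in range(1, 11)]
        if reader.fieldnames is None or not set(cols).issubset(reader.fieldnames):
            raise ValueError(f"{path}: SUS CSV must have columns {cols}")
        return [SusResponse(answers=tuple(int(row[c]) for c in cols)) for row in reader]


def read_sus_counts(path: str | Path):
    """Aggregated CSV: one row per item with columns n1..n5 (answer counts)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = [f"n{i}" for i in range(1, 6)]
        if reader.fieldnames is None or not set(cols).issubset(reader.fieldnames):
            raise ValueError(f"{path}: SUS counts CSV must have columns {cols}")
        rows = [[int(row[c]) for c in cols] for row in reader]
    return counts_from_rows(rows)
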