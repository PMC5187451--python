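"""Flat-file I/O: JSONL event logs and the CSV visit table.

The event log is one JSON record per line with a ``record`` discriminator
(``ema``, ``message`` or ``on_demand``), append- and diff-friendly. Reading
returns records ordered by timestamp within each participant; a write/read
round trip of an ordered log is lossless.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from pydantic import ValidationError

from .errors import EventLogError
from .types import EmaRecord, MessageEvent, OnDemandEvent, VisitRecord

__all__ = ["Event", "read_event_log", "write_event_log", "read_visit_table",
           "write_visit_table", "sort_events"]

logger = logging.getLogger(__name__)

Event = Union[EmaRecord, MessageEvent, OnDemandEvent]

_TAGS: dict[str, type] = {"ema": EmaRecord, "message": MessageEvent,
                          "on_demand": OnDemandEvent}


def _event_time(ev: Event):
    return ev.at


def sort_events(events: Iterable[Event]) -> list[Event]:
    """Stable sort by (participant, timestamp)."""
    return sorted(events, key=lambda e: (e.participant_id, _event_time(e)))


def write_event_log(events: Iterable[Event], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ev in events:
            tag = {EmaRecord: "ema", MessageEvent: "message",
                   OnDemandEvent: "on_demand"}[type(ev)]
            rec = {"record": tag, **ev.model_dump(mode="json", exclude_none=True)}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_event_log(path: str | Path) -> list[Event]:
    """Parse a JSONL event log.

    Unknown record tags and invalid records raise :class:`EventLogError`
    naming the offending line. Out-of-order logs are returned sorted, with
    a warning.
    """
    path = Path(path)
    events: list[Event] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EventLogError(f"{path}:{lineno}: not valid JSON: {exc}") from exc
            tag = raw.pop("record", None)
            cls = _TAGS.get(tag)
            if cls is None:
                raise EventLogError(f"{path}:{lineno}: unknown record kind {tag!r}")
            try:
                events.append(cls(**raw))
            except ValidationError as exc:
                raise EventLogError(f"{path}:{lineno}: invalid {tag} record: {exc}") from exc
    ordered = sort_events(events)
    if ordered != events:
        logger.warning("%s: events were out of order; returning sorted", path)
    return ordered


_VISIT_COLUMNS = ["participant_id", "visit", "attended", "self_report_abstinent", "co_ppm"]


def write_visit_table(visits: Iterable[VisitRecord], path: str | Path) -> None:
    rows = [v.model_dump(mode="json") for v in visits]
    pd.DataFrame(rows, columns=_VISIT_COLUMNS).to_csv(path, index=False)


def read_visit_table(path: str | Path) -> list[VisitRecord]:
    df = pd.read_csv(path)
    missing = set(_VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise EventLogError(f"{path}: visit table missing columns {sorted(missing)}")
    out: list[VisitRecord] = []
    for i, row in df.iterrows():
        data = {
            "participant_id": str(row["participant_id"]),
            "visit": row["visit"],
            "attended": bool(row["attended"]),
            "self_report_abstinent": None if pd.isna(row["self_report_abstinent"])
            else bool(row["self_report_abstinent"]),
            "co_ppm": None if pd.isna(row["co_ppm"]) else float(row["co_ppm"]),
        }
        try:
            out.append(VisitRecord(**data))
        except ValidationError as exc:
            raise EventLogError(f"{path}: row {i}: invalid visit record: {exc}") from exc
    return out
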