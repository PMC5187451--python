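"""Message bank: the tailored-message text, keyed by level/trigger/category.

Message content is data, not code. The bank is a CSV with columns
``level, trigger_or_category, message_id, text``. Automated-message slots are
``L0``, ``L1``, ``L2`` (one slot per lapse trigger), and ``L3``; on-demand
content lives under ``quit_tips`` (5 categories) and ``medication_tips``
(4 medications). A bundled default bank covers every slot the engine can
reach.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import BankError
from .types import MessageLevel, Trigger

__all__ = ["MessageBank", "load_message_bank", "default_bank", "QUIT_TIP_CATEGORIES",
           "MEDICATION_CATEGORIES"]

QUIT_TIP_CATEGORIES = ("general_advice", "benefits", "coping_urges", "coping_stress",
                       "coping_mood")
MEDICATION_CATEGORIES = ("varenicline", "patch", "gum", "bupropion")

#: Slots the decision engine can reach; each must hold at least one entry.
REQUIRED_SLOTS = (
    ("L0", ""),
    ("L1", ""),
    ("L2", "stress_affect"),
    ("L2", "urge"),
    ("L2", "availability"),
    ("L2", "motivation"),
    ("L3", ""),
    *(("quit_tips", c) for c in QUIT_TIP_CATEGORIES),
    *(("medication_tips", c) for c in MEDICATION_CATEGORIES),
)

_LEVEL_NAMES = {"L0", "L1", "L2", "L3", "quit_tips", "medication_tips"}
_L2_TRIGGERS = {t.value for t in Trigger if t is not Trigger.none}


@dataclass
class MessageBank:
    """Ordered message entries per slot. Order matters: prequit Level-0
    messages are delivered in bank order."""

    entries: dict[tuple[str, str], list[tuple[str, str]]] = field(default_factory=dict)

    def slot(self, level: MessageLevel | str, trigger_or_category: str = "") -> list[tuple[str, str]]:
        key = (getattr(level, "value", level), trigger_or_category)
        try:
            return self.entries[key]
        except KeyError:
            raise BankError(f"message bank has no entries for slot {key}") from None

    def counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.entries.items()}

    def validate(self) -> "MessageBank":
        seen: set[str] = set()
        for key, rows in self.entries.items():
            for mid, _ in rows:
                if mid in seen:
                    raise BankError(f"duplicate message_id {mid!r}")
                seen.add(mid)
        missing = [s for s in REQUIRED_SLOTS if not self.entries.get(s)]
        if missing:
            raise BankError(f"message bank incomplete; empty slots: {missing}")
        return self


def _parse_rows(rows: list[dict[str, str]], source: str) -> MessageBank:
    entries: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, row in enumerate(rows, start=2):  # header is line 1
        level = (row.get("level") or "").strip()
        cat = (row.get("trigger_or_category") or "").strip()
        mid = (row.get("message_id") or "").strip()
        text = (row.get("text") or "").strip()
        if level not in _LEVEL_NAMES:
            raise BankError(f"{source}:{i}: unknown level {level!r}")
        if level == "L2" and cat not in _L2_TRIGGERS:
            raise BankError(f"{source}:{i}: L2 rows need a trigger, got {cat!r}")
        if level == "quit_tips" and cat not in QUIT_TIP_CATEGORIES:
            raise BankError(f"{source}:{i}: unknown quit-tip category {cat!r}")
        if level == "medication_tips" and cat not in MEDICATION_CATEGORIES:
            raise BankError(f"{source}:{i}: unknown medication category {cat!r}")
        if level in {"L0", "L1", "L3"}:
            cat = ""
        if not mid or not text:
            raise BankError(f"{source}:{i}: message_id and text are required")
        entries.setdefault((level, cat), []).append((mid, text))
    return MessageBank(entries).validate()


def load_message_bank(path: str | Path) -> MessageBank:
    """Load and validate a message bank CSV."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"level", "message_id", "text"} <= set(reader.fieldnames):
            raise BankError(f"{path}: expected columns level, trigger_or_category, message_id, text")
        rows = list(reader)
    return _parse_rows(rows, str(path))


def default_bank() -> MessageBank:
    """The bundled default message bank (every engine-reachable slot filled)."""
    ref = resources.files("smartquit.data").joinpath("default_bank.csv")
    with resources.as_file(ref) as p:
        return load_message_bank(p)
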