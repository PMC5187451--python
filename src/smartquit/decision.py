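"""Tailored-message decision algorithm.

Every completed EMA yields exactly one automated message. The level is
classified by a fixed precedence:

1. prequit phase → Level 0 (untailored preparation messages, delivered in a
   predetermined bank order);
2. postquit, participant has lapsed and reports no further interest in
   quitting → Level 0;
3. the EMA records a *new* lapse → Level 3 (return-to-abstinence messages);
4. any escalation condition → Level 2, tailored to the highest-rated current
   lapse trigger. The conditions: the lapse-risk estimator flags high
   imminent risk; the participant smoked today or yesterday; today's daily
   diary reported a smoking likelihood strictly above the threshold (25% by
   default); or the EMA is a participant-initiated urge / about-to-slip /
   already-slipped assessment;
5. otherwise → Level 1 (low-risk maintenance content).

Trigger tailoring takes the arg-max of the four trigger intensities —
negative affect/stress, urge, cigarette availability, and motivation
deficit (scale max − motivation, so low motivation competes on the same
high-is-bad axis) — breaking ties by that fixed priority order.

The lapse-risk estimator is a pluggable linear score; the published
momentary estimators can be substituted by swapping the spec without
touching the engine.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .bank import MessageBank
from .config import RiskEstimatorSpec, StudyConfig
from .errors import ConfigError, PeriodError
from .eventlog import Event, sort_events
from .types import (
    EmaKind,
    EmaRecord,
    EmaStatus,
    ItemResponses,
    MessageEvent,
    MessageLevel,
    OnDemandEvent,
    OnDemandKind,
    Participant,
    Trigger,
)

__all__ = [
    "Phase",
    "ContextFeatures",
    "estimate_lapse_risk",
    "classify_level",
    "select_trigger",
    "MessageSelector",
    "countdown_message",
    "record_on_demand",
    "run_engine",
]

#: Self-initiated EMA kinds that escalate to Level 2 by themselves.
SLIP_KINDS = frozenset({EmaKind.urge, EmaKind.about_to_slip, EmaKind.already_slipped})


class Phase(str, enum.Enum):
    prequit = "prequit"
    postquit = "postquit"


class ContextFeatures(BaseModel):
    """Everything the level classifier needs about one completed EMA,
    recomputable from the event log alone."""

    model_config = ConfigDict(extra="forbid")

    phase: Phase
    ema_kind: EmaKind
    items: ItemResponses
    smoked_today_or_yesterday: bool = False
    diary_likelihood_today_pct: Optional[float] = None
    lapsed_and_uninterested: bool = False
    new_lapse_event: bool = False
    high_risk: Optional[bool] = None  # precomputed override; None → use estimator

    @model_validator(mode="after")
    def _check(self) -> "ContextFeatures":
        if self.phase is Phase.prequit and (
            self.lapsed_and_uninterested or self.new_lapse_event
            or self.smoked_today_or_yesterday
        ):
            raise ValueError("postquit-only lapse flags set on a prequit context")
        return self


def estimate_lapse_risk(
    items: ItemResponses,
    spec: RiskEstimatorSpec,
    scale_max: int = 10,
) -> dict:
    """Linear lapse-risk score; high risk iff score strictly exceeds the
    spec threshold. Deterministic, and monotone nondecreasing in urge and
    negative affect/stress under the default (nonnegative) weights."""
    features = {
        "urge": float(items.urge),
        "negative_affect_stress": float(items.negative_affect_stress),
        "cigarette_availability": float(items.cigarette_availability),
        "motivation_deficit": float(scale_max - items.motivation_to_quit),
        "smoked_since_last": 1.0 if items.smoked_since_last else 0.0,
    }
    score = spec.intercept
    for name, weight in spec.weights.items():
        try:
            score += weight * features[name]
        except KeyError:
            raise ConfigError(f"risk estimator weight refers to unknown item {name!r}")
    if not math.isfinite(score):
        raise ConfigError("risk score is not finite; check estimator weights")
    return {"score": score, "high_risk": score > spec.threshold}


def classify_level(context: ContextFeatures, config: StudyConfig) -> MessageLevel:
    """Map one completed EMA's context to a message level (precedence above)."""
    if context.phase is Phase.prequit:
        return MessageLevel.L0
    if context.lapsed_and_uninterested:
        return MessageLevel.L0
    if context.new_lapse_event:
        return MessageLevel.L3
    high_risk = context.high_risk
    if high_risk is None:
        high_risk = estimate_lapse_risk(
            context.items, config.risk_estimator, config.item_scale_max
        )["high_risk"]
    diary_over = (
        context.diary_likelihood_today_pct is not None
        and context.diary_likelihood_today_pct > config.diary_risk_threshold_pct
    )
    if (
        high_risk
        or context.smoked_today_or_yesterday
        or diary_over
        or context.ema_kind in SLIP_KINDS
    ):
        return MessageLevel.L2
    return MessageLevel.L1


def select_trigger(items: ItemResponses, scale_max: int = 10) -> Trigger:
    """Highest-rated current lapse trigger; ties go to the fixed priority
    order stress/affect > urge > availability > motivation."""
    intensities = (
        (Trigger.stress_affect, items.negative_affect_stress),
        (Trigger.urge, items.urge),
        (Trigger.availability, items.cigarette_availability),
        (Trigger.motivation, scale_max - items.motivation_to_quit),
    )
    best = max(v for _, v in intensities)
    for trig, v in intensities:
        if v == best:
            return trig
    raise AssertionError("unreachable")


@dataclass
class MessageSelector:
    """Stateful message choice within bank slots.

    Level-0 prequit messages follow the bank's predetermined order,
    cycling; every other slot is served round-robin, which avoids delivering
    the same message twice in a row whenever a slot holds at least two
    entries."""

    bank: MessageBank
    _cursor: dict[tuple[str, str], int] = field(default_factory=dict)

    def next_message(self, level: MessageLevel, trigger: Trigger = Trigger.none) -> tuple[str, str]:
        slot_key = (level.value, trigger.value if level is MessageLevel.L2 else "")
        entries = self.bank.slot(level, slot_key[1])
        i = self._cursor.get(slot_key, 0)
        self._cursor[slot_key] = i + 1
        return entries[i % len(entries)]


def countdown_message(today: datetime, quit_datetime: datetime) -> str:
    """Daily prequit countdown: how many days until the scheduled quit."""
    if today >= quit_datetime:
        raise PeriodError("countdown message is a prequit feature")
    days = math.ceil((quit_datetime - today) / timedelta(days=1))
    unit = "DAY" if days == 1 else "DAYS"
    when = quit_datetime.strftime("%A at %I:%M %p").replace(" 0", " ")
    return (
        f"You are scheduled to quit smoking in {days} {unit}, on {when}. "
        "Having a plan and taking your medications will GREATLY increase "
        "your chances of staying quit."
    )


def record_on_demand(
    kind: OnDemandKind,
    at: datetime,
    participant_id: str,
    category: Optional[str] = None,
    n_tips_viewed: Optional[int] = None,
    bank: Optional[MessageBank] = None,
) -> OnDemandEvent:
    """Log one on-demand feature use (Quit Tips, Medication Tips, the
    one-click quitline call stub, staff call, or the payment screen)."""
    if kind in (OnDemandKind.quit_tips, OnDemandKind.medication_tips):
        from .bank import MEDICATION_CATEGORIES, QUIT_TIP_CATEGORIES

        valid = QUIT_TIP_CATEGORIES if kind is OnDemandKind.quit_tips else MEDICATION_CATEGORIES
        if category not in valid:
            raise ValueError(f"unknown {kind.value} category {category!r}")
        if bank is not None:
            bank.slot(kind.value, category)  # raises if the slot is empty
    else:
        if category is not None:
            raise ValueError(f"{kind.value} takes no category")
    return OnDemandEvent(
        participant_id=participant_id,
        at=at,
        kind=kind,
        category=category,
        n_tips_viewed=n_tips_viewed,
    )


# ---------------------------------------------------------------------------
# Event-log replay


def _reports_lapse(rec: EmaRecord) -> bool:
    """Did this completed EMA itself record a lapse?"""
    if rec.kind is EmaKind.already_slipped:
        return True
    if rec.kind is EmaKind.slip_followup and rec.items is not None:
        return rec.items.smoked_since_last
    return False


@dataclass
class _ParticipantHistory:
    lapse_days: set[int] = field(default_factory=set)
    last_diary_pct: Optional[float] = None
    last_diary_day: Optional[int] = None
    uninterested: bool = False

    def smoked_today_or_yesterday(self, day: int) -> bool:
        return day in self.lapse_days or (day - 1) in self.lapse_days


def _day_index(at: datetime, participant: Optional[Participant]) -> int:
    if participant is not None:
        return participant.day_index(at)
    # external logs without a participant table: 04:00 day boundary
    return (at - timedelta(hours=4)).date().toordinal()


def build_context(
    rec: EmaRecord,
    history: _ParticipantHistory,
    config: StudyConfig,
    participant: Optional[Participant] = None,
) -> ContextFeatures:
    """Derive the classifier context for one completed EMA from history."""
    assert rec.items is not None
    at = rec.at
    phase = Phase.prequit if at < config.quit_datetime else Phase.postquit
    if phase is Phase.prequit:
        return ContextFeatures(phase=phase, ema_kind=rec.kind, items=rec.items)
    day = _day_index(at, participant)
    prior_smoked = history.smoked_today_or_yesterday(day)
    reports = _reports_lapse(rec)
    new_lapse = reports and not prior_smoked
    smoked = prior_smoked or reports or rec.items.smoked_since_last
    diary_pct = history.last_diary_pct if history.last_diary_day == day else None
    if rec.kind is EmaKind.daily_diary and rec.items.diary_smoking_likelihood_pct is not None:
        diary_pct = float(rec.items.diary_smoking_likelihood_pct)
    lapsed_ever = bool(history.lapse_days) or reports or rec.items.smoked_since_last
    uninterested = history.uninterested
    if rec.items.still_interested_in_quitting is not None:
        uninterested = not rec.items.still_interested_in_quitting
    return ContextFeatures(
        phase=phase,
        ema_kind=rec.kind,
        items=rec.items,
        smoked_today_or_yesterday=smoked,
        diary_likelihood_today_pct=diary_pct,
        lapsed_and_uninterested=lapsed_ever and uninterested,
        new_lapse_event=new_lapse,
    )


def _update_history(
    rec: EmaRecord,
    history: _ParticipantHistory,
    config: StudyConfig,
    participant: Optional[Participant],
) -> None:
    assert rec.items is not None
    at = rec.at
    day = _day_index(at, participant)
    if rec.kind is EmaKind.daily_diary and rec.items.diary_smoking_likelihood_pct is not None:
        history.last_diary_pct = float(rec.items.diary_smoking_likelihood_pct)
        history.last_diary_day = day
    if at >= config.quit_datetime:
        if _reports_lapse(rec) or rec.items.smoked_since_last:
            history.lapse_days.add(day)
        if rec.items.still_interested_in_quitting is not None:
            history.uninterested = not rec.items.still_interested_in_quitting


def run_engine(
    events: Iterable[Event],
    bank: MessageBank,
    config: StudyConfig,
    participants: Optional[dict[str, Participant]] = None,
) -> list[MessageEvent]:
    """Replay an event log and emit exactly one message per completed EMA.

    Deterministic: the same log, bank and configuration always produce the
    same message sequence.
    """
    participants = participants or {}
    selectors: dict[str, MessageSelector] = {}
    histories: dict[str, _ParticipantHistory] = {}
    messages: list[MessageEvent] = []
    ema_counter: dict[str, int] = {}
    for ev in sort_events(events):
        if not isinstance(ev, EmaRecord):
            continue
        pid = ev.participant_id
        ema_counter[pid] = ema_counter.get(pid, 0) + 1
        if ev.status is not EmaStatus.completed:
            continue
        participant = participants.get(pid)
        history = histories.setdefault(pid, _ParticipantHistory())
        selector = selectors.setdefault(pid, MessageSelector(bank))
        context = build_context(ev, history, config, participant)
        level = classify_level(context, config)
        trigger = (
            select_trigger(ev.items, config.item_scale_max)
            if level is MessageLevel.L2
            else Trigger.none
        )
        mid, _text = selector.next_message(level, trigger)
        messages.append(
            MessageEvent(
                participant_id=pid,
                at=ev.completed_at or ev.at,
                level=level,
                trigger=trigger,
                message_id=mid,
                source_ema_id=f"{pid}-ema-{ema_counter[pid]}",
            )
        )
        _update_history(ev, history, config, participant)
    return sort_events(messages)
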