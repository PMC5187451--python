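"""Domain records shared by the scheduler, decision engine, simulator and metrics.

All timestamps are timezone-naive study-local time. The study day boundary is
the participant's wake time, not midnight: the daily diary is anchored to
waking, so "today" for decision rules runs wake-to-wake.
"""

from __future__ import annotations

import enum
from datetime import date, datetime, time, timedelta
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class EmaKind(str, enum.Enum):
    daily_diary = "daily_diary"
    random = "random"
    precig = "precig"
    postcig = "postcig"
    urge = "urge"
    about_to_slip = "about_to_slip"
    slip_followup = "slip_followup"
    already_slipped = "already_slipped"


class EmaOrigin(str, enum.Enum):
    prompted = "prompted"
    self_initiated = "self_initiated"
    system_followup = "system_followup"


class EmaStatus(str, enum.Enum):
    pending = "pending"
    completed = "completed"
    missed = "missed"


class MessageLevel(str, enum.Enum):
    L0 = "L0"
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"


class Trigger(str, enum.Enum):
    """Lapse triggers a Level-2 message can be tailored to, in the fixed
    tie-break priority order: negative affect/stress first, then smoking
    urge, cigarette availability, and low motivation to quit."""

    stress_affect = "stress_affect"
    urge = "urge"
    availability = "availability"
    motivation = "motivation"
    none = "none"


class VisitKind(str, enum.Enum):
    quit_date = "quit_date"
    wk1 = "wk1"
    wk2 = "wk2"
    wk3 = "wk3"
    wk4 = "wk4"
    wk12 = "wk12"


class OnDemandKind(str, enum.Enum):
    quit_tips = "quit_tips"
    medication_tips = "medication_tips"
    phone_counselor = "phone_counselor"
    call_staff = "call_staff"
    payment_view = "payment_view"


#: EMA kinds delivered as system prompts (subject to the answer window).
PROMPTED_KINDS = frozenset({EmaKind.daily_diary, EmaKind.random})
#: Kinds the participant initiates by pressing a button.
SELF_INITIATED_KINDS = frozenset(
    {EmaKind.precig, EmaKind.urge, EmaKind.about_to_slip, EmaKind.already_slipped}
)
#: System-scheduled follow-ups to an event.
FOLLOWUP_KINDS = frozenset({EmaKind.postcig, EmaKind.slip_followup})


class Participant(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    wake_time: time = time(8, 0)
    sleep_time: time = time(22, 0)
    enrollment_date: date = date(2023, 1, 2)
    eligibility_flags: dict[str, bool] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "Participant":
        if self.waking_minutes <= 0:
            raise ValueError(f"participant {self.id}: sleep_time must be after wake_time")
        return self

    @property
    def waking_minutes(self) -> float:
        w = self.wake_time.hour * 60 + self.wake_time.minute
        s = self.sleep_time.hour * 60 + self.sleep_time.minute
        return float(s - w)

    def wake_datetime(self, day: date) -> datetime:
        return datetime.combine(day, self.wake_time)

    def sleep_datetime(self, day: date) -> datetime:
        return datetime.combine(day, self.sleep_time)

    def day_index(self, at: datetime) -> int:
        """Participant-day index of a timestamp, with days bounded by wake time."""
        anchor = datetime.combine(self.enrollment_date, self.wake_time)
        return (at - anchor) // timedelta(days=1)


class ItemResponses(BaseModel):
    """Answers to the momentary items. Scores use 0–10 integer scales,
    likelihood 0–100; scales are declared in StudyConfig so a different
    instrument is a configuration change."""

    model_config = ConfigDict(extra="forbid")

    urge: int = Field(0, ge=0, le=10)
    negative_affect_stress: int = Field(0, ge=0, le=10)
    cigarette_availability: int = Field(0, ge=0, le=10)
    motivation_to_quit: int = Field(10, ge=0, le=10)
    smoked_since_last: bool = False
    diary_smoking_likelihood_pct: Optional[int] = Field(None, ge=0, le=100)
    still_interested_in_quitting: Optional[bool] = None
    alcohol_last_24h: bool = False


class EmaRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    participant_id: str
    kind: EmaKind
    origin: EmaOrigin
    scheduled_at: Optional[datetime] = None
    presented_at: Optional[datetime] = None
    completed_at: Optional[datetime] = None
    response_latency_sec: Optional[float] = Field(None, ge=0)
    status: EmaStatus = EmaStatus.pending
    items: Optional[ItemResponses] = None

    @model_validator(mode="after")
    def _check(self) -> "EmaRecord":
        if self.status is EmaStatus.completed and self.items is None:
            raise ValueError("completed EMA must carry item responses")
        if self.status is EmaStatus.missed and self.items is not None:
            raise ValueError("missed EMA must not carry item responses")
        if self.origin is EmaOrigin.self_initiated and self.scheduled_at is not None:
            raise ValueError("self-initiated EMA cannot have a scheduled time")
        if (
            self.items is not None
            and self.items.diary_smoking_likelihood_pct is not None
            and self.kind is not EmaKind.daily_diary
        ):
            raise ValueError("diary smoking likelihood only appears on daily diaries")
        return self

    @property
    def at(self) -> datetime:
        """Canonical event time: presentation, else schedule, else completion."""
        t = self.presented_at or self.scheduled_at or self.completed_at
        if t is None:
            raise ValueError("EMA record has no timestamp")
        return t

    @property
    def completion_minutes(self) -> Optional[float]:
        if self.presented_at is None or self.completed_at is None:
            return None
        return (self.completed_at - self.presented_at).total_seconds() / 60.0


class MessageEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    participant_id: str
    at: datetime
    level: MessageLevel
    trigger: Trigger = Trigger.none
    message_id: str
    source_ema_id: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "MessageEvent":
        if (self.trigger is not Trigger.none) != (self.level is MessageLevel.L2):
            raise ValueError("trigger is set if and only if level is L2")
        return self


class OnDemandEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    participant_id: str
    at: datetime
    kind: OnDemandKind
    category: Optional[str] = None
    n_tips_viewed: Optional[int] = Field(None, ge=0)


class VisitRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    participant_id: str
    visit: VisitKind
    attended: bool
    self_report_abstinent: Optional[bool] = None
    co_ppm: Optional[float] = Field(None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "VisitRecord":
        if not self.attended and (
            self.self_report_abstinent is not None or self.co_ppm is not None
        ):
            raise ValueError("a missed visit cannot carry self-report or CO data")
        return self
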