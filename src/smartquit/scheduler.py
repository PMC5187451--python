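"""Prompt scheduling: daily diary, random prompts, and event-contingent follow-ups.

Each active study day carries one daily diary (at wake time + a fixed offset,
30 minutes by default) and ``n_random_per_day`` random prompts placed inside
the participant's waking window. Random placement stratifies the window into
equal segments and draws uniformly within each, rejecting draws that put two
prompts (or a prompt and the diary) closer than the minimum gap — standard
experience-sampling practice that spreads prompts across the day while
keeping them unpredictable.

System prompts cue for a fixed answer window (60 s); a response initiated
after the window, or no response, records the assessment as missed and it
never re-fires. Event-contingent logic lives in :class:`SamplingState`:
during the prequit week at most ``max_sampled_cigs_per_day`` logged smoking
occasions per day receive the full pre-cigarette assessment, each followed by
a post-cigarette prompt 15 minutes later; during the postquit weeks an
about-to-slip report schedules a 15-minute follow-up asking whether the
participant actually smoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np

from .config import StudyConfig
from .errors import PeriodError, SchedulingError
from .types import EmaKind, EmaOrigin, EmaRecord, EmaStatus, Participant

__all__ = ["DaySchedule", "SamplingState", "build_day_schedule", "resolve_prompt",
           "register_precig_event", "register_slip_event"]

_MAX_REJECTION_TRIES = 200


@dataclass(frozen=True)
class DaySchedule:
    participant_id: str
    date: date
    prompts: tuple[tuple[EmaKind, datetime], ...]


def _random_times(
    wake: datetime,
    sleep: datetime,
    diary_at: datetime,
    n: int,
    min_gap: timedelta,
    rng: np.random.Generator,
) -> list[datetime]:
    """Stratified placement with rejection; deterministic grid fallback."""
    window = (sleep - wake).total_seconds()
    stratum = window / n

    def ok(times: list[datetime]) -> bool:
        ts = sorted(times)
        if any(t2 - t1 < min_gap for t1, t2 in zip(ts, ts[1:])):
            return False
        return all(abs(t - diary_at) >= min_gap for t in ts)

    for _ in range(_MAX_REJECTION_TRIES):
        draws = [
            wake + timedelta(seconds=round(stratum * i + rng.uniform(0, stratum)))
            for i in range(n)
        ]
        draws = [min(t, sleep) for t in draws]
        if ok(draws):
            return sorted(draws)

    # Grid fallback: candidates min_gap apart from wake, skipping the diary's
    # exclusion zone. Feasibility was checked by the caller, so n remain.
    candidates = []
    t = wake
    while t <= sleep:
        if abs(t - diary_at) >= min_gap:
            candidates.append(t)
        t += min_gap
    if len(candidates) < n:
        raise SchedulingError(
            "waking window too short for the requested prompt spacing; reduce min_gap_min"
        )
    idx = np.linspace(0, len(candidates) - 1, n).round().astype(int)
    return [candidates[i] for i in idx]


def build_day_schedule(
    participant: Participant,
    day: date,
    config: StudyConfig,
    rng: np.random.Generator,
) -> DaySchedule:
    """Build one study day's prompted-EMA schedule (1 diary + n random).

    Deterministic given the generator state; the same seeded generator
    yields the same schedule.
    """
    start = config.enrollment_datetime.date()
    end = start + timedelta(days=config.total_days)
    if not (start <= day < end):
        raise SchedulingError(
            f"{day} outside the EMA period [{start}, {end})"
        )
    wake = participant.wake_datetime(day)
    sleep = participant.sleep_datetime(day)
    min_gap = timedelta(minutes=config.min_gap_min)
    needed = (config.n_random_per_day + 2) * config.min_gap_min
    if (sleep - wake).total_seconds() / 60.0 < needed:
        raise SchedulingError(
            f"waking window shorter than feasible spacing for "
            f"{config.n_random_per_day} random prompts; reduce min_gap_min"
        )
    diary_at = wake + timedelta(minutes=config.diary_offset_min)
    prompts: list[tuple[EmaKind, datetime]] = [(EmaKind.daily_diary, diary_at)]
    if config.n_random_per_day > 0:
        for t in _random_times(wake, sleep, diary_at, config.n_random_per_day, min_gap, rng):
            prompts.append((EmaKind.random, t))
    prompts.sort(key=lambda p: p[1])
    return DaySchedule(participant.id, day, tuple(prompts))


def resolve_prompt(
    prompt: EmaRecord,
    response_latency_sec: Optional[float],
    config: StudyConfig,
) -> EmaStatus:
    """Resolve a cued prompt: completed iff the response began within the
    answer window; no response, or a late one, is missed (final — prompts
    never re-fire)."""
    if response_latency_sec is None:
        return EmaStatus.missed
    if response_latency_sec < 0:
        raise ValueError("response latency cannot be negative")
    if response_latency_sec <= config.prompt_window_sec:
        return EmaStatus.completed
    return EmaStatus.missed


@dataclass
class SamplingState:
    """Per-participant event-sampling state: the day's sampled smoking
    occasions (counted as completed pre-cigarette assessments) and the queue
    of pending system follow-ups."""

    participant: Participant
    sampled_by_day: dict[int, int] = field(default_factory=dict)
    pending_followups: list[tuple[EmaKind, datetime]] = field(default_factory=list)

    def sampled_today(self, at: datetime) -> int:
        return self.sampled_by_day.get(self.participant.day_index(at), 0)

    def pop_due(self, now: datetime) -> list[tuple[EmaKind, datetime]]:
        due = [f for f in self.pending_followups if f[1] <= now]
        self.pending_followups = [f for f in self.pending_followups if f[1] > now]
        return due


def register_precig_event(
    participant: Participant,
    at: datetime,
    state: SamplingState,
    config: StudyConfig,
    rng: np.random.Generator,
) -> dict:
    """Handle a prequit "Record Cigarette" press.

    While the day's sampled count is under the cap, the occasion is sampled
    with probability ``p_sample_occasion`` (default 1 — sample every occasion
    until the cap); a sampled occasion presents the pre-cigarette assessment
    now and queues the post-cigarette follow-up 15 minutes after its
    completion. Postquit presses are rejected: the slip buttons apply then.
    """
    if at >= config.quit_datetime:
        raise PeriodError(
            "Record Cigarette applies to the prequit period only; "
            "use the Urge / About to Slip / Already Slipped buttons after quitting"
        )
    day = participant.day_index(at)
    count = state.sampled_by_day.get(day, 0)
    if count >= config.max_sampled_cigs_per_day:
        return {"sampled": False, "followup_due": None}
    if rng.uniform() > config.p_sample_occasion:
        return {"sampled": False, "followup_due": None}
    state.sampled_by_day[day] = count + 1
    due = at + timedelta(minutes=config.postcig_delay_min)
    state.pending_followups.append((EmaKind.postcig, due))
    return {"sampled": True, "followup_due": due}


def register_slip_event(
    kind: EmaKind,
    at: datetime,
    state: SamplingState,
    config: StudyConfig,
) -> dict:
    """Handle a postquit Urge / About to Slip / Already Slipped press.

    Only About to Slip schedules a follow-up (15 minutes later, asking
    whether the participant actually smoked)."""
    if kind not in (EmaKind.urge, EmaKind.about_to_slip, EmaKind.already_slipped):
        raise ValueError(f"not a slip-button kind: {kind}")
    if at < config.quit_datetime:
        raise PeriodError(
            "slip buttons apply to the postquit period only; "
            "use Record Cigarette before the quit date"
        )
    if kind is EmaKind.about_to_slip:
        due = at + timedelta(minutes=config.slip_followup_delay_min)
        state.pending_followups.append((EmaKind.slip_followup, due))
        return {"kind": kind, "followup_due": due}
    return {"kind": kind, "followup_due": None}


def make_prompt_record(
    participant_id: str,
    kind: EmaKind,
    scheduled_at: datetime,
    origin: EmaOrigin = EmaOrigin.prompted,
) -> EmaRecord:
    """A pending prompt record, before resolution."""
    return EmaRecord(
        participant_id=participant_id,
        kind=kind,
        origin=origin,
        scheduled_at=scheduled_at,
        status=EmaStatus.pending,
    )
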