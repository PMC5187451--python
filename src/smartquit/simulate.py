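"""Synthetic-cohort generator.

Emulates the 3-week protocol flow for a cohort of treatment-seeking smokers:
per-participant waking windows, the prompted schedule (1 diary + 4 random
EMAs/day for 21 days), Bernoulli prompt adherence, latent AR(1) urge /
negative-affect / availability / motivation dynamics read out as item
responses, prequit cigarette logging with the 2-occasion/day sampling cap,
postquit lapses from a per-epoch logistic hazard on the latent state,
self-initiated urge/slip assessments, on-demand feature use, and follow-up
visits with status-conditional expired-CO readings.

Defaults are calibrated to the observed feasibility figures: 87 % prompt
completion, ~15.5 self-initiated assessments per participant over the
21 days, 20.3 (SD 11.6) cigarettes/day at baseline, and baseline CO
18.6 (SD 13.0) ppm for active smokers. The generator claims no behavioral
realism beyond this declared structure; intervention messages do not feed
back into the lapse hazard (a feedback coefficient exists but defaults
to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import truncnorm

from .bank import MEDICATION_CATEGORIES, QUIT_TIP_CATEGORIES
from .config import StudyConfig
from .eventlog import Event, sort_events
from .scheduler import SamplingState, build_day_schedule, register_precig_event, register_slip_event
from .types import (
    EmaKind,
    EmaOrigin,
    EmaRecord,
    EmaStatus,
    ItemResponses,
    OnDemandEvent,
    OnDemandKind,
    Participant,
    VisitKind,
    VisitRecord,
)

__all__ = ["BehaviorParams", "CohortDataset", "RecoveryResult", "simulate_participant",
           "simulate_cohort", "recover_parameters"]


class BehaviorParams(BaseModel):
    """Generative parameters of the synthetic cohort (defaults = study
    conditions)."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(59, ge=1)
    p_respond: float = Field(0.87, ge=0.0, le=1.0)

    #: Declared expectation of self-initiated EMAs per participant over the
    #: EMA period. Implemented by two mechanisms whose defaults were chosen
    #: to meet it: prequit cigarette logging (p_record_cig per cigarette,
    #: capped at 2 sampled occasions/day) plus postquit urge/slip events at
    #: postquit_event_rate per day.
    self_initiated_rate: float = Field(15.5, ge=0.0)
    p_record_cig: float = Field(0.12, ge=0.0, le=1.0)
    postquit_event_rate: float = Field(0.30, ge=0.0)

    # latent AR(1) dynamics on the 0-10 item scale
    ar_phi: float = Field(0.7, ge=0.0, lt=1.0)
    ar_sigma: float = Field(1.5, gt=0.0)
    latent_means: dict[str, float] = Field(
        default_factory=lambda: {
            "urge": 5.0,
            "negative_affect_stress": 4.0,
            "cigarette_availability": 6.0,
            "motivation_to_quit": 7.0,
        }
    )

    # per-epoch logistic lapse hazard on the latent state (postquit only)
    hazard_intercept: float = -7.0
    hazard_coefs: dict[str, float] = Field(
        default_factory=lambda: {
            "urge": 0.4,
            "negative_affect_stress": 0.2,
            "cigarette_availability": 0.15,
            "motivation_deficit": 0.1,
        }
    )
    #: effect of delivered messages on the hazard logit; 0 = no feedback
    message_feedback: float = 0.0

    cigs_per_day_mean: float = Field(20.3, gt=0.0)
    cigs_per_day_sd: float = Field(11.6, gt=0.0)
    cigs_per_day_min: float = Field(5.0, ge=0.0)

    p_still_interested: float = Field(0.9, ge=0.0, le=1.0)
    p_alcohol: float = Field(0.15, ge=0.0, le=1.0)

    visit_attendance: dict[str, float] = Field(
        default_factory=lambda: {
            "quit_date": 0.92,
            "wk1": 0.98,
            "wk2": 0.98,
            "wk3": 0.90,
            "wk4": 0.83,
            "wk12": 0.78,
        }
    )
    co_abstinent_mean: float = 3.0
    co_abstinent_sd: float = 1.5
    co_smoker_mean: float = 18.6
    co_smoker_sd: float = 13.0
    #: weekly carry-forward of abstinence beyond the EMA window
    abstinence_persistence: float = Field(0.85, ge=0.0, le=1.0)
    recycle_prob: float = Field(0.08, ge=0.0, le=1.0)

    # on-demand feature use
    p_use_quit_tips: float = Field(0.83, ge=0.0, le=1.0)
    quit_tips_accesses_mean: float = 5.5
    quit_tips_intensity_median: float = 18.0
    p_use_med_tips: float = Field(0.83, ge=0.0, le=1.0)
    med_tips_accesses_mean: float = 4.2
    med_tips_intensity_median: float = 10.0
    p_phone_counselor: float = Field(0.22, ge=0.0, le=1.0)

    seed: int = 0


# mean/SD completion minutes by (kind, phase); calibrated to the reported
# completion times for each assessment type
_DURATIONS: dict[tuple[str, bool], tuple[float, float]] = {
    ("daily_diary", True): (6.1, 1.9),
    ("daily_diary", False): (4.8, 1.5),
    ("random", True): (2.3, 0.6),
    ("random", False): (2.1, 0.9),
    ("urge", False): (2.0, 0.9),
    ("already_slipped", False): (4.5, 1.5),
}
_DEFAULT_DURATION = (2.5, 1.0)


def _duration_min(kind: EmaKind, prequit: bool, rng: np.random.Generator) -> float:
    mean, sd = _DURATIONS.get((kind.value, prequit), _DEFAULT_DURATION)
    return max(0.5, rng.normal(mean, sd))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    a = (lo - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


@dataclass
class _Latent:
    """AR(1) latent state, clipped to the item scale at read-out."""

    mu: dict[str, float]
    phi: float
    sigma: float
    x: dict[str, float]

    @classmethod
    def init(cls, params: BehaviorParams, rng: np.random.Generator) -> "_Latent":
        mu = dict(params.latent_means)
        sd0 = params.ar_sigma / math.sqrt(1.0 - params.ar_phi**2)
        x = {k: v + rng.normal(0.0, sd0) for k, v in mu.items()}
        return cls(mu, params.ar_phi, params.ar_sigma, x)

    def step(self, rng: np.random.Generator) -> None:
        for k in self.x:
            self.x[k] = self.mu[k] + self.phi * (self.x[k] - self.mu[k]) + rng.normal(
                0.0, self.sigma
            )

    def read(self, scale_max: int) -> dict[str, int]:
        return {k: int(np.clip(round(v), 0, scale_max)) for k, v in self.x.items()}


def _hazard_p(latent: _Latent, params: BehaviorParams, scale_max: int) -> float:
    vals = latent.read(scale_max)
    logit = params.hazard_intercept
    for name, b in params.hazard_coefs.items():
        if name == "motivation_deficit":
            logit += b * (scale_max - vals["motivation_to_quit"])
        else:
            logit += b * vals[name]
    return 1.0 / (1.0 + math.exp(-logit))


def _make_items(
    latent: _Latent,
    kind: EmaKind,
    smoked_since_last: bool,
    config: StudyConfig,
    params: BehaviorParams,
    rng: np.random.Generator,
    still_interested: Optional[bool] = None,
) -> ItemResponses:
    vals = latent.read(config.item_scale_max)
    diary_pct = None
    if kind is EmaKind.daily_diary:
        # self-forecast loosely tracks current urge
        diary_pct = int(
            np.clip(round(5.0 * latent.x["urge"] + rng.normal(0.0, 10.0)), 0,
                    config.diary_scale_max)
        )
    return ItemResponses(
        urge=vals["urge"],
        negative_affect_stress=vals["negative_affect_stress"],
        cigarette_availability=vals["cigarette_availability"],
        motivation_to_quit=vals["motivation_to_quit"],
        smoked_since_last=smoked_since_last,
        diary_smoking_likelihood_pct=diary_pct,
        still_interested_in_quitting=still_interested,
        alcohol_last_24h=bool(rng.random() < params.p_alcohol),
    )


def make_participant(index: int, config: StudyConfig, rng: np.random.Generator) -> Participant:
    wake_min = int(rng.integers(6 * 60, 9 * 60))
    duration_min = int(rng.uniform(14 * 60, 16.5 * 60))
    sleep_min = min(wake_min + duration_min, 23 * 60 + 45)
    return Participant(
        id=f"P{index:03d}",
        wake_time=time(wake_min // 60, wake_min % 60),
        sleep_time=time(sleep_min // 60, sleep_min % 60),
        enrollment_date=config.enrollment_datetime.date(),
        eligibility_flags={
            "literacy_grade6": True,
            "age_18_plus": True,
            "baseline_co_8ppm": True,
            "cigs_per_day_5_plus": True,
            "willing_to_quit_7d": True,
        },
    )


_VISIT_OFFSETS_DAYS = {
    VisitKind.quit_date: 0,
    VisitKind.wk1: 7,
    VisitKind.wk2: 14,
    VisitKind.wk3: 21,
    VisitKind.wk4: 28,
    VisitKind.wk12: 84,
}


def _simulate_one(
    participant: Participant,
    params: BehaviorParams,
    config: StudyConfig,
    rng: np.random.Generator,
):
    events: list[Event] = []
    epoch_rows: list[dict] = []
    lapse_times: list[datetime] = []
    latent = _Latent.init(params, rng)
    state = SamplingState(participant=participant)
    cigs_mean = _truncnorm(rng, params.cigs_per_day_mean, params.cigs_per_day_sd,
                           params.cigs_per_day_min)
    last_epoch_at: Optional[datetime] = None

    def smoked_since(prev: Optional[datetime], now: datetime) -> bool:
        lo = prev if prev is not None else config.quit_datetime
        return any(lo < lt <= now for lt in lapse_times)

    def draw_lapse(at: datetime) -> bool:
        p = _hazard_p(latent, params, config.item_scale_max)
        vals = latent.read(config.item_scale_max)
        fired = bool(rng.random() < p)
        epoch_rows.append(
            {
                "participant_id": participant.id,
                "at": at,
                "urge": vals["urge"],
                "negative_affect_stress": vals["negative_affect_stress"],
                "cigarette_availability": vals["cigarette_availability"],
                "motivation_deficit": config.item_scale_max - vals["motivation_to_quit"],
                "lapse": int(fired),
            }
        )
        if fired:
            lapse_times.append(at)
        return fired

    start = config.enrollment_datetime.date()
    for d in range(config.total_days):
        day = start + timedelta(days=d)
        prequit_day = d < config.prequit_days
        sched = build_day_schedule(participant, day, config, rng)
        epochs: list[tuple[str, EmaKind, datetime]] = [
            ("prompt", kind, at) for kind, at in sched.prompts
        ]
        wake = participant.wake_datetime(day)
        sleep = participant.sleep_datetime(day)
        window_sec = (sleep - wake).total_seconds()
        if prequit_day:
            n_cigs = int(rng.poisson(cigs_mean))
            n_press = int(rng.binomial(n_cigs, params.p_record_cig)) if n_cigs else 0
            for _ in range(n_press):
                t = wake + timedelta(seconds=float(rng.uniform(0, window_sec)))
                if t < config.quit_datetime:
                    epochs.append(("press", EmaKind.precig, t))
        else:
            for _ in range(int(rng.poisson(params.postquit_event_rate))):
                t = wake + timedelta(seconds=float(rng.uniform(0, window_sec)))
                if t >= config.quit_datetime:
                    epochs.append(("slip_button", EmaKind.urge, t))
        epochs.sort(key=lambda e: e[2])

        for source, kind, at in epochs:
            latent.step(rng)
            postquit_now = at >= config.quit_datetime

            if source == "prompt":
                completed = bool(rng.random() < params.p_respond)
                if postquit_now:
                    draw_lapse(at)
                if completed:
                    latency = float(rng.uniform(2, min(55, config.prompt_window_sec)))
                    items = _make_items(
                        latent, kind, smoked_since(last_epoch_at, at) and postquit_now,
                        config, params, rng,
                    )
                    dur = _duration_min(kind, prequit_day, rng)
                    events.append(
                        EmaRecord(
                            participant_id=participant.id,
                            kind=kind,
                            origin=EmaOrigin.prompted,
                            scheduled_at=at,
                            presented_at=at,
                            completed_at=at + timedelta(minutes=dur),
                            response_latency_sec=latency,
                            status=EmaStatus.completed,
                            items=items,
                        )
                    )
                else:
                    events.append(
                        EmaRecord(
                            participant_id=participant.id,
                            kind=kind,
                            origin=EmaOrigin.prompted,
                            scheduled_at=at,
                            presented_at=at,
                            status=EmaStatus.missed,
                        )
                    )

            elif source == "press":
                res = register_precig_event(participant, at, state, config, rng)
                if not res["sampled"]:
                    continue
                items = _make_items(latent, EmaKind.precig, True, config, params, rng)
                dur = _duration_min(EmaKind.precig, True, rng)
                completed_at = at + timedelta(minutes=dur)
                events.append(
                    EmaRecord(
                        participant_id=participant.id,
                        kind=EmaKind.precig,
                        origin=EmaOrigin.self_initiated,
                        presented_at=at,
                        completed_at=completed_at,
                        status=EmaStatus.completed,
                        items=items,
                    )
                )
                # post-cigarette follow-up 15 min after the precig completes
                due = completed_at + timedelta(minutes=config.postcig_delay_min)
                latent.step(rng)
                if rng.random() < params.p_respond:
                    items2 = _make_items(latent, EmaKind.postcig, True, config, params, rng)
                    events.append(
                        EmaRecord(
                            participant_id=participant.id,
                            kind=EmaKind.postcig,
                            origin=EmaOrigin.system_followup,
                            scheduled_at=due,
                            presented_at=due,
                            completed_at=due + timedelta(
                                minutes=_duration_min(EmaKind.postcig, True, rng)
                            ),
                            response_latency_sec=float(rng.uniform(2, 55)),
                            status=EmaStatus.completed,
                            items=items2,
                        )
                    )
                else:
                    events.append(
                        EmaRecord(
                            participant_id=participant.id,
                            kind=EmaKind.postcig,
                            origin=EmaOrigin.system_followup,
                            scheduled_at=due,
                            presented_at=due,
                            status=EmaStatus.missed,
                        )
                    )

            else:  # postquit slip-button event
                unreported = smoked_since(last_epoch_at, at)
                if unreported and rng.random() < 0.7:
                    ev_kind = EmaKind.already_slipped
                elif rng.random() < 0.7:
                    ev_kind = EmaKind.urge
                else:
                    ev_kind = EmaKind.about_to_slip
                res = register_slip_event(ev_kind, at, state, config)
                still = (
                    bool(rng.random() < params.p_still_interested)
                    if ev_kind is EmaKind.already_slipped
                    else None
                )
                items = _make_items(
                    latent, ev_kind, ev_kind is EmaKind.already_slipped, config, params,
                    rng, still_interested=still,
                )
                events.append(
                    EmaRecord(
                        participant_id=participant.id,
                        kind=ev_kind,
                        origin=EmaOrigin.self_initiated,
                        presented_at=at,
                        completed_at=at + timedelta(
                            minutes=_duration_min(ev_kind, False, rng)
                        ),
                        status=EmaStatus.completed,
                        items=items,
                    )
                )
                if res["followup_due"] is not None:
                    due = res["followup_due"]
                    latent.step(rng)
                    smoked = draw_lapse(due)
                    if rng.random() < params.p_respond:
                        items2 = _make_items(
                            latent, EmaKind.slip_followup, smoked, config, params, rng,
                            still_interested=bool(rng.random() < params.p_still_interested)
                            if smoked else None,
                        )
                        events.append(
                            EmaRecord(
                                participant_id=participant.id,
                                kind=EmaKind.slip_followup,
                                origin=EmaOrigin.system_followup,
                                scheduled_at=due,
                                presented_at=due,
                                completed_at=due + timedelta(
                                    minutes=_duration_min(EmaKind.slip_followup, False, rng)
                                ),
                                response_latency_sec=float(rng.uniform(2, 55)),
                                status=EmaStatus.completed,
                                items=items2,
                            )
                        )
                    else:
                        events.append(
                            EmaRecord(
                                participant_id=participant.id,
                                kind=EmaKind.slip_followup,
                                origin=EmaOrigin.system_followup,
                                scheduled_at=due,
                                presented_at=due,
                                status=EmaStatus.missed,
                            )
                        )
            last_epoch_at = at

    events.extend(_on_demand_events(participant, params, config, rng))
    visits, prescriptions = _visits(participant, params, config, lapse_times, rng)
    return events, visits, epoch_rows, prescriptions


def _on_demand_events(
    participant: Participant,
    params: BehaviorParams,
    config: StudyConfig,
    rng: np.random.Generator,
) -> list[OnDemandEvent]:
    out: list[OnDemandEvent] = []
    start = config.enrollment_datetime
    span_sec = config.total_days * 86400.0

    def times(n: int) -> list[datetime]:
        return [start + timedelta(seconds=float(rng.uniform(0, span_sec))) for _ in range(n)]

    qt_weights = np.array([0.18, 0.12, 0.30, 0.18, 0.22])  # coping_urges most used
    if rng.random() < params.p_use_quit_tips:
        n = 1 + int(rng.poisson(params.quit_tips_accesses_mean))
        cats = rng.choice(len(QUIT_TIP_CATEGORIES), size=n, p=qt_weights / qt_weights.sum())
        for t, ci in zip(times(n), cats):
            tips = int(max(1, round(rng.lognormal(math.log(params.quit_tips_intensity_median), 0.8))))
            out.append(OnDemandEvent(participant_id=participant.id, at=t,
                                     kind=OnDemandKind.quit_tips,
                                     category=QUIT_TIP_CATEGORIES[ci], n_tips_viewed=tips))
    if rng.random() < params.p_use_med_tips:
        n = 1 + int(rng.poisson(params.med_tips_accesses_mean))
        cats = rng.choice(len(MEDICATION_CATEGORIES), size=n)
        for t, ci in zip(times(n), cats):
            tips = int(max(1, round(rng.lognormal(math.log(params.med_tips_intensity_median), 0.8))))
            out.append(OnDemandEvent(participant_id=participant.id, at=t,
                                     kind=OnDemandKind.medication_tips,
                                     category=MEDICATION_CATEGORIES[ci], n_tips_viewed=tips))
    if rng.random() < params.p_phone_counselor:
        for t in times(1 + int(rng.poisson(0.4))):
            out.append(OnDemandEvent(participant_id=participant.id, at=t,
                                     kind=OnDemandKind.phone_counselor))
    return out


def _visits(
    participant: Participant,
    params: BehaviorParams,
    config: StudyConfig,
    lapse_times: list[datetime],
    rng: np.random.Generator,
):
    visits: list[VisitRecord] = []
    quit = config.quit_datetime

    def abstinent_window(lo: datetime, hi: datetime) -> bool:
        return not any(lo <= lt <= hi for lt in lapse_times)

    visit_dt = {v: quit + timedelta(days=off, hours=10) for v, off in _VISIT_OFFSETS_DAYS.items()}
    truth: dict[VisitKind, bool] = {}
    truth[VisitKind.quit_date] = abstinent_window(quit, visit_dt[VisitKind.quit_date])
    truth[VisitKind.wk1] = abstinent_window(visit_dt[VisitKind.wk1] - timedelta(days=7),
                                            visit_dt[VisitKind.wk1])
    truth[VisitKind.wk2] = abstinent_window(visit_dt[VisitKind.wk2] - timedelta(days=7),
                                            visit_dt[VisitKind.wk2])
    # beyond the EMA window: weekly Markov carry-forward (stand-in dynamics)
    def carry(prev: bool) -> bool:
        p = params.abstinence_persistence if prev else params.recycle_prob
        return bool(rng.random() < p)

    truth[VisitKind.wk3] = carry(truth[VisitKind.wk2])
    truth[VisitKind.wk4] = carry(truth[VisitKind.wk3])
    state = truth[VisitKind.wk4]
    for _ in range(8):
        state = carry(state)
    truth[VisitKind.wk12] = state

    for visit in VisitKind:
        attended = bool(rng.random() < params.visit_attendance[visit.value])
        if not attended:
            visits.append(VisitRecord(participant_id=participant.id, visit=visit,
                                      attended=False))
            continue
        abst = truth[visit]
        if abst:
            co = _truncnorm(rng, params.co_abstinent_mean, params.co_abstinent_sd, 0.0)
        else:
            co = _truncnorm(rng, params.co_smoker_mean, params.co_smoker_sd, 1.0)
        visits.append(
            VisitRecord(participant_id=participant.id, visit=visit, attended=True,
                        self_report_abstinent=abst, co_ppm=round(co, 1))
        )

    meds = [m for m in MEDICATION_CATEGORIES if rng.random() < 0.4]
    return visits, set(meds)


@dataclass
class CohortDataset:
    """Simulated cohort with the ground truth attached for recovery tests."""

    events: list[Event]
    visits: list[VisitRecord]
    epochs: pd.DataFrame
    participants: dict[str, Participant]
    prescriptions: dict[str, set[str]]
    params: BehaviorParams
    config: StudyConfig


def simulate_participant(
    params: BehaviorParams,
    config: StudyConfig,
    seed: int,
    participant: Optional[Participant] = None,
):
    """Simulate one participant's 21-day event log and visit rows.

    Fully reproducible: the same (params, config, seed) yields byte-identical
    output.
    """
    rng = np.random.default_rng(seed)
    if participant is None:
        participant = make_participant(0, config, rng)
    events, visits, epoch_rows, _ = _simulate_one(participant, params, config, rng)
    return sort_events(events), visits


def simulate_cohort(params: BehaviorParams, config: StudyConfig) -> CohortDataset:
    """Simulate a full cohort with independent per-participant substreams."""
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_participants + 1)
    meta_rng = np.random.default_rng(children[0])
    all_events: list[Event] = []
    all_visits: list[VisitRecord] = []
    all_epochs: list[dict] = []
    participants: dict[str, Participant] = {}
    prescriptions: dict[str, set[str]] = {}
    for i in range(params.n_participants):
        rng = np.random.default_rng(children[i + 1])
        participant = make_participant(i + 1, config, meta_rng)
        participants[participant.id] = participant
        events, visits, epoch_rows, meds = _simulate_one(participant, params, config, rng)
        all_events.extend(events)
        all_visits.extend(visits)
        all_epochs.extend(epoch_rows)
        prescriptions[participant.id] = meds
    epochs = pd.DataFrame(
        all_epochs,
        columns=["participant_id", "at", "urge", "negative_affect_stress",
                 "cigarette_availability", "motivation_deficit", "lapse"],
    )
    return CohortDataset(
        events=sort_events(all_events),
        visits=all_visits,
        epochs=epochs,
        participants=participants,
        prescriptions=prescriptions,
        params=params,
        config=config,
    )


@dataclass
class RecoveryResult:
    p_respond_hat: float
    p_respond_se: float
    p_respond_true: float
    n_prompted: int
    hazard_coefs_hat: Optional[dict[str, float]]
    hazard_coefs_se: Optional[dict[str, float]]
    hazard_coefs_true: dict[str, float]
    n_lapses: int
    degenerate: bool


_HAZARD_COLS = ["urge", "negative_affect_stress", "cigarette_availability",
                "motivation_deficit"]


def recover_parameters(dataset: CohortDataset) -> RecoveryResult:
    """Recover the generative parameters from a simulated cohort.

    Prompt adherence is estimated as completed/prompted over prompted-origin
    EMAs (binomial SE); the lapse-hazard coefficients by logistic-regression
    maximum likelihood on the per-epoch (latent covariates, lapse) draws.
    With no observed lapses the coefficient recovery is flagged degenerate
    and skipped.
    """
    import statsmodels.api as sm

    prompted = [e for e in dataset.events
                if isinstance(e, EmaRecord) and e.origin is EmaOrigin.prompted]
    n = len(prompted)
    completed = sum(1 for e in prompted if e.status is EmaStatus.completed)
    p_hat = completed / n if n else float("nan")
    se = math.sqrt(p_hat * (1.0 - p_hat) / n) if n else float("nan")

    epochs = dataset.epochs
    n_lapses = int(epochs["lapse"].sum()) if len(epochs) else 0
    coefs = ses = None
    degenerate = n_lapses == 0 or len(epochs) == 0
    if not degenerate:
        X = sm.add_constant(epochs[_HAZARD_COLS].astype(float))
        fit = sm.Logit(epochs["lapse"].astype(float), X).fit(disp=0)
        coefs = {"intercept": float(fit.params["const"]),
                 **{c: float(fit.params[c]) for c in _HAZARD_COLS}}
        ses = {"intercept": float(fit.bse["const"]),
               **{c: float(fit.bse[c]) for c in _HAZARD_COLS}}
    return RecoveryResult(
        p_respond_hat=p_hat,
        p_respond_se=se,
        p_respond_true=dataset.params.p_respond,
        n_prompted=n,
        hazard_coefs_hat=coefs,
        hazard_coefs_se=ses,
        hazard_coefs_true={"intercept": dataset.params.hazard_intercept,
                           **dataset.params.hazard_coefs},
        n_lapses=n_lapses,
        degenerate=degenerate,
    )
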