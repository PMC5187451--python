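"""Feasibility metrics: compliance, compensation, feature use, abstinence.

All reports are deterministic functions of their inputs and are exposed as
tidy pandas DataFrames suitable for external modeling; regression modeling
and hypothesis testing are out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import EventLogError
from .eventlog import Event
from .types import (
    EmaOrigin,
    EmaRecord,
    EmaStatus,
    MessageEvent,
    OnDemandEvent,
    OnDemandKind,
    VisitKind,
    VisitRecord,
)

__all__ = ["ComplianceReport", "FeatureUseReport", "AbstinenceReport",
           "compute_compensation", "compliance_report", "feature_use_report",
           "classify_abstinence", "abstinence_report"]

logger = logging.getLogger(__name__)


def compute_compensation(completed: int, prompted: int, config: StudyConfig) -> float:
    """USD gift-card amount for a completion fraction, by protocol tier.

    Default tiers: below 50% → $0, 50–74% → $40, 75–89% → $80, 90% or
    more → $120. Boundaries are half-open on the real-valued fraction, so
    every fraction maps to exactly one tier and the amount is monotone
    nondecreasing in the fraction.
    """
    if prompted <= 0:
        raise ValueError("prompted must be positive to compute a completion fraction")
    if not 0 <= completed <= prompted:
        raise ValueError("completed must lie in [0, prompted]")
    f = completed / prompted
    amount = 0.0
    for bound, usd in config.compensation_tiers:
        if f >= bound:
            amount = usd
    return amount


@dataclass
class ComplianceReport:
    """Prompt adherence: per-kind counts/rates over system-cued EMAs, mean
    completion minutes, per-participant completion fractions, and mean
    delivered messages per participant (when messages are in the log)."""

    by_kind: pd.DataFrame  # kind, origin_scope, prompted, completed, rate, mean_completion_min
    per_participant: pd.DataFrame  # participant_id, prompted, completed, fraction
    overall_rate: Optional[float]
    self_initiated_per_participant: Optional[float]
    mean_messages_per_participant: Optional[float]


def compliance_report(log: Iterable[Event]) -> ComplianceReport:
    """Compute prompt adherence from an event log.

    Prompted-only rates use records with prompted origin; a second set of
    rows (``origin_scope="all_cued"``) also counts system follow-ups, since
    published completion denominators do not always say which was used.
    Self-initiated records are tallied separately (they are completed by
    construction and are not compensated).
    """
    events = list(log)
    emas = [e for e in events if isinstance(e, EmaRecord)]
    messages = [e for e in events if isinstance(e, MessageEvent)]
    if not events:
        logger.warning("compliance_report: empty event log")

    def rows_for(scope: str, keep: set[EmaOrigin]) -> list[dict]:
        pool = [e for e in emas if e.origin in keep]
        rows = []
        kinds = sorted({e.kind.value for e in pool})
        for kind in kinds + ["overall"]:
            sub = pool if kind == "overall" else [e for e in pool if e.kind.value == kind]
            prompted = len(sub)
            done = [e for e in sub if e.status is EmaStatus.completed]
            mins = [e.completion_minutes for e in done if e.completion_minutes is not None]
            rows.append(
                {
                    "kind": kind,
                    "origin_scope": scope,
                    "prompted": prompted,
                    "completed": len(done),
                    "rate": len(done) / prompted if prompted else None,
                    "mean_completion_min": float(np.mean(mins)) if mins else None,
                }
            )
        return rows

    by_kind = pd.DataFrame(
        rows_for("prompted", {EmaOrigin.prompted})
        + rows_for("all_cued", {EmaOrigin.prompted, EmaOrigin.system_followup}),
        columns=["kind", "origin_scope", "prompted", "completed", "rate",
                 "mean_completion_min"],
    )

    prompted_only = [e for e in emas if e.origin is EmaOrigin.prompted]
    pids = sorted({e.participant_id for e in emas})
    pp_rows = []
    for pid in pids:
        sub = [e for e in prompted_only if e.participant_id == pid]
        done = sum(1 for e in sub if e.status is EmaStatus.completed)
        pp_rows.append(
            {"participant_id": pid, "prompted": len(sub), "completed": done,
             "fraction": done / len(sub) if sub else None}
        )
    per_participant = pd.DataFrame(
        pp_rows, columns=["participant_id", "prompted", "completed", "fraction"]
    )

    n_prompted = len(prompted_only)
    overall = (
        sum(1 for e in prompted_only if e.status is EmaStatus.completed) / n_prompted
        if n_prompted
        else None
    )
    n_participants = len(pids)
    self_init = (
        sum(1 for e in emas if e.origin is EmaOrigin.self_initiated) / n_participants
        if n_participants
        else None
    )
    mean_msgs = len(messages) / n_participants if (messages and n_participants) else None
    return ComplianceReport(
        by_kind=by_kind,
        per_participant=per_participant,
        overall_rate=overall,
        self_initiated_per_participant=self_init,
        mean_messages_per_participant=mean_msgs,
    )


@dataclass
class FeatureUseReport:
    """On-demand feature use: access frequency per participant and tips
    viewed per occasion (intensity), overall and per category, plus counts
    of viewers not prescribed each medication when prescriptions are known."""

    table: pd.DataFrame  # feature, category, n_users, freq stats, intensity stats
    not_prescribed: Optional[pd.DataFrame]  # medication, viewers_not_prescribed


def feature_use_report(
    log: Iterable[Event],
    prescriptions: Optional[dict[str, set[str]]] = None,
) -> FeatureUseReport:
    events = [e for e in log if isinstance(e, OnDemandEvent)]
    rows = []

    def stats(feature: str, category: Optional[str], pool: list[OnDemandEvent]) -> dict:
        users = sorted({e.participant_id for e in pool})
        freq = [sum(1 for e in pool if e.participant_id == pid) for pid in users]
        intensity = [e.n_tips_viewed for e in pool if e.n_tips_viewed is not None]
        return {
            "feature": feature,
            "category": category or "all",
            "n_users": len(users),
            "accesses_mean": float(np.mean(freq)) if freq else 0.0,
            "accesses_sd": float(np.std(freq, ddof=1)) if len(freq) > 1 else 0.0,
            "accesses_median": float(np.median(freq)) if freq else 0.0,
            "intensity_mean": float(np.mean(intensity)) if intensity else 0.0,
            "intensity_sd": float(np.std(intensity, ddof=1)) if len(intensity) > 1 else 0.0,
            "intensity_median": float(np.median(intensity)) if intensity else 0.0,
        }

    for kind in (OnDemandKind.quit_tips, OnDemandKind.medication_tips):
        pool = [e for e in events if e.kind is kind]
        rows.append(stats(kind.value, None, pool))
        for cat in sorted({e.category for e in pool if e.category}):
            rows.append(stats(kind.value, cat, [e for e in pool if e.category == cat]))
    for kind in (OnDemandKind.phone_counselor, OnDemandKind.call_staff,
                 OnDemandKind.payment_view):
        rows.append(stats(kind.value, None, [e for e in events if e.kind is kind]))

    table = pd.DataFrame(
        rows,
        columns=["feature", "category", "n_users", "accesses_mean", "accesses_sd",
                 "accesses_median", "intensity_mean", "intensity_sd",
                 "intensity_median"],
    )

    not_prescribed = None
    if prescriptions is not None:
        med_events = [e for e in events if e.kind is OnDemandKind.medication_tips]
        np_rows = []
        for med in sorted({e.category for e in med_events if e.category}):
            viewers = {e.participant_id for e in med_events if e.category == med}
            n_not = sum(1 for pid in viewers if med not in prescriptions.get(pid, set()))
            np_rows.append({"medication": med, "viewers": len(viewers),
                            "viewers_not_prescribed": n_not})
        not_prescribed = pd.DataFrame(
            np_rows, columns=["medication", "viewers", "viewers_not_prescribed"]
        )
    return FeatureUseReport(table=table, not_prescribed=not_prescribed)


def classify_abstinence(visit: VisitRecord, config: StudyConfig) -> bool:
    """Biochemically verified point-prevalence abstinence for one visit.

    Abstinent iff the participant attended, self-reported no smoking over
    the visit's 7-day window, and the expired-CO reading fell strictly below
    the cutoff (the quit-date visit uses the higher quit-date cutoff). A
    missed visit is nonabstinent.
    """
    if not visit.attended:
        return False
    if visit.co_ppm is None:
        raise EventLogError(
            f"{visit.participant_id}/{visit.visit.value}: attended visit lacks a CO "
            "reading; biochemical verification is required"
        )
    if visit.self_report_abstinent is None:
        raise EventLogError(
            f"{visit.participant_id}/{visit.visit.value}: attended visit lacks a "
            "self-report"
        )
    cutoff = (
        config.co_cutoff_quitdate_ppm
        if visit.visit is VisitKind.quit_date
        else config.co_cutoff_followup_ppm
    )
    return bool(visit.self_report_abstinent) and visit.co_ppm < cutoff


@dataclass
class AbstinenceReport:
    by_visit: pd.DataFrame  # visit, n_abstinent, n_enrolled, proportion
    per_participant: pd.DataFrame  # participant_id × visit boolean matrix
    n_enrolled: int


def abstinence_report(
    visits: Iterable[VisitRecord],
    config: StudyConfig,
    n_enrolled: Optional[int] = None,
) -> AbstinenceReport:
    """Point-prevalence abstinence per visit over ALL enrolled participants.

    The denominator is the cohort size (every enrolled participant), not the
    attendees: nonattendance counts as nonabstinent. Duplicate
    participant-visit rows are an error.
    """
    visits = list(visits)
    seen: set[tuple[str, str]] = set()
    for v in visits:
        key = (v.participant_id, v.visit.value)
        if key in seen:
            raise EventLogError(f"duplicate visit row for {key}")
        seen.add(key)
    pids = sorted({v.participant_id for v in visits})
    if n_enrolled is None:
        n_enrolled = len(pids)
    flags = {pid: {vk.value: False for vk in VisitKind} for pid in pids}
    for v in visits:
        flags[v.participant_id][v.visit.value] = classify_abstinence(v, config)
    per_participant = pd.DataFrame.from_dict(flags, orient="index").rename_axis(
        "participant_id"
    )
    rows = []
    for vk in VisitKind:
        n_abst = int(per_participant[vk.value].sum()) if len(per_participant) else 0
        rows.append(
            {"visit": vk.value, "n_abstinent": n_abst, "n_enrolled": n_enrolled,
             "proportion": n_abst / n_enrolled if n_enrolled else math.nan}
        )
    return AbstinenceReport(
        by_visit=pd.DataFrame(rows, columns=["visit", "n_abstinent", "n_enrolled",
                                             "proportion"]),
        per_participant=per_participant,
        n_enrolled=n_enrolled,
    )
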