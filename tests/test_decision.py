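"""Message-level classification, trigger tailoring, and message selection."""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartquit import (
    ContextFeatures,
    EmaKind,
    EmaOrigin,
    EmaRecord,
    EmaStatus,
    ItemResponses,
    MessageLevel,
    MessageSelector,
    OnDemandKind,
    Phase,
    RiskEstimatorSpec,
    StudyConfig,
    Trigger,
    classify_level,
    countdown_message,
    estimate_lapse_risk,
    record_on_demand,
    run_engine,
    select_trigger,
)
from smartquit.errors import PeriodError


class TestRiskEstimator:
    def test_all_zero_items_are_low_risk(self):
        spec = RiskEstimatorSpec()
        assert spec.threshold > 0
        items = ItemResponses(urge=0, negative_affect_stress=0,
                              cigarette_availability=0, motivation_to_quit=10)
        out = estimate_lapse_risk(items, spec)
        assert out["score"] == 0.0
        assert out["high_risk"] is False

    def test_extreme_items_are_high_risk(self):
        # expected score under the default spec, computed by hand:
        # 0.3*10 + 0.3*10 + 0.2*10 + 0.2*(10-0) + 1.0*0 = 10 > 4
        items = ItemResponses(urge=10, negative_affect_stress=10,
                              cigarette_availability=10, motivation_to_quit=0)
        out = estimate_lapse_risk(items, RiskEstimatorSpec())
        assert out["score"] == pytest.approx(10.0)
        assert out["high_risk"] is True

    def test_deterministic(self):
        items = ItemResponses(urge=4, negative_affect_stress=7,
                              cigarette_availability=2, motivation_to_quit=5)
        spec = RiskEstimatorSpec()
        assert estimate_lapse_risk(items, spec) == estimate_lapse_risk(items, spec)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(urge=st.integers(0, 9), stress=st.integers(0, 10))
    def test_monotone_in_urge_and_stress(self, urge, stress):
        spec = RiskEstimatorSpec()
        base = estimate_lapse_risk(
            ItemResponses(urge=urge, negative_affect_stress=stress), spec
        )["score"]
        up = estimate_lapse_risk(
            ItemResponses(urge=urge + 1, negative_affect_stress=stress), spec
        )["score"]
        assert up >= base

    def test_unknown_weight_item_is_config_error(self):
        with pytest.raises(ValueError, match="unknown items"):
            RiskEstimatorSpec(weights={"shoe_size": 1.0})


def oracle_level(phase, lapsed_uninterested, new_lapse, high_risk, smoked,
                 diary_over, slip_kind):
    """Independently coded truth table for the level precedence."""
    if phase == "prequit":
        return "L0"
    if lapsed_uninterested:
        return "L0"
    if new_lapse:
        return "L3"
    if high_risk or smoked or diary_over or slip_kind:
        return "L2"
    return "L1"


class TestClassifyLevel:
    def test_matches_truth_table_exhaustively(self, config):
        """Exhaustive enumeration of phase x risk-condition x lapse-flag
        combinations against the brute-force oracle."""
        items = ItemResponses()  # low everything; high_risk supplied explicitly
        for (lapsed_uninterested, new_lapse, high_risk, smoked, diary_over,
             slip) in itertools.product([False, True], repeat=6):
            # prequit forbids the postquit-only flags
            if not (lapsed_uninterested or new_lapse or smoked):
                ctx = ContextFeatures(
                    phase=Phase.prequit,
                    ema_kind=EmaKind.random,
                    items=items,
                    high_risk=high_risk,
                )
                assert classify_level(ctx, config).value == "L0"
            ctx = ContextFeatures(
                phase=Phase.postquit,
                ema_kind=EmaKind.urge if slip else EmaKind.random,
                items=items,
                smoked_today_or_yesterday=smoked,
                diary_likelihood_today_pct=30.0 if diary_over else 10.0,
                lapsed_and_uninterested=lapsed_uninterested,
                new_lapse_event=new_lapse,
                high_risk=high_risk,
            )
            expected = oracle_level("postquit", lapsed_uninterested, new_lapse,
                                    high_risk, smoked, diary_over, slip)
            assert classify_level(ctx, config).value == expected, (
                lapsed_uninterested, new_lapse, high_risk, smoked, diary_over, slip)

    def test_diary_threshold_strictly_above_25(self, config):
        items = ItemResponses(motivation_to_quit=10)
        for pct, expected in [(25, MessageLevel.L1), (26, MessageLevel.L2)]:
            ctx = ContextFeatures(
                phase=Phase.postquit, ema_kind=EmaKind.daily_diary, items=items,
                diary_likelihood_today_pct=float(pct), high_risk=False,
            )
            assert classify_level(ctx, config) is expected

    def test_prequit_context_rejects_postquit_flags(self):
        with pytest.raises(ValueError, match="postquit-only"):
            ContextFeatures(
                phase=Phase.prequit, ema_kind=EmaKind.random,
                items=ItemResponses(), new_lapse_event=True,
            )


def oracle_trigger(stress, urge, avail, mot_deficit):
    best = max(stress, urge, avail, mot_deficit)
    for name, v in [("stress_affect", stress), ("urge", urge),
                    ("availability", avail), ("motivation", mot_deficit)]:
        if v == best:
            return name


class TestSelectTrigger:
    def test_matches_argmax_priority_on_full_grid(self):
        grid = range(0, 11, 2)
        for s, u, a, m in itertools.product(grid, repeat=4):
            items = ItemResponses(
                negative_affect_stress=s, urge=u, cigarette_availability=a,
                motivation_to_quit=10 - m,
            )
            assert select_trigger(items).value == oracle_trigger(s, u, a, m)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(s=st.integers(0, 10), u=st.integers(0, 10), a=st.integers(0, 10),
           m=st.integers(0, 10))
    def test_total_over_intensity_grid(self, s, u, a, m):
        items = ItemResponses(negative_affect_stress=s, urge=u,
                              cigarette_availability=a, motivation_to_quit=10 - m)
        assert select_trigger(items).value == oracle_trigger(s, u, a, m)

    def test_tie_prefers_stress_affect(self):
        items = ItemResponses(negative_affect_stress=4, urge=4,
                              cigarette_availability=1, motivation_to_quit=10)
        assert select_trigger(items) is Trigger.stress_affect

    def test_all_equal_goes_to_first_priority(self):
        items = ItemResponses(negative_affect_stress=5, urge=5,
                              cigarette_availability=5, motivation_to_quit=5)
        assert select_trigger(items) is Trigger.stress_affect

    def test_unique_max_wins(self):
        items = ItemResponses(urge=9, negative_affect_stress=5,
                              cigarette_availability=3, motivation_to_quit=6)
        assert select_trigger(items) is Trigger.urge


class TestMessageSelector:
    def test_prequit_messages_follow_bank_order(self, bank):
        sel = MessageSelector(bank)
        expected = [mid for mid, _ in bank.slot(MessageLevel.L0)][:7]
        got = [sel.next_message(MessageLevel.L0)[0] for _ in range(7)]
        assert got == expected

    def test_no_immediate_repeat_with_multiple_entries(self, bank):
        sel = MessageSelector(bank)
        ids = [sel.next_message(MessageLevel.L2, Trigger.urge)[0] for _ in range(4)]
        assert all(a != b for a, b in zip(ids, ids[1:]))

    def test_single_entry_slot_repeats(self):
        from smartquit.bank import MessageBank

        bank = MessageBank({("L1", ""): [("only", "text")]})
        sel = MessageSelector(bank)
        assert [sel.next_message(MessageLevel.L1)[0] for _ in range(3)] == ["only"] * 3


class TestCountdown:
    def test_five_days_out(self, config):
        text = countdown_message(config.quit_datetime - timedelta(days=5),
                                 config.quit_datetime)
        assert "5 DAYS" in text

    def test_singular_day(self, config):
        text = countdown_message(config.quit_datetime - timedelta(days=1),
                                 config.quit_datetime)
        assert "1 DAY" in text and "1 DAYS" not in text

    def test_postquit_call_is_an_error(self, config):
        with pytest.raises(PeriodError):
            countdown_message(config.quit_datetime, config.quit_datetime)


class TestOnDemand:
    def test_quit_tips_access_logged_with_intensity(self, bank):
        ev = record_on_demand(OnDemandKind.quit_tips, datetime(2023, 1, 10, 12),
                              "P1", category="coping_urges", n_tips_viewed=16,
                              bank=bank)
        assert ev.n_tips_viewed == 16 and ev.category == "coping_urges"

    def test_medication_tips_gum(self, bank):
        ev = record_on_demand(OnDemandKind.medication_tips, datetime(2023, 1, 10, 12),
                              "P1", category="gum", n_tips_viewed=4, bank=bank)
        assert ev.n_tips_viewed == 4

    def test_phone_counselor_is_a_stub(self):
        ev = record_on_demand(OnDemandKind.phone_counselor, datetime(2023, 1, 10, 12), "P1")
        assert ev.category is None and ev.n_tips_viewed is None

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            record_on_demand(OnDemandKind.quit_tips, datetime(2023, 1, 10, 12),
                             "P1", category="astrology")


def _completed(pid, kind, at, config, origin=EmaOrigin.prompted, **item_kw):
    return EmaRecord(
        participant_id=pid, kind=kind, origin=origin,
        scheduled_at=at if origin is not EmaOrigin.self_initiated else None,
        presented_at=at, completed_at=at + timedelta(minutes=3),
        response_latency_sec=10.0 if origin is not EmaOrigin.self_initiated else None,
        status=EmaStatus.completed, items=ItemResponses(**item_kw),
    )


class TestEngineReplay:
    def test_scenario_levels_and_one_message_per_completed_ema(self, bank, config):
        """A hand-built participant history walks through every level."""
        quit = config.quit_datetime
        low = dict(urge=1, negative_affect_stress=1, cigarette_availability=0,
                   motivation_to_quit=10)
        events = [
            # prequit -> L0 regardless of answers
            _completed("P1", EmaKind.random, quit - timedelta(days=3), config,
                       urge=9, negative_affect_stress=9),
            # postquit, everything low -> L1
            _completed("P1", EmaKind.random, quit + timedelta(days=1, hours=10),
                       config, **low),
            # diary forecasting 30% chance of smoking -> L2
            _completed("P1", EmaKind.daily_diary, quit + timedelta(days=2, hours=8),
                       config, diary_smoking_likelihood_pct=30, **low),
            # first report of a lapse -> L3
            _completed("P1", EmaKind.already_slipped,
                       quit + timedelta(days=5, hours=12), config,
                       origin=EmaOrigin.self_initiated, smoked_since_last=True,
                       still_interested_in_quitting=True),
            # next EMA the same day: smoked today -> L2
            _completed("P1", EmaKind.random, quit + timedelta(days=5, hours=16),
                       config, **low),
            # lapsed and no longer interested -> L0
            _completed("P1", EmaKind.already_slipped,
                       quit + timedelta(days=8, hours=12), config,
                       origin=EmaOrigin.self_initiated, smoked_since_last=True,
                       still_interested_in_quitting=False),
            _completed("P1", EmaKind.random, quit + timedelta(days=8, hours=15),
                       config, **low),
        ]
        messages = run_engine(events, bank, config)
        assert len(messages) == len(events)  # one per completed EMA
        levels = [m.level.value for m in messages]
        # the final slip report states no further interest in quitting, so it
        # and everything after it drop to the untailored L0 stream
        assert levels == ["L0", "L1", "L2", "L3", "L2", "L0", "L0"]
        # trigger set iff L2
        for m in messages:
            assert (m.trigger is not Trigger.none) == (m.level is MessageLevel.L2)

    def test_missed_prompts_get_no_message(self, bank, config):
        quit = config.quit_datetime
        events = [
            _completed("P1", EmaKind.random, quit + timedelta(days=1, hours=10), config),
            EmaRecord(participant_id="P1", kind=EmaKind.random,
                      origin=EmaOrigin.prompted,
                      scheduled_at=quit + timedelta(days=1, hours=13),
                      presented_at=quit + timedelta(days=1, hours=13),
                      status=EmaStatus.missed),
        ]
        assert len(run_engine(events, bank, config)) == 1

    def test_prequit_purity_on_simulated_cohort(self, cohort59_messages, config):
        """No tailored (L1/L2/L3) message ever carries a prequit timestamp."""
        for m in cohort59_messages:
            if m.at < config.quit_datetime:
                assert m.level is MessageLevel.L0

    def test_one_message_per_completed_ema_on_simulated_cohort(
        self, cohort59, cohort59_messages
    ):
        n_completed = sum(
            1 for e in cohort59.events
            if isinstance(e, EmaRecord) and e.status is EmaStatus.completed
        )
        assert len(cohort59_messages) == n_completed
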