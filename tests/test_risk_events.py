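"""Transition classification, detection, and hygiene adherence attribution."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from handseq.event_model import Hand, HygieneKind, SurfaceType
from handseq.risk_events import (
    AdherencePolicy,
    AdherenceSummary,
    DetectionConfig,
    InfectionOriginExclusion,
    RiskKind,
    adherence_summary,
    attach_hygiene,
    classify_transition,
    detect_risk_events,
    hand_stream,
)
from conftest import brute_force_risk_events, hse, rub, session_of, quick_session

L, R = Hand.LEFT, Hand.RIGHT
OUT_MOB = SurfaceType.MOBILE_OBJECT_OUTSIDE
IN_MOB = SurfaceType.MOBILE_OBJECT_INSIDE
SKIN = SurfaceType.PATIENT_INTACT_SKIN
CVC = SurfaceType.INVASIVE_DEVICE_ACCESS


class TestHandStream:
    def test_filters_and_orders_by_hand(self):
        events = [
            hse(L, OUT_MOB, 5.0, 6.0),
            hse(R, IN_MOB, 0.0, 1.0),
            hse(L, IN_MOB, 1.0, 2.0),
            hse(L, SKIN, 3.0, 4.0),
        ]
        s = session_of(events)
        left = hand_stream(s, L)
        assert [e.start_s for e in left] == [1.0, 3.0, 5.0]
        assert len(hand_stream(s, R)) == 1

    def test_empty_session_gives_empty_stream(self):
        assert hand_stream(session_of([]), L) == []

    def test_shuffled_input_equals_sorted_input(self):
        evs = [hse(L, OUT_MOB, float(t), float(t) + 0.5) for t in (7, 1, 5, 3)]
        assert hand_stream(session_of(evs), L) == hand_stream(
            session_of(sorted(evs, key=lambda e: e.start_s)), L
        )


class TestClassifyTransition:
    def test_outside_to_inside_is_colonization(self):
        # door handle -> bedside monitor
        o = hse(L, OUT_MOB, 0, 1, site="door handle")
        d = hse(L, IN_MOB, 2, 3, site="bedside monitor")
        assert classify_transition(o, d) is RiskKind.COLONIZATION

    def test_patient_skin_to_device_is_infection(self):
        o = hse(L, SKIN, 0, 1)
        d = hse(L, CVC, 2, 3, site="CVC insertion site")
        assert classify_transition(o, d) is RiskKind.INFECTION

    def test_zone_exit_is_no_event(self):
        assert classify_transition(hse(L, IN_MOB, 0, 1), hse(L, OUT_MOB, 2, 3)) is None

    def test_same_critical_site_excluded_by_default(self):
        o = hse(L, CVC, 0, 1, site="CVC")
        d = hse(L, CVC, 2, 3, site="CVC")
        assert classify_transition(o, d) is None

    def test_different_critical_site_is_infection_under_same_site_only(self):
        o = hse(L, CVC, 0, 1, site="CVC")
        d = hse(L, CVC, 2, 3, site="urinary catheter")
        assert classify_transition(o, d) is RiskKind.INFECTION

    def test_unlabeled_same_leaf_treated_as_same_site(self):
        o = hse(L, CVC, 0, 1)
        d = hse(L, CVC, 2, 3)
        assert classify_transition(o, d) is None

    def test_any_critical_exclusion_drops_cross_site_transitions(self):
        cfg = DetectionConfig(
            infection_origin_exclusion=InfectionOriginExclusion.ANY_CRITICAL_SITE
        )
        o = hse(L, CVC, 0, 1, site="CVC")
        d = hse(L, SurfaceType.WOUND, 2, 3, site="wound")
        assert classify_transition(o, d, cfg) is None
        assert classify_transition(o, d) is RiskKind.INFECTION

    def test_different_hands_is_usage_error(self):
        with pytest.raises(ValueError, match="same hand"):
            classify_transition(hse(L, OUT_MOB, 0, 1), hse(R, IN_MOB, 2, 3))


class TestDetect:
    def test_single_event_session_has_no_pairs(self):
        assert detect_risk_events(session_of([hse(L, IN_MOB, 0, 1)])) == []

    def test_toy_stream_two_colonizations_one_infection(self):
        # L: outside -> inside -> critical -> outside -> inside
        evs = [
            hse(L, OUT_MOB, 0, 1),
            hse(L, IN_MOB, 2, 3),
            hse(L, CVC, 4, 5, site="CVC"),
            hse(L, OUT_MOB, 6, 7),
            hse(L, SKIN, 8, 9),
        ]
        events = detect_risk_events(session_of(evs))
        kinds = [e.kind for e in events]
        assert kinds.count(RiskKind.COLONIZATION) == 2
        assert kinds.count(RiskKind.INFECTION) == 1
        # ordered by destination start
        assert [e.destination.start_s for e in events] == [2.0, 4.0, 8.0]

    def test_events_bounded_by_pair_count(self):
        s = quick_session(3)
        events = detect_risk_events(s)
        n_pairs = sum(max(0, len(hand_stream(s, h)) - 1) for h in Hand)
        assert len(events) <= n_pairs

    def test_per_hand_additivity(self):
        s = quick_session(11)
        events = detect_risk_events(s)
        by_hand = {h: sum(1 for e in events if e.hand is h) for h in Hand}
        assert sum(by_hand.values()) == len(events)

    def test_removing_one_hand_does_not_change_the_other(self):
        s = quick_session(5)
        left_only = session_of(hand_stream(s, L), duration=s.coded_duration_s)
        full_left = [e for e in detect_risk_events(s) if e.hand is L]
        alone = detect_risk_events(left_only)
        assert [(e.kind, e.origin.start_s) for e in alone] == [
            (e.kind, e.origin.start_s) for e in full_left
        ]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_matches_brute_force_oracle(self, seed):
        s = quick_session(seed)
        got = [
            (e.kind.value, e.hand.value, e.origin.start_s, e.destination.start_s)
            for e in detect_risk_events(s)
        ]
        assert sorted(got, key=lambda t: t[3]) == brute_force_risk_events(s)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_any_critical_exclusion_yields_subset_of_infections(self, seed):
        s = quick_session(seed)
        strict = DetectionConfig(
            infection_origin_exclusion=InfectionOriginExclusion.ANY_CRITICAL_SITE
        )
        keys = lambda evs: {
            (e.hand, e.origin.start_s) for e in evs if e.kind is RiskKind.INFECTION
        }
        assert keys(detect_risk_events(s, strict)) <= keys(detect_risk_events(s))


class TestAttachHygiene:
    def _one_event(self):
        evs = [hse(L, OUT_MOB, 0.0, 10.0), hse(L, IN_MOB, 20.0, 25.0)]
        s = session_of(evs)
        return s, detect_risk_events(s)

    def test_no_actions_means_no_adherence(self):
        s, events = self._one_event()
        attach_hygiene(events, [])
        assert all(not e.preceded_by_hygiene for e in events)

    def test_action_inside_gap_counts_under_both_policies(self):
        for policy in AdherencePolicy:
            s, events = self._one_event()
            attach_hygiene(events, [rub(12.0, 18.0)], DetectionConfig(adherence_policy=policy))
            assert events[0].preceded_by_hygiene

    def test_action_straddling_destination_start_depends_on_policy(self):
        s, events = self._one_event()
        straddling = [rub(15.0, 22.0)]  # runs into the destination contact
        attach_hygiene(events, straddling)
        assert not events[0].preceded_by_hygiene  # STRICT_CONTAINMENT default
        attach_hygiene(
            events,
            straddling,
            DetectionConfig(adherence_policy=AdherencePolicy.ANY_OVERLAP_WITH_GAP),
        )
        assert events[0].preceded_by_hygiene

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 40),
        b=st.integers(1, 20),
    )
    def test_interval_logic_truth_table(self, a, b):
        """Brute-force check of both policies on integer endpoints.

        Gap is (10, 20); action is [a, a+b)."""
        s, events = self._one_event()
        action = rub(float(a), float(a + b))
        attach_hygiene(events, [action])
        contained = a >= 10 and a + b <= 20
        assert events[0].preceded_by_hygiene == contained
        attach_hygiene(
            events,
            [action],
            DetectionConfig(adherence_policy=AdherencePolicy.ANY_OVERLAP_WITH_GAP),
        )
        overlaps = a < 20 and a + b > 10
        assert events[0].preceded_by_hygiene == overlaps

    def test_uncounted_hygiene_kind_is_ignored(self):
        s, events = self._one_event()
        cfg = DetectionConfig(hygiene_kinds_counted=frozenset({HygieneKind.HANDWASH}))
        attach_hygiene(events, [rub(12.0, 18.0)], cfg)
        assert not events[0].preceded_by_hygiene

    def test_hygiene_applies_to_both_hands(self):
        evs = [
            hse(L, OUT_MOB, 0.0, 10.0),
            hse(L, IN_MOB, 20.0, 25.0),
            hse(R, OUT_MOB, 0.0, 11.0),
            hse(R, IN_MOB, 21.0, 26.0),
        ]
        events = detect_risk_events(session_of(evs))
        attach_hygiene(events, [rub(12.0, 18.0)])
        assert len(events) == 2 and all(e.preceded_by_hygiene for e in events)

    def test_adding_actions_is_monotone(self):
        s = quick_session(17)
        events = detect_risk_events(s)
        attach_hygiene(events, s.hygiene_actions)
        before = [e.preceded_by_hygiene for e in events]
        attach_hygiene(events, list(s.hygiene_actions) + [rub(0.1, 0.2)])
        after = [e.preceded_by_hygiene for e in events]
        assert all(a >= b for a, b in zip(after, before))

    def test_multiple_qualifying_actions_count_once_last_kept(self):
        s, events = self._one_event()
        first, second = rub(11.0, 13.0), rub(14.0, 16.0)
        attach_hygiene(events, [second, first])
        assert events[0].preceded_by_hygiene
        assert events[0].hygiene_ref is second

    def test_empty_gap_cannot_contain_an_action(self):
        evs = [hse(L, OUT_MOB, 0.0, 10.0), hse(L, IN_MOB, 8.0, 25.0)]  # overlapping pair
        events = detect_risk_events(session_of(evs))
        assert len(events) == 1 and events[0].gap_s < 0
        attach_hygiene(events, [rub(8.5, 9.5)])
        assert not events[0].preceded_by_hygiene


class TestAdherenceSummary:
    def test_campaign_scale_percentage(self):
        a = AdherenceSummary(n_events=291, n_with_hygiene=14)
        assert round(a.adherence_pct, 1) == 4.8

    def test_zero_events_renders_na(self):
        a = AdherenceSummary(n_events=0, n_with_hygiene=0)
        assert a.adherence_pct is None
        assert a.render() == "NA"

    def test_full_adherence_is_100(self):
        assert AdherenceSummary(3, 3).adherence_pct == 100.0

    def test_counts_by_kind(self):
        evs = [
            hse(L, OUT_MOB, 0, 10),
            hse(L, IN_MOB, 20, 25),
            hse(L, CVC, 30, 31, site="cvc"),
        ]
        events = detect_risk_events(session_of(evs))
        attach_hygiene(events, [rub(12.0, 18.0)])
        col = adherence_summary(events, RiskKind.COLONIZATION)
        inf = adherence_summary(events, RiskKind.INFECTION)
        assert (col.n_events, col.n_with_hygiene) == (1, 1)
        assert (inf.n_events, inf.n_with_hygiene) == (1, 0)
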