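"""Sequential analysis of per-hand HSE streams.

Two consecutive contacts of the *same hand* form a transition. Two transition
patterns carry infectious risk for the patient:

* **colonization event** — from any surface outside the patient zone directly
  to a surface inside the patient zone (critical sites excluded as
  destination). A modified WHO "Moment 1" indication: it captures hospital
  flora carried into the patient's immediate environment, not only onto the
  patient.
* **infection event** — from any surface directly to a critical site, unless
  the origin is the *same* critical site (repeated touches of one device are
  not a new risk). WHO "Moment 2".

A hand-hygiene action *covers* a risk event when it is performed in the
inter-contact gap of that hand before the destination contact; the fraction of
covered events is the *adherence*. Detection and adherence attribution never
suppress events — risk events are counted regardless of hygiene.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

from .event_model import (
    CodedSession,
    Hand,
    HSEEvent,
    HygieneAction,
    HygieneKind,
    Zone,
)
from ._util import pct

__all__ = [
    "RiskKind",
    "InfectionOriginExclusion",
    "AdherencePolicy",
    "StreamMode",
    "DetectionConfig",
    "RiskEvent",
    "AdherenceSummary",
    "hand_stream",
    "classify_transition",
    "detect_risk_events",
    "attach_hygiene",
    "adherence_summary",
    "risk_events_to_csv",
]


class RiskKind(str, Enum):
    COLONIZATION = "COLONIZATION"
    INFECTION = "INFECTION"


class InfectionOriginExclusion(str, Enum):
    """Which origins do NOT trigger an infection event at a critical destination.

    SAME_SITE_ONLY excludes only repeated contact with the identical critical
    site; ANY_CRITICAL_SITE excludes every critical-site origin.
    """

    SAME_SITE_ONLY = "SAME_SITE_ONLY"
    ANY_CRITICAL_SITE = "ANY_CRITICAL_SITE"


class AdherencePolicy(str, Enum):
    """How a hygiene action must relate to the inter-contact gap to count.

    STRICT_CONTAINMENT: the action completes inside the gap — a contact begun
    mid-rub is not protected. ANY_OVERLAP_WITH_GAP: any intersection with the
    open gap interval counts.
    """

    STRICT_CONTAINMENT = "STRICT_CONTAINMENT"
    ANY_OVERLAP_WITH_GAP = "ANY_OVERLAP_WITH_GAP"


class StreamMode(str, Enum):
    """PER_HAND analyzes each hand's own chronological stream (default);
    INTERLEAVED analyzes the merged two-hand stream (sensitivity analysis)."""

    PER_HAND = "PER_HAND"
    INTERLEAVED = "INTERLEAVED"


@dataclass(frozen=True)
class DetectionConfig:
    infection_origin_exclusion: InfectionOriginExclusion = InfectionOriginExclusion.SAME_SITE_ONLY
    colonization_destination_excludes_critical: bool = True
    adherence_policy: AdherencePolicy = AdherencePolicy.STRICT_CONTAINMENT
    hygiene_kinds_counted: frozenset[HygieneKind] = frozenset(HygieneKind)
    stream_mode: StreamMode = StreamMode.PER_HAND

    def __post_init__(self) -> None:
        if not self.hygiene_kinds_counted:
            raise ValueError("at least one hygiene kind must be counted")

    @classmethod
    def from_dict(cls, d: Mapping) -> "DetectionConfig":
        kwargs: dict = {}
        if "infection_origin_exclusion" in d:
            kwargs["infection_origin_exclusion"] = InfectionOriginExclusion(
                d["infection_origin_exclusion"]
            )
        if "colonization_destination_excludes_critical" in d:
            kwargs["colonization_destination_excludes_critical"] = bool(
                d["colonization_destination_excludes_critical"]
            )
        if "adherence_policy" in d:
            kwargs["adherence_policy"] = AdherencePolicy(d["adherence_policy"])
        if "hygiene_kinds_counted" in d:
            kwargs["hygiene_kinds_counted"] = frozenset(
                HygieneKind(k) for k in d["hygiene_kinds_counted"]
            )
        if "stream_mode" in d:
            kwargs["stream_mode"] = StreamMode(d["stream_mode"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "infection_origin_exclusion": self.infection_origin_exclusion.value,
            "colonization_destination_excludes_critical": self.colonization_destination_excludes_critical,
            "adherence_policy": self.adherence_policy.value,
            "hygiene_kinds_counted": sorted(k.value for k in self.hygiene_kinds_counted),
            "stream_mode": self.stream_mode.value,
        }


@dataclass
class RiskEvent:
    """A detected colonization or infection event on one hand.

    ``origin_index``/``dest_index`` index into the session's sorted
    ``hse_events`` list. The inter-contact gap ``(origin.end_s,
    destination.start_s)`` may be empty or negative when contacts overlap; no
    hygiene action can then be strictly contained in it.
    """

    kind: RiskKind
    hand: Hand
    origin: HSEEvent
    destination: HSEEvent
    origin_index: int
    dest_index: int
    preceded_by_hygiene: bool = False
    hygiene_ref: HygieneAction | None = None

    @property
    def gap_s(self) -> float:
        return self.destination.start_s - self.origin.end_s


@dataclass(frozen=True)
class AdherenceSummary:
    """Adherence is undefined (reported "NA") when there are no events."""

    n_events: int
    n_with_hygiene: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_with_hygiene <= self.n_events:
            raise ValueError("0 <= n_with_hygiene <= n_events required")

    @property
    def adherence_pct(self) -> float | None:
        if self.n_events == 0:
            return None
        return 100.0 * self.n_with_hygiene / self.n_events

    def render(self) -> str:
        p = self.adherence_pct
        return "NA" if p is None else f"{self.n_with_hygiene} ({pct(self.n_with_hygiene, self.n_events)})"


def hand_stream(session: CodedSession, hand: Hand) -> list[HSEEvent]:
    """All and only the HSE of one hand, in stream order.

    Session events are already sorted stably by (start, end, input order), so
    filtering preserves that order.
    """
    return [e for e in session.hse_events if e.hand is hand]


def _same_critical_site(origin: HSEEvent, dest: HSEEvent) -> bool:
    """Identity rule for the same-site exclusion.

    With surface ids on both contacts, identity is id equality. Without ids,
    two contacts of the same critical leaf type are conservatively treated as
    the same site (avoids inventing distinct sites from unlabeled data).
    """
    if origin.zone is not Zone.CRITICAL_SITE or dest.zone is not Zone.CRITICAL_SITE:
        return False
    if origin.surface_id is not None and dest.surface_id is not None:
        return origin.surface_id == dest.surface_id
    return origin.surface_type is dest.surface_type


def _classify(origin: HSEEvent, dest: HSEEvent, config: DetectionConfig) -> RiskKind | None:
    dz = dest.zone
    if dz is Zone.CRITICAL_SITE:
        if config.infection_origin_exclusion is InfectionOriginExclusion.ANY_CRITICAL_SITE:
            excluded = origin.zone is Zone.CRITICAL_SITE
        else:
            excluded = _same_critical_site(origin, dest)
        if not excluded:
            return RiskKind.INFECTION
        # an excluded infection origin is by definition a critical site, which
        # is never an outside-zone origin, so this pair cannot be a
        # colonization event either — regardless of the destination flag
        return None
    if dz is Zone.INSIDE_PATIENT_ZONE and origin.zone is Zone.OUTSIDE_PATIENT_ZONE:
        return RiskKind.COLONIZATION
    return None


def classify_transition(
    origin: HSEEvent, dest: HSEEvent, config: DetectionConfig | None = None
) -> RiskKind | None:
    """Classify one consecutive same-hand pair; None when no risk pattern matches.

    Infection takes precedence by construction: destination zones are disjoint,
    so a critical-site destination can never simultaneously be a colonization
    destination.
    """
    config = config or DetectionConfig()
    if config.stream_mode is StreamMode.PER_HAND and origin.hand is not dest.hand:
        raise ValueError("origin and destination must be contacts of the same hand")
    return _classify(origin, dest, config)


def detect_risk_events(
    session: CodedSession, config: DetectionConfig | None = None
) -> list[RiskEvent]:
    """Scan every consecutive pair of each hand's stream; ordered by destination start.

    Equivalent to the naive double loop over consecutive same-hand pairs; each
    pair yields at most one event.
    """
    config = config or DetectionConfig()
    index_of = {id(e): i for i, e in enumerate(session.hse_events)}
    events: list[RiskEvent] = []

    if config.stream_mode is StreamMode.INTERLEAVED:
        streams: list[list[HSEEvent]] = [list(session.hse_events)]
    else:
        streams = [hand_stream(session, hand) for hand in Hand]

    for stream in streams:
        for origin, dest in zip(stream, stream[1:]):
            kind = _classify(origin, dest, config)
            if kind is not None:
                events.append(
                    RiskEvent(
                        kind=kind,
                        hand=dest.hand,
                        origin=origin,
                        destination=dest,
                        origin_index=index_of[id(origin)],
                        dest_index=index_of[id(dest)],
                    )
                )
    events.sort(key=lambda ev: (ev.destination.start_s, ev.dest_index))
    return events


def _qualifies(action: HygieneAction, event: RiskEvent, config: DetectionConfig) -> bool:
    if action.kind not in config.hygiene_kinds_counted:
        return False
    gap_start = event.origin.end_s
    gap_end = event.destination.start_s
    if config.adherence_policy is AdherencePolicy.STRICT_CONTAINMENT:
        return action.start_s >= gap_start and action.end_s <= gap_end
    # open-interval overlap with (gap_start, gap_end)
    return action.start_s < gap_end and action.end_s > gap_start


def attach_hygiene(
    events: list[RiskEvent],
    actions: Sequence[HygieneAction],
    config: DetectionConfig | None = None,
) -> list[RiskEvent]:
    """Set ``preceded_by_hygiene`` on each event from the session's hygiene actions.

    Hygiene is handless: every action is evaluated against both hands' events.
    Multiple qualifying actions count once; ``hygiene_ref`` keeps the last one
    in time order.
    """
    config = config or DetectionConfig()
    actions = sorted(actions, key=lambda a: (a.start_s, a.end_s))
    for ev in events:
        ev.preceded_by_hygiene = False
        ev.hygiene_ref = None
        for action in actions:
            if _qualifies(action, ev, config):
                ev.preceded_by_hygiene = True
                ev.hygiene_ref = action
    return events


def adherence_summary(events: Iterable[RiskEvent], kind: RiskKind) -> AdherenceSummary:
    """Count hygiene-covered events of one kind; 0 events -> undefined ("NA")."""
    selected = [ev for ev in events if ev.kind is kind]
    return AdherenceSummary(
        n_events=len(selected),
        n_with_hygiene=sum(1 for ev in selected if ev.preceded_by_hygiene),
    )


_CSV_COLUMNS = [
    "session_id",
    "kind",
    "hand",
    "origin_index",
    "dest_index",
    "origin_zone",
    "origin_surface_type",
    "dest_surface_type",
    "gap_s",
    "preceded_by_hygiene",
]


def risk_events_to_csv(
    events_by_session: Mapping[str, Sequence[RiskEvent]], sink: TextIO
) -> None:
    """Export detected events of one or more sessions as CSV."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for session_id, events in events_by_session.items():
        for ev in events:
            writer.writerow(
                [
                    session_id,
                    ev.kind.value,
                    ev.hand.value,
                    ev.origin_index,
                    ev.dest_index,
                    ev.origin.zone.value,
                    ev.origin.surface_type.value,
                    ev.destination.surface_type.value,
                    f"{ev.gap_s:.3f}",
                    "true" if ev.preceded_by_hygiene else "false",
                ]
            )
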