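"""Per-session and pooled descriptive statistics of HSE streams.

Mirrors the classic observation-study report: contact counts and densities,
duration statistics, hand and glove splits, zone shares with within-zone
surface-type breakdowns, risk-event counts, hygiene-action rates, and
adherence per event kind.

Conventions: sample (n-1) standard deviation; densities divide by the coded
duration of the session (not the first-to-last event span); pooled statistics
are computed over the concatenated events — pooled density is total count over
total duration, never the mean of per-session densities. Percentages are kept
unrounded internally and displayed at one decimal, half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import pct, round_half_up
from .event_model import (
    CodedSession,
    Hand,
    SelfSubtype,
    SurfaceType,
    Zone,
    LEAF_TO_ZONE,
)
from .risk_events import AdherenceSummary, RiskEvent, RiskKind, adherence_summary

__all__ = [
    "TimeUnit",
    "DurationStats",
    "SessionSummary",
    "density",
    "duration_stats",
    "session_summary",
    "pooled_summary",
    "summaries_to_json",
    "summary_table",
    "REPORT_SCHEMA_VERSION",
    "REPORT_SCHEMA",
    "check_report",
]

REPORT_SCHEMA_VERSION = "handseq-report-1"


class TimeUnit(str, Enum):
    MINUTE = "MINUTE"
    HOUR = "HOUR"


_UNIT_SECONDS = {TimeUnit.MINUTE: 60.0, TimeUnit.HOUR: 3600.0}


def density(count: int, duration_s: float, per: TimeUnit) -> float:
    """Event rate per minute or per hour; raises on non-positive duration."""
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    return count * _UNIT_SECONDS[TimeUnit(per)] / duration_s


@dataclass(frozen=True)
class DurationStats:
    """n, mean, sample SD, median (midpoint rule), min, max; all None when n=0."""

    n: int
    mean_s: float | None
    sd_s: float | None
    median_s: float | None
    min_s: float | None
    max_s: float | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_s": self.mean_s,
            "sd_s": self.sd_s,
            "median_s": self.median_s,
            "min_s": self.min_s,
            "max_s": self.max_s,
        }


def duration_stats(durations: Sequence[float]) -> DurationStats:
    x = np.asarray(list(durations), dtype=float)
    if x.size == 0:
        return DurationStats(0, None, None, None, None, None)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return DurationStats(
        n=int(x.size),
        mean_s=float(np.mean(x)),
        sd_s=sd,
        median_s=float(np.median(x)),
        min_s=float(np.min(x)),
        max_s=float(np.max(x)),
    )


_ZONE_LEAVES: dict[Zone, list[SurfaceType]] = {
    zone: [leaf for leaf, z in LEAF_TO_ZONE.items() if z is zone] for zone in Zone
}


@dataclass
class SessionSummary:
    """Everything the standard report table carries for one session (or pooled)."""

    session_id: str
    n_sessions: int
    coded_duration_s: float
    profession: str | None
    gender: str | None
    icu_specialty: str | None

    n_hse: int
    hse_duration: DurationStats
    n_by_hand: dict[Hand, int]
    n_gloved: int
    n_bare: int
    n_by_zone: dict[Zone, int]
    n_by_surface_type: dict[SurfaceType, int]
    n_by_self_subtype: dict[SelfSubtype, int]

    n_risk_by_kind: dict[RiskKind, int]
    n_risk_by_kind_hand: dict[RiskKind, dict[Hand, int]]
    adherence: dict[RiskKind, AdherenceSummary]

    n_hygiene: int
    hygiene_duration: DurationStats

    @property
    def hse_density_per_min(self) -> float:
        return density(self.n_hse, self.coded_duration_s, TimeUnit.MINUTE)

    @property
    def hygiene_density_per_hour(self) -> float:
        return density(self.n_hygiene, self.coded_duration_s, TimeUnit.HOUR)

    @property
    def n_risk_total(self) -> int:
        return sum(self.n_risk_by_kind.values())

    def to_dict(self) -> dict:
        adh = {
            kind.value: {
                "n_events": a.n_events,
                "n_with_hygiene": a.n_with_hygiene,
                "adherence_pct": None
                if a.adherence_pct is None
                else round_half_up(a.adherence_pct, 1),
            }
            for kind, a in self.adherence.items()
        }
        return {
            "session_id": self.session_id,
            "n_sessions": self.n_sessions,
            "coded_duration_s": self.coded_duration_s,
            "profession": self.profession,
            "gender": self.gender,
            "icu_specialty": self.icu_specialty,
            "hse": {
                "n": self.n_hse,
                "density_per_min": round_half_up(self.hse_density_per_min, 1),
                "duration": self.hse_duration.to_dict(),
                "by_hand": {h.value: self.n_by_hand[h] for h in Hand},
                "gloved": self.n_gloved,
                "bare": self.n_bare,
                "by_zone": {z.value: self.n_by_zone[z] for z in Zone},
                "by_surface_type": {t.value: self.n_by_surface_type[t] for t in SurfaceType},
                "by_self_subtype": {s.value: self.n_by_self_subtype[s] for s in SelfSubtype},
            },
            "risk_events": {
                "total": self.n_risk_total,
                "by_kind": {k.value: self.n_risk_by_kind[k] for k in RiskKind},
                "by_kind_hand": {
                    k.value: {h.value: self.n_risk_by_kind_hand[k][h] for h in Hand}
                    for k in RiskKind
                },
                "adherence": adh,
            },
            "hygiene": {
                "n": self.n_hygiene,
                "density_per_hour": round_half_up(self.hygiene_density_per_hour, 1),
                "duration": self.hygiene_duration.to_dict(),
            },
        }


def _check_events_belong(session: CodedSession, events: Sequence[RiskEvent]) -> None:
    ids = {id(e) for e in session.hse_events}
    for ev in events:
        if id(ev.origin) not in ids or id(ev.destination) not in ids:
            raise ValueError(
                f"risk event references contacts outside session {session.session_id!r}"
            )


def _summarize(
    sessions: Sequence[CodedSession],
    events: Sequence[RiskEvent],
    session_id: str,
    profession: str | None,
    gender: str | None,
    icu_specialty: str | None,
) -> SessionSummary:
    hse = [e for s in sessions for e in s.hse_events]
    hygiene = [a for s in sessions for a in s.hygiene_actions]
    duration = sum(s.coded_duration_s for s in sessions)

    n_by_hand = {h: sum(1 for e in hse if e.hand is h) for h in Hand}
    n_gloved = sum(1 for e in hse if e.gloved)
    n_by_zone = {z: sum(1 for e in hse if e.zone is z) for z in Zone}
    n_by_type = {t: sum(1 for e in hse if e.surface_type is t) for t in SurfaceType}
    n_by_self = {
        s: sum(1 for e in hse if e.category.self_subtype is s) for s in SelfSubtype
    }
    n_risk = {k: sum(1 for ev in events if ev.kind is k) for k in RiskKind}
    n_risk_hand = {
        k: {h: sum(1 for ev in events if ev.kind is k and ev.hand is h) for h in Hand}
        for k in RiskKind
    }

    return SessionSummary(
        session_id=session_id,
        n_sessions=len(sessions),
        coded_duration_s=duration,
        profession=profession,
        gender=gender,
        icu_specialty=icu_specialty,
        n_hse=len(hse),
        hse_duration=duration_stats([e.duration_s for e in hse]),
        n_by_hand=n_by_hand,
        n_gloved=n_gloved,
        n_bare=len(hse) - n_gloved,
        n_by_zone=n_by_zone,
        n_by_surface_type=n_by_type,
        n_by_self_subtype=n_by_self,
        n_risk_by_kind=n_risk,
        n_risk_by_kind_hand=n_risk_hand,
        adherence={k: adherence_summary(events, k) for k in RiskKind},
        n_hygiene=len(hygiene),
        hygiene_duration=duration_stats([a.duration_s for a in hygiene]),
    )


def session_summary(session: CodedSession, events: Sequence[RiskEvent]) -> SessionSummary:
    """Summarize one session; ``events`` must have been detected from it."""
    _check_events_belong(session, events)
    return _summarize(
        [session],
        events,
        session.session_id,
        session.profession.value,
        session.gender,
        session.icu_specialty,
    )


def pooled_summary(
    sessions: Sequence[CodedSession], events_per_session: Sequence[Sequence[RiskEvent]]
) -> SessionSummary:
    """Pool sessions: counts concatenate, durations add, rates use the totals."""
    if not sessions:
        raise ValueError("pooled_summary requires at least one session")
    if len(sessions) != len(events_per_session):
        raise ValueError("one event list per session required")
    for s, evs in zip(sessions, events_per_session):
        _check_events_belong(s, evs)
    flat = [ev for evs in events_per_session for ev in evs]
    return _summarize([*sessions], flat, "overall", None, None, None)


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

#: Published structural schema of the JSON report (JSON-Schema-like dict).
REPORT_SCHEMA: dict = {
    "$id": "handseq-report-1",
    "type": "object",
    "required": ["schema_version", "sessions", "overall"],
    "properties": {
        "schema_version": {"const": REPORT_SCHEMA_VERSION},
        "detection_config": {"type": "object"},
        "sessions": {"type": "array", "items": {"$ref": "#/definitions/summary"}},
        "overall": {"$ref": "#/definitions/summary"},
    },
    "definitions": {
        "summary": {
            "type": "object",
            "required": [
                "session_id",
                "n_sessions",
                "coded_duration_s",
                "hse",
                "risk_events",
                "hygiene",
            ],
        }
    },
}


def check_report(report: Mapping) -> None:
    """Light structural check of a report dict against REPORT_SCHEMA; raises ValueError."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unexpected schema_version {report['schema_version']!r}")
    summaries = list(report["sessions"]) + [report["overall"]]
    for s in summaries:
        for key in REPORT_SCHEMA["definitions"]["summary"]["required"]:
            if key not in s:
                raise ValueError(f"summary {s.get('session_id')!r} missing key {key!r}")


def summaries_to_json(
    per_session: Sequence[SessionSummary],
    overall: SessionSummary,
    detection_config: Mapping | None = None,
) -> str:
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "detection_config": dict(detection_config) if detection_config else {},
        "sessions": [s.to_dict() for s in per_session],
        "overall": overall.to_dict(),
    }
    check_report(report)
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def _fmt_count_pct(n: int, whole: int) -> str:
    p = pct(n, whole)
    return f"{n}" if p is None else f"{n} ({p})"


def _fmt_duration(d: DurationStats) -> str:
    if d.n == 0:
        return "NA"
    return f"{round_half_up(d.mean_s, 2)} ({round_half_up(d.sd_s, 1)})"


def summary_table(per_session: Sequence[SessionSummary], overall: SessionSummary) -> pd.DataFrame:
    """Report-table-shaped frame: descriptive rows, one column per session plus overall."""
    columns = [*per_session, overall]

    def row(label: str, fn) -> tuple[str, list]:
        return label, [fn(c) for c in columns]

    zone_label = {
        Zone.INSIDE_PATIENT_ZONE: "Any surface inside patient zone (% of all HSE)",
        Zone.OUTSIDE_PATIENT_ZONE: "Any surface outside patient zone (% of all HSE)",
        Zone.CRITICAL_SITE: "Any critical site (inside patient zone) (% of all HSE)",
    }
    rows: list[tuple[str, list]] = [
        row("ICU specialty", lambda c: c.icu_specialty or ""),
        row("Length of coded care sequence; min", lambda c: round_half_up(c.coded_duration_s / 60.0, 1)),
        row("Profession", lambda c: c.profession or ""),
        row("HSE; n", lambda c: c.n_hse),
        row("HSE density; n/min", lambda c: round_half_up(c.hse_density_per_min, 1)),
        row("Mean HSE duration (SD); sec", lambda c: _fmt_duration(c.hse_duration)),
        row("Right hand (%)", lambda c: _fmt_count_pct(c.n_by_hand[Hand.RIGHT], c.n_hse)),
        row("Left hand (%)", lambda c: _fmt_count_pct(c.n_by_hand[Hand.LEFT], c.n_hse)),
        row("Gloves worn: no (%)", lambda c: _fmt_count_pct(c.n_bare, c.n_hse)),
        row("Gloves worn: yes (%)", lambda c: _fmt_count_pct(c.n_gloved, c.n_hse)),
    ]
    type_labels: dict[SurfaceType, str] = {
        SurfaceType.PATIENT_INTACT_SKIN: "Patient intact skin (% of HSE inside patient zone)",
        SurfaceType.MOBILE_OBJECT_INSIDE: "Mobile object inside patient zone (% of HSE inside patient zone)",
        SurfaceType.IMMOBILE_SURFACE_INSIDE: "Immobile surface inside patient zone (% of HSE inside patient zone)",
        SurfaceType.HCW_SELF: "HCW own body (outside patient zone) (% of HSE outside patient zone)",
        SurfaceType.MOBILE_OBJECT_OUTSIDE: "Mobile object outside patient zone (% of HSE outside patient zone)",
        SurfaceType.IMMOBILE_SURFACE_OUTSIDE: "Immobile surface outside patient zone (% of HSE outside patient zone)",
        SurfaceType.STERILE_EQUIPMENT: "Sterile equipment (% of HSE at critical site)",
        SurfaceType.INVASIVE_DEVICE_ACCESS: "Invasive device access (% of HSE at critical site)",
        SurfaceType.MUCOUS_MEMBRANE: "Mucous membrane (% of HSE at critical site)",
        SurfaceType.WOUND: "Wound (% of HSE at critical site)",
    }
    for zone in (Zone.INSIDE_PATIENT_ZONE, Zone.OUTSIDE_PATIENT_ZONE, Zone.CRITICAL_SITE):
        rows.append(
            row(zone_label[zone], lambda c, z=zone: _fmt_count_pct(c.n_by_zone[z], c.n_hse))
        )
        for leaf in _ZONE_LEAVES[zone]:
            rows.append(
                row(
                    type_labels[leaf],
                    lambda c, z=zone, t=leaf: _fmt_count_pct(
                        c.n_by_surface_type[t], c.n_by_zone[z]
                    ),
                )
            )
    rows += [
        row("Infectious risk events", lambda c: c.n_risk_total),
        row("Patient colonization events", lambda c: c.n_risk_by_kind[RiskKind.COLONIZATION]),
        row("Patient infection events", lambda c: c.n_risk_by_kind[RiskKind.INFECTION]),
        row("Hand hygiene actions; n", lambda c: c.n_hygiene),
        row(
            "Hand hygiene action at colonization event; n (% adherence)",
            lambda c: c.adherence[RiskKind.COLONIZATION].render(),
        ),
        row(
            "Hand hygiene action at infection event; n (% adherence)",
            lambda c: c.adherence[RiskKind.INFECTION].render(),
        ),
        row(
            "Average density of hand hygiene actions; n/hour",
            lambda c: round_half_up(c.hygiene_density_per_hour, 1),
        ),
        row(
            "Mean duration of hand hygiene actions (SD); sec",
            lambda c: _fmt_duration(c.hygiene_duration),
        ),
    ]
    frame = pd.DataFrame(
        {label: values for label, values in rows},
        index=[c.session_id for c in columns],
    ).T
    frame.index.name = "statistic"
    return frame
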