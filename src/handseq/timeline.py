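"""Lane-based timeline rendering of a coded session.

One lane per (hand, glove state, zone) combination — 12 contact lanes — plus a
hand-hygiene lane on top, the way behavioral-coding timelines are drawn.
Colonization/infection events are marked at the start of their destination
contact. Output is either plain text (fixed-width, deterministic, good for
terminals and golden tests) or SVG via matplotlib.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .event_model import CodedSession, Hand, HSEEvent, Zone
from .risk_events import RiskEvent, RiskKind

__all__ = ["TimelineFormat", "Lane", "TimelineSpec", "build_timeline_spec", "render_timeline"]


class TimelineFormat(str, Enum):
    TEXT = "TEXT"
    SVG = "SVG"


@dataclass(frozen=True)
class Lane:
    hand: Hand
    gloved: bool
    zone: Zone

    @property
    def label(self) -> str:
        glove = "gloved" if self.gloved else "bare"
        zone = {
            Zone.INSIDE_PATIENT_ZONE: "inside",
            Zone.CRITICAL_SITE: "critical",
            Zone.OUTSIDE_PATIENT_ZONE: "outside",
        }[self.zone]
        return f"{glove} {self.hand.value.lower()[0].upper()} {zone}"


@dataclass(frozen=True)
class TimelineSpec:
    """Lane order (top to bottom, after the hygiene lane) and the time window."""

    lanes: tuple[Lane, ...]
    start_s: float
    end_s: float

    def lane_of(self, event: HSEEvent) -> int:
        return self.lanes.index(Lane(event.hand, event.gloved, event.zone))


_ZONE_ORDER = (Zone.INSIDE_PATIENT_ZONE, Zone.CRITICAL_SITE, Zone.OUTSIDE_PATIENT_ZONE)


def build_timeline_spec(start_s: float, end_s: float) -> TimelineSpec:
    """The canonical 12-lane layout: bare R, bare L, gloved R, gloved L x zones."""
    if end_s <= start_s:
        raise ValueError(f"empty window [{start_s}, {end_s}]")
    lanes = tuple(
        Lane(hand, gloved, zone)
        for gloved in (False, True)
        for hand in (Hand.RIGHT, Hand.LEFT)
        for zone in _ZONE_ORDER
    )
    return TimelineSpec(lanes=lanes, start_s=start_s, end_s=end_s)


def _in_window(start: float, end: float, spec: TimelineSpec) -> bool:
    return end > spec.start_s and start < spec.end_s


_MARK = {RiskKind.COLONIZATION: "C", RiskKind.INFECTION: "I"}


def _render_text(
    session: CodedSession, events: Sequence[RiskEvent], spec: TimelineSpec, bin_s: float
) -> str:
    width = max(1, int(round((spec.end_s - spec.start_s) / bin_s)))
    col_of = lambda t: min(width - 1, max(0, int((t - spec.start_s) / bin_s)))
    label_w = max(len("hygiene"), max(len(lane.label) for lane in spec.lanes))
    rows: list[list[str]] = [["."] * width for _ in range(len(spec.lanes) + 1)]

    for action in session.hygiene_actions:
        if _in_window(action.start_s, action.end_s, spec):
            for c in range(col_of(action.start_s), col_of(max(action.start_s, action.end_s - 1e-9)) + 1):
                rows[0][c] = "#"
    for event in session.hse_events:
        if _in_window(event.start_s, event.end_s, spec):
            r = spec.lane_of(event) + 1
            for c in range(col_of(event.start_s), col_of(max(event.start_s, event.end_s - 1e-9)) + 1):
                rows[r][c] = "#"
    for ev in events:
        t = ev.destination.start_s
        if spec.start_s <= t < spec.end_s:
            rows[spec.lane_of(ev.destination) + 1][col_of(t)] = _MARK[ev.kind]

    header = (
        f"session {session.session_id}  "
        f"window {spec.start_s:.1f}-{spec.end_s:.1f}s  ({bin_s:g}s/char)"
    )
    lines = [header]
    labels = ["hygiene"] + [lane.label for lane in spec.lanes]
    for label, row in zip(labels, rows):
        lines.append(f"{label:>{label_w}} |{''.join(row)}|")
    return "\n".join(lines) + "\n"


def _render_svg(
    session: CodedSession, events: Sequence[RiskEvent], spec: TimelineSpec
) -> str:
    plt.rcParams["svg.hashsalt"] = "handseq"
    n_lanes = len(spec.lanes) + 1
    fig, ax = plt.subplots(figsize=(10, 0.45 * n_lanes + 1))
    y_of = lambda r: n_lanes - 1 - r  # hygiene on top

    for action in session.hygiene_actions:
        if _in_window(action.start_s, action.end_s, spec):
            ax.broken_barh(
                [(action.start_s, action.duration_s)], (y_of(0) - 0.35, 0.7), color="#2b8cbe"
            )
    zone_color = {
        Zone.INSIDE_PATIENT_ZONE: "#74c476",
        Zone.CRITICAL_SITE: "#de2d26",
        Zone.OUTSIDE_PATIENT_ZONE: "#969696",
    }
    for event in session.hse_events:
        if _in_window(event.start_s, event.end_s, spec):
            r = spec.lane_of(event) + 1
            ax.broken_barh(
                [(event.start_s, event.duration_s)],
                (y_of(r) - 0.35, 0.7),
                color=zone_color[event.zone],
            )
    for ev in events:
        t = ev.destination.start_s
        if spec.start_s <= t < spec.end_s:
            r = spec.lane_of(ev.destination) + 1
            ax.plot(
                [t], [y_of(r) + 0.45], marker="v",
                color="black" if ev.kind is RiskKind.COLONIZATION else "red",
                markersize=5, linestyle="none",
            )
    ax.set_xlim(spec.start_s, spec.end_s)
    ax.set_ylim(-0.6, n_lanes - 0.4)
    ax.set_yticks([y_of(0)] + [y_of(i + 1) for i in range(len(spec.lanes))])
    ax.set_yticklabels(["hygiene"] + [lane.label for lane in spec.lanes], fontsize=7)
    ax.set_xlabel("time from session start (s)")
    ax.set_title(f"session {session.session_id}")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None}, bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def render_timeline(
    session: CodedSession,
    events: Sequence[RiskEvent] = (),
    window: tuple[float, float] | None = None,
    format: TimelineFormat = TimelineFormat.TEXT,
    bin_s: float = 1.0,
) -> str:
    """Render the session's coding timeline; deterministic for fixed input.

    ``window`` defaults to the whole coded duration; an empty window raises.
    Every in-window contact appears on exactly one lane (the lane assignment
    is a bijection from (hand, glove, zone) triples).
    """
    start, end = window if window is not None else (0.0, session.coded_duration_s)
    spec = build_timeline_spec(start, end)
    if TimelineFormat(format) is TimelineFormat.TEXT:
        return _render_text(session, events, spec, bin_s)
    return _render_svg(session, events, spec)
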