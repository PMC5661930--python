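"""Domain model for coded hand-to-surface exposure (HSE) sessions.

An observed care episode is coded as a stream of timed events: every contact
between one of the healthcare worker's hands and a surface (an *HSE*), plus
hand-hygiene actions (alcohol handrub or hand washing). Surfaces are
classified by a hierarchical scheme whose analytic level is the *zone*:

* ``INSIDE_PATIENT_ZONE`` — the patient and the immediate environment assumed
  colonized with the patient's own flora (WHO patient-zone concept);
* ``OUTSIDE_PATIENT_ZONE`` — everything else, including the worker's own body
  and apparel;
* ``CRITICAL_SITE`` — clean sites (wounds, mucous membranes, accessed invasive
  devices, sterile equipment) that must be protected from colonization.
  Critical sites are physically located inside the patient zone but are
  analyzed as their own class.

This module defines the in-memory types, the ``handseq-v1`` event-log CSV
dialect (one file per session, metadata in a ``#key=value`` comment header),
and session validation.

Time convention: seconds from session start, half-open intervals
``[start_s, end_s)``; abutting contacts therefore do not overlap.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence, TextIO

__all__ = [
    "Zone",
    "SurfaceType",
    "SelfSubtype",
    "Hand",
    "HygieneKind",
    "Profession",
    "SurfaceCategory",
    "HSEEvent",
    "HygieneAction",
    "CodedSession",
    "ValidationIssue",
    "ValidationReport",
    "FormatError",
    "OTHER_OWN_HAND",
    "LEAF_TO_ZONE",
    "leaf_to_zone",
    "parse_session_log",
    "write_session_log",
    "validate_session",
]


class Zone(str, Enum):
    INSIDE_PATIENT_ZONE = "INSIDE_PATIENT_ZONE"
    OUTSIDE_PATIENT_ZONE = "OUTSIDE_PATIENT_ZONE"
    CRITICAL_SITE = "CRITICAL_SITE"


class SurfaceType(str, Enum):
    """The ten leaves of the surface taxonomy (coding levels 3-4)."""

    # inside patient zone
    PATIENT_INTACT_SKIN = "PATIENT_INTACT_SKIN"
    MOBILE_OBJECT_INSIDE = "MOBILE_OBJECT_INSIDE"
    IMMOBILE_SURFACE_INSIDE = "IMMOBILE_SURFACE_INSIDE"
    # outside patient zone
    HCW_SELF = "HCW_SELF"
    MOBILE_OBJECT_OUTSIDE = "MOBILE_OBJECT_OUTSIDE"
    IMMOBILE_SURFACE_OUTSIDE = "IMMOBILE_SURFACE_OUTSIDE"
    # critical sites
    STERILE_EQUIPMENT = "STERILE_EQUIPMENT"
    INVASIVE_DEVICE_ACCESS = "INVASIVE_DEVICE_ACCESS"
    MUCOUS_MEMBRANE = "MUCOUS_MEMBRANE"
    WOUND = "WOUND"


class SelfSubtype(str, Enum):
    """Refinement of HCW_SELF contacts (what part of the worker was touched)."""

    CLOTHES = "CLOTHES"
    PPE = "PPE"
    FACE = "FACE"
    BARE_SKIN_OR_HAIR = "BARE_SKIN_OR_HAIR"


class Hand(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class HygieneKind(str, Enum):
    HANDRUB = "HANDRUB"
    HANDWASH = "HANDWASH"


class Profession(str, Enum):
    NURSE = "NURSE"
    PHYSICIAN = "PHYSICIAN"
    OTHER = "OTHER"


LEAF_TO_ZONE: dict[SurfaceType, Zone] = {
    SurfaceType.PATIENT_INTACT_SKIN: Zone.INSIDE_PATIENT_ZONE,
    SurfaceType.MOBILE_OBJECT_INSIDE: Zone.INSIDE_PATIENT_ZONE,
    SurfaceType.IMMOBILE_SURFACE_INSIDE: Zone.INSIDE_PATIENT_ZONE,
    SurfaceType.HCW_SELF: Zone.OUTSIDE_PATIENT_ZONE,
    SurfaceType.MOBILE_OBJECT_OUTSIDE: Zone.OUTSIDE_PATIENT_ZONE,
    SurfaceType.IMMOBILE_SURFACE_OUTSIDE: Zone.OUTSIDE_PATIENT_ZONE,
    SurfaceType.STERILE_EQUIPMENT: Zone.CRITICAL_SITE,
    SurfaceType.INVASIVE_DEVICE_ACCESS: Zone.CRITICAL_SITE,
    SurfaceType.MUCOUS_MEMBRANE: Zone.CRITICAL_SITE,
    SurfaceType.WOUND: Zone.CRITICAL_SITE,
}

#: Reserved surface label: one hand touching the other hand of the same worker
#: is not a codable surface; a row carrying this label is a validation error.
OTHER_OWN_HAND = "OTHER_OWN_HAND"


def leaf_to_zone(surface_type: SurfaceType) -> Zone:
    """Map a surface-taxonomy leaf to its zone (total, single-valued)."""
    try:
        return LEAF_TO_ZONE[SurfaceType(surface_type)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown surface type: {surface_type!r}") from None


@dataclass(frozen=True)
class SurfaceCategory:
    """One leaf of the taxonomy together with its zone.

    ``self_subtype`` is present iff ``surface_type`` is HCW_SELF.
    """

    surface_type: SurfaceType
    self_subtype: SelfSubtype | None = None

    def __post_init__(self) -> None:
        leaf_to_zone(self.surface_type)  # raises on unknown leaf
        if self.surface_type is SurfaceType.HCW_SELF:
            if self.self_subtype is None:
                raise ValueError("HCW_SELF requires a self_subtype")
        elif self.self_subtype is not None:
            raise ValueError(
                f"self_subtype is only valid for HCW_SELF, not {self.surface_type.value}"
            )

    @property
    def zone(self) -> Zone:
        return LEAF_TO_ZONE[self.surface_type]


@dataclass
class HSEEvent:
    """One timed hand-to-surface contact.

    ``surface_id`` optionally identifies the specific surface (e.g. which
    invasive device); it is what makes the "same critical site" exclusion of
    the infection-event definition decidable.
    """

    hand: Hand
    gloved: bool
    category: SurfaceCategory
    start_s: float
    end_s: float
    surface_id: str | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def zone(self) -> Zone:
        return self.category.zone

    @property
    def surface_type(self) -> SurfaceType:
        return self.category.surface_type


@dataclass
class HygieneAction:
    """One hand-hygiene action; applies to both hands (handless in the model)."""

    kind: HygieneKind
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _time_sorted(items: Sequence) -> list:
    """Stable sort by (start_s, end_s); equal intervals keep input order."""
    return sorted(items, key=lambda e: (e.start_s, e.end_s))


@dataclass
class CodedSession:
    """All events of one observed care episode plus its metadata.

    Events are kept sorted by ``(start_s, end_s, input order)``; the sort is
    stable so simultaneous contacts preserve the order they were coded in.
    """

    session_id: str
    coded_duration_s: float
    profession: Profession = Profession.OTHER
    gender: str | None = None
    icu_specialty: str | None = None
    hse_events: list[HSEEvent] = field(default_factory=list)
    hygiene_actions: list[HygieneAction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hse_events = _time_sorted(self.hse_events)
        self.hygiene_actions = _time_sorted(self.hygiene_actions)


# ---------------------------------------------------------------------------
# handseq-v1 event-log dialect
# ---------------------------------------------------------------------------

_COLUMNS = [
    "record_type",
    "hand",
    "gloved",
    "zone",
    "surface_type",
    "self_subtype",
    "surface_id",
    "kind",
    "start_s",
    "end_s",
]

_META_KEYS = ("session_id", "coded_duration_s", "profession", "gender", "icu_specialty")


class FormatError(ValueError):
    """Structural problem in an event-log file (missing header, bad columns)."""


def _fmt_time(t: float) -> str:
    return f"{t:.3f}"


def _parse_time(text: str, row_no: int, col: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise ValueError(f"row {row_no}: non-numeric {col} {text!r}") from None
    if v < 0:
        raise ValueError(f"row {row_no}: negative {col} {text!r}")
    return v


def parse_session_log(source: TextIO | str, dialect: str = "handseq-v1") -> CodedSession:
    """Parse one handseq-v1 event log into a validated, time-sorted session.

    Raises :class:`FormatError` for structural problems (missing metadata or
    column header) and :class:`ValueError` (with the offending row number) for
    non-numeric/negative times or non-positive durations.
    """
    if dialect != "handseq-v1":
        raise FormatError(f"unknown dialect {dialect!r}")
    if isinstance(source, str):
        source = io.StringIO(source)

    meta: dict[str, str] = {}
    header_line: str | None = None
    data_lines: list[str] = []
    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise FormatError(f"malformed metadata line {line!r}")
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif header_line is None:
            header_line = line
        else:
            data_lines.append(line)

    for required in ("session_id", "coded_duration_s"):
        if required not in meta:
            raise FormatError(f"missing #{required}= metadata line")
    if header_line is None:
        raise FormatError("missing column header line")
    if [c.strip() for c in header_line.split(",")] != _COLUMNS:
        raise FormatError(f"unexpected column header {header_line!r}")

    duration = _parse_time(meta["coded_duration_s"], 0, "coded_duration_s")
    profession = Profession(meta.get("profession", "OTHER"))

    hse: list[HSEEvent] = []
    hygiene: list[HygieneAction] = []
    reader = csv.DictReader(data_lines, fieldnames=_COLUMNS)
    for row_no, row in enumerate(reader, start=1):
        if None in row or any(row.get(c) is None for c in _COLUMNS):
            raise FormatError(f"row {row_no}: wrong number of fields")
        start = _parse_time(row["start_s"], row_no, "start_s")
        end = _parse_time(row["end_s"], row_no, "end_s")
        if end <= start:
            raise ValueError(f"row {row_no}: end_s {end} <= start_s {start}")
        rtype = row["record_type"].strip()
        if rtype == "HSE":
            surface_type = SurfaceType(row["surface_type"])
            subtype = SelfSubtype(row["self_subtype"]) if row["self_subtype"] else None
            category = SurfaceCategory(surface_type, subtype)
            if row["zone"] and Zone(row["zone"]) is not category.zone:
                raise ValueError(
                    f"row {row_no}: zone {row['zone']} inconsistent with "
                    f"surface_type {surface_type.value}"
                )
            hse.append(
                HSEEvent(
                    hand=Hand(row["hand"]),
                    gloved={"true": True, "false": False}[row["gloved"].lower()],
                    category=category,
                    surface_id=row["surface_id"] or None,
                    start_s=start,
                    end_s=end,
                )
            )
        elif rtype == "HYGIENE":
            hygiene.append(HygieneAction(kind=HygieneKind(row["kind"]), start_s=start, end_s=end))
        else:
            raise ValueError(f"row {row_no}: unknown record_type {rtype!r}")

    return CodedSession(
        session_id=meta["session_id"],
        coded_duration_s=duration,
        profession=profession,
        gender=meta.get("gender") or None,
        icu_specialty=meta.get("icu_specialty") or None,
        hse_events=hse,
        hygiene_actions=hygiene,
    )


def write_session_log(session: CodedSession, sink: TextIO) -> None:
    """Emit the canonical handseq-v1 form of a session.

    Canonical means: fixed column order, times printed with exactly three
    decimals, HSE rows before HYGIENE rows within equal times, rows sorted by
    (start, end). Refuses sessions whose validation report contains errors, so
    a written file always parses back.
    """
    report = validate_session(session)
    if report.errors:
        first = report.errors[0]
        raise ValueError(f"refusing to write invalid session: {first.rule_id}: {first.message}")

    sink.write(f"#session_id={session.session_id}\n")
    sink.write(f"#coded_duration_s={_fmt_time(session.coded_duration_s)}\n")
    sink.write(f"#profession={session.profession.value}\n")
    if session.gender:
        sink.write(f"#gender={session.gender}\n")
    if session.icu_specialty:
        sink.write(f"#icu_specialty={session.icu_specialty}\n")
    sink.write(",".join(_COLUMNS) + "\n")

    rows: list[tuple] = []
    for e in session.hse_events:
        rows.append(
            (
                e.start_s,
                e.end_s,
                0,
                [
                    "HSE",
                    e.hand.value,
                    "true" if e.gloved else "false",
                    e.zone.value,
                    e.surface_type.value,
                    e.category.self_subtype.value if e.category.self_subtype else "",
                    e.surface_id or "",
                    "",
                    _fmt_time(e.start_s),
                    _fmt_time(e.end_s),
                ],
            )
        )
    for a in session.hygiene_actions:
        rows.append(
            (
                a.start_s,
                a.end_s,
                1,
                ["HYGIENE", "", "", "", "", "", "", a.kind.value, _fmt_time(a.start_s), _fmt_time(a.end_s)],
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    for _, _, _, cells in rows:
        sink.write(",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    index: int | None
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_session(session: CodedSession) -> ValidationReport:
    """Deterministic rule-based check of a session.

    Errors reject the session from analysis; warnings do not. Overlapping
    same-hand contacts are a warning only — lane-based coding tools legitimately
    produce visually overlapping annotations.
    """
    report = ValidationReport()
    err = lambda rule, i, msg: report.errors.append(ValidationIssue(rule, i, msg))
    warn = lambda rule, i, msg: report.warnings.append(ValidationIssue(rule, i, msg))

    if session.coded_duration_s <= 0:
        err("SESSION_DURATION", None, f"coded_duration_s {session.coded_duration_s} must be > 0")

    for i, e in enumerate(session.hse_events):
        if e.end_s <= e.start_s:
            err("NONPOSITIVE_DURATION", i, f"HSE [{e.start_s}, {e.end_s}] has duration <= 0")
        if e.start_s < 0 or e.end_s > session.coded_duration_s:
            err(
                "TIME_BOUNDS",
                i,
                f"HSE [{e.start_s}, {e.end_s}] outside [0, {session.coded_duration_s}]",
            )
        if e.surface_id == OTHER_OWN_HAND:
            err(
                "OTHER_OWN_HAND",
                i,
                "contact with the worker's own other hand is not a codable surface",
            )
        # category internal consistency is enforced at construction; re-check
        # here for sessions assembled by hand with bad categories
        try:
            SurfaceCategory(e.category.surface_type, e.category.self_subtype)
        except ValueError as exc:  # pragma: no cover - frozen dataclass blocks most
            err("CATEGORY", i, str(exc))

    for i, a in enumerate(session.hygiene_actions):
        if a.end_s <= a.start_s:
            err("NONPOSITIVE_DURATION", i, f"hygiene [{a.start_s}, {a.end_s}] has duration <= 0")
        if a.start_s < 0 or a.end_s > session.coded_duration_s:
            err(
                "TIME_BOUNDS",
                i,
                f"hygiene [{a.start_s}, {a.end_s}] outside [0, {session.coded_duration_s}]",
            )

    # overlap warnings: same-hand HSE, and hygiene actions among themselves;
    # half-open intervals, so touching endpoints do not overlap
    for hand in Hand:
        stream = [(i, e) for i, e in enumerate(session.hse_events) if e.hand is hand]
        for (i1, e1), (i2, e2) in zip(stream, stream[1:]):
            if e2.start_s < e1.end_s:
                warn(
                    "OVERLAP_SAME_HAND",
                    i2,
                    f"{hand.value} HSE #{i2} starts at {e2.start_s} before #{i1} ends at {e1.end_s}",
                )
    for (i1, a1), (i2, a2) in zip(
        enumerate(session.hygiene_actions), list(enumerate(session.hygiene_actions))[1:]
    ):
        if a2.start_s < a1.end_s:
            warn("OVERLAP_HYGIENE", i2, f"hygiene #{i2} overlaps hygiene #{i1}")

    return report


def canonicalize(session: CodedSession) -> CodedSession:
    """Return a copy that would round-trip byte-identically through the dialect.

    Times are quantized to the dialect's 3-decimal resolution.
    """
    q = lambda t: float(_fmt_time(t))
    return CodedSession(
        session_id=session.session_id,
        coded_duration_s=q(session.coded_duration_s),
        profession=session.profession,
        gender=session.gender,
        icu_specialty=session.icu_specialty,
        hse_events=[replace(e, start_s=q(e.start_s), end_s=q(e.end_s)) for e in session.hse_events],
        hygiene_actions=[
            replace(a, start_s=q(a.start_s), end_s=q(a.end_s)) for a in session.hygiene_actions
        ],
    )
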