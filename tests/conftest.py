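"""Shared fixtures and oracle helpers.

All test data is generated programmatically: either hand-built micro-sessions
or output of the seeded synthetic generator.
"""

from __future__ import annotations

import pytest

from handseq.event_model import (
    CodedSession,
    Hand,
    HSEEvent,
    HygieneAction,
    HygieneKind,
    SelfSubtype,
    SurfaceCategory,
    SurfaceType,
    Zone,
)
from handseq.benchmark import build_benchmark_sessions
from handseq.synthetic import default_generator_config, generate_session


def hse(
    hand: Hand,
    leaf: SurfaceType,
    start: float,
    end: float,
    gloved: bool = False,
    site: str | None = None,
) -> HSEEvent:
    subtype = SelfSubtype.CLOTHES if leaf is SurfaceType.HCW_SELF else None
    return HSEEvent(
        hand=hand,
        gloved=gloved,
        category=SurfaceCategory(leaf, subtype),
        surface_id=site,
        start_s=start,
        end_s=end,
    )


def rub(start: float, end: float) -> HygieneAction:
    return HygieneAction(kind=HygieneKind.HANDRUB, start_s=start, end_s=end)


def session_of(events, hygiene=(), duration=1000.0, session_id="s") -> CodedSession:
    return CodedSession(
        session_id=session_id,
        coded_duration_s=duration,
        hse_events=list(events),
        hygiene_actions=list(hygiene),
    )


def brute_force_risk_events(session, config=None):
    """Independent naive oracle: scan all consecutive same-hand pairs.

    Re-implements the classification rules directly from their definitions,
    without calling the detection module's classifier.
    """
    from handseq.risk_events import DetectionConfig, InfectionOriginExclusion

    config = config or DetectionConfig()
    found = []
    for hand in Hand:
        stream = [e for e in session.hse_events if e.hand is hand]
        for k in range(len(stream) - 1):
            o, d = stream[k], stream[k + 1]
            kind = None
            if d.zone is Zone.CRITICAL_SITE:
                if config.infection_origin_exclusion is InfectionOriginExclusion.ANY_CRITICAL_SITE:
                    skip = o.zone is Zone.CRITICAL_SITE
                else:
                    if o.zone is Zone.CRITICAL_SITE:
                        if o.surface_id is not None and d.surface_id is not None:
                            skip = o.surface_id == d.surface_id
                        else:
                            skip = o.surface_type is d.surface_type
                    else:
                        skip = False
                if not skip:
                    kind = "INFECTION"
            elif d.zone is Zone.INSIDE_PATIENT_ZONE and o.zone is Zone.OUTSIDE_PATIENT_ZONE:
                kind = "COLONIZATION"
            if kind:
                found.append((kind, hand.value, o.start_s, d.start_s))
    return sorted(found, key=lambda t: t[3])


@pytest.fixture(scope="session")
def bench_sessions():
    return build_benchmark_sessions()


@pytest.fixture(scope="session")
def default_config():
    return default_generator_config(seed=0)


def quick_session(seed: int, duration_s: float = 180.0):
    """Small simulated session for property tests (~40 contacts)."""
    cfg = default_generator_config(seed=seed, session_duration_s=duration_s)
    return generate_session(cfg)
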