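"""Batch pipeline: parse event logs, detect risk events, write the report set.

Outputs (all deterministic for identical inputs): ``summary.json`` (versioned
schema, per-session + pooled), ``summary_table.csv`` (report-table shape,
sessions as columns plus an overall column), and ``risk_events.csv``. Invalid
sessions are excluded and listed in the log; the exit status distinguishes
complete success, partial failure, and total failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .event_model import CodedSession, parse_session_log, validate_session
from .risk_events import DetectionConfig, RiskEvent, attach_hygiene, detect_risk_events, risk_events_to_csv
from .summary_stats import pooled_summary, session_summary, summaries_to_json, summary_table

__all__ = ["PipelineResult", "run_pipeline", "EXIT_OK", "EXIT_TOTAL_FAILURE", "EXIT_PARTIAL"]

log = logging.getLogger("handseq")

EXIT_OK = 0
EXIT_TOTAL_FAILURE = 1
EXIT_PARTIAL = 3


@dataclass
class PipelineResult:
    exit_status: int
    n_processed: int
    failures: list[tuple[str, str]]  # (path, reason)
    output_dir: Path


def run_pipeline(
    inputs: Sequence[str | Path],
    config: DetectionConfig | None = None,
    output_dir: str | Path = ".",
) -> PipelineResult:
    """Process event logs end to end; see module docstring for outputs."""
    config = config or DetectionConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    sessions: list[CodedSession] = []
    failures: list[tuple[str, str]] = []
    for path in inputs:
        path = Path(path)
        try:
            with open(path, encoding="utf-8") as fh:
                session = parse_session_log(fh)
        except (OSError, ValueError) as exc:
            log.error("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
            continue
        report = validate_session(session)
        for w in report.warnings:
            log.debug("%s: %s: %s", path, w.rule_id, w.message)
        if not report.ok:
            reason = "; ".join(f"{e.rule_id}: {e.message}" for e in report.errors[:3])
            log.error("skipping %s: %s", path, reason)
            failures.append((str(path), reason))
            continue
        sessions.append(session)
        log.info("parsed %s: %d HSE, %d hygiene actions", path, len(session.hse_events), len(session.hygiene_actions))

    if not sessions:
        log.error("no valid sessions; nothing to report")
        return PipelineResult(EXIT_TOTAL_FAILURE, 0, failures, output_dir)

    events_per_session: list[list[RiskEvent]] = []
    for session in sessions:
        events = detect_risk_events(session, config)
        attach_hygiene(events, session.hygiene_actions, config)
        events_per_session.append(events)
        log.info(
            "%s: %d risk events", session.session_id, len(events)
        )

    per = [session_summary(s, evs) for s, evs in zip(sessions, events_per_session)]
    overall = pooled_summary(sessions, events_per_session)

    (output_dir / "summary.json").write_text(
        summaries_to_json(per, overall, config.to_dict()), encoding="utf-8"
    )
    summary_table(per, overall).to_csv(output_dir / "summary_table.csv")
    with open(output_dir / "risk_events.csv", "w", encoding="utf-8") as fh:
        risk_events_to_csv(
            {s.session_id: evs for s, evs in zip(sessions, events_per_session)}, fh
        )
    log.info("wrote reports for %d sessions to %s", len(sessions), output_dir)

    status = EXIT_PARTIAL if failures else EXIT_OK
    return PipelineResult(status, len(sessions), failures, output_dir)
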