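"""Ward overviews, per-patient reports, the phone list, and call documentation.

Rendering functions are pure views over engine state; only
:func:`record_call` mutates (it appends to the engine's call log).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

from .errors import DuplicateCallError, UnknownNotificationError
from .engine import Engine, Notification
from .rules import Severity, classify_aki

__all__ = [
    "CallRecord",
    "WardOverviewRow",
    "ReportLine",
    "PatientReport",
    "CAVEAT_BANNER",
    "DEFAULT_POLL_SECONDS",
    "render_ward_overview",
    "render_patient_report",
    "export_phone_list",
    "record_call",
    "phone_list_csv",
    "call_log_csv",
    "overview_rows_json",
]

#: Terminal poll period in seconds; the display goes STALE past 2x this age.
DEFAULT_POLL_SECONDS = 600

CAVEAT_BANNER = (
    "Automated analysis by an ongoing research project; "
    "results should be used with caution."
)


@dataclass(frozen=True)
class CallRecord:
    """Documentation of one notification phone call, with the two feedback answers."""

    call_id: str
    notification_id: str
    call_time: datetime
    phone_number: str
    callee_name: str
    therapy_started: bool | None = None  # None == unanswered
    notification_helped: bool | None = None


@dataclass(frozen=True)
class WardOverviewRow:
    patient_id: str
    summary_color: Severity | None  # None when STALE (column left empty)
    checkmark: bool
    last_refresh: datetime

    @property
    def stale(self) -> bool:
        return self.summary_color is None


@dataclass(frozen=True)
class ReportLine:
    algorithm_id: str
    diagnosis: str
    severity: Severity
    trigger_value: float | None
    trigger_at: datetime | None
    ttc_status: str
    silenced: bool
    acknowledged: bool
    annotations: tuple[str, ...] = ()

    def render(self) -> str:
        label = self.diagnosis
        if self.annotations:
            label += " — " + "; ".join(self.annotations)
        return f"{label} — {self.severity.name}"


@dataclass(frozen=True)
class PatientReport:
    patient_id: str
    banner: str
    lines: tuple[ReportLine, ...] = ()

    def render(self) -> str:
        body = "\n".join(line.render() for line in self.lines)
        return f"[{self.banner}]\nPatient {self.patient_id}\n{body}\n"


def render_ward_overview(
    engine: Engine,
    patient_ids: Sequence[str],
    now: datetime,
    *,
    last_refresh: Mapping[str, datetime] | datetime | None = None,
    poll_seconds: int = DEFAULT_POLL_SECONDS,
) -> list[WardOverviewRow]:
    """One row per patient; color replaced by STALE (empty column) when the
    refresh age exceeds twice the poll interval."""
    rows: list[WardOverviewRow] = []
    for pid in patient_ids:
        if isinstance(last_refresh, Mapping):
            refresh = last_refresh.get(pid, now)
        elif isinstance(last_refresh, datetime):
            refresh = last_refresh
        else:
            refresh = now  # no refresh info: treat the display as fresh
        summary = engine.summarize_patient(pid)
        stale = (now - refresh) > timedelta(seconds=2 * poll_seconds)
        rows.append(
            WardOverviewRow(
                patient_id=pid,
                summary_color=None if stale else summary.color,
                checkmark=summary.checkmark,
                last_refresh=refresh,
            )
        )
    return rows


def render_patient_report(engine: Engine, patient_id: str) -> PatientReport:
    """One line per active algorithm; unknown patients yield all-GREEN lines."""
    lines: list[ReportLine] = []
    for rule in engine.config.active_rules:
        episode = engine.current_episode(patient_id, rule.algorithm_id)
        annotations: tuple[str, ...] = ()
        if episode is not None:
            severity = episode.severity
            trigger_value = episode.trigger_result.value
            trigger_at = episode.trigger_result.measured_at
            annotations = episode.annotations
            if episode.ttc_deadline is None:
                ttc_status = "immediate" if rule.ttc_is_immediate else "n/a"
            elif episode.escalated:
                ttc_status = f"OVERDUE since {episode.ttc_deadline.isoformat()}"
            else:
                ttc_status = f"due {episode.ttc_deadline.isoformat()}"
            acknowledged = episode.acknowledged_by is not None
            silenced = engine.is_silenced(patient_id, rule.algorithm_id)
        else:
            severity = Severity.GREEN
            trigger_value = None
            trigger_at = None
            ttc_status = "n/a"
            acknowledged = False
            silenced = engine.is_silenced(patient_id, rule.algorithm_id)
        lines.append(
            ReportLine(
                algorithm_id=rule.algorithm_id,
                diagnosis=rule.diagnosis,
                severity=severity,
                trigger_value=trigger_value,
                trigger_at=trigger_at,
                ttc_status=ttc_status,
                silenced=silenced,
                acknowledged=acknowledged,
                annotations=annotations,
            )
        )
    return PatientReport(patient_id=patient_id, banner=CAVEAT_BANNER, lines=tuple(lines))


def export_phone_list(
    engine: Engine, since: datetime | None = None
) -> list[Notification]:
    """Un-called notifications since a timestamp, oldest first.

    The engine's notification log only ever contains the displayed
    (intervention-arm, unsilenced) channel, so control-arm findings can
    never appear here.
    """
    items = [
        n
        for n in engine.notifications
        if n.notification_id not in engine.call_log
        and (since is None or n.created_at >= since)
    ]
    items.sort(key=lambda n: (n.created_at, n.notification_id))
    return items


def record_call(engine: Engine, notification_id: str, call: CallRecord) -> None:
    """Attach a call record to a notification; at most one call per notification."""
    known = {n.notification_id for n in engine.notifications}
    if notification_id not in known:
        raise UnknownNotificationError(notification_id)
    if notification_id in engine.call_log:
        raise DuplicateCallError(notification_id)
    if call.notification_id != notification_id:
        raise UnknownNotificationError(
            f"call references {call.notification_id}, expected {notification_id}"
        )
    engine.call_log[notification_id] = call


# ---------------------------------------------------------------------------
# Flat-file exports


def phone_list_csv(engine: Engine, since: datetime | None = None) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(("created_at", "patient_id", "algorithm", "severity", "message"))
    for n in export_phone_list(engine, since):
        writer.writerow(
            (n.created_at.isoformat(), n.patient_id, n.algorithm_id,
             n.severity.name, n.message)
        )
    return buf.getvalue()


def call_log_csv(engine: Engine) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ("call_id", "notification_id", "call_time", "phone_number",
         "callee_name", "therapy_started", "notification_helped")
    )

    def tri(v: bool | None) -> str:
        return "unanswered" if v is None else ("yes" if v else "no")

    for call in engine.call_log.values():
        writer.writerow(
            (call.call_id, call.notification_id, call.call_time.isoformat(),
             call.phone_number, call.callee_name,
             tri(call.therapy_started), tri(call.notification_helped))
        )
    return buf.getvalue()


def overview_rows_json(rows: Sequence[WardOverviewRow]) -> list[dict]:
    return [
        {
            "patient_id": r.patient_id,
            "summary_color": None if r.stale else r.summary_color.name,
            "stale": r.stale,
            "checkmark": r.checkmark,
            "last_refresh": r.last_refresh.isoformat(),
        }
        for r in rows
    ]
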