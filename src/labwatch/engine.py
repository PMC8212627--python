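"""Stateful surveillance core.

The engine ingests validated :class:`~labwatch.hl7_io.LabResult` events,
maintains one alert episode per patient and algorithm, runs time-to-control
(TTC) timers via an explicit ``tick`` clock, and emits notifications with
at-most-once semantics per (patient, algorithm, trigger time, kind).

Semantics are defined by a rebuild of the per-patient, per-algorithm
timeline from the sorted result history: every result controls the episode
that was open before it, and every non-GREEN result opens a fresh episode
(so a controlled-but-still-critical value restarts the TTC clock).
In-order and out-of-order arrivals share this single code path; emitted
notifications are never retracted.  The whole state is reconstructible by
replaying the canonical event log.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .arms import Arm, assign_arm
from .errors import (
    ClockRegressionError,
    ConfigError,
    StaleResultError,
    UnknownAlgorithmError,
    UnknownPatientError,
)
from .hl7_io import LabResult, Source
from .rules import (
    RuleSet,
    Severity,
    annotate_result,
    build_default_rulesets,
    classify_aki,
    evaluate_threshold_rule,
    severity_for_aki,
)

__all__ = [
    "NotificationKind",
    "Notification",
    "AlertEpisode",
    "EngineConfig",
    "PatientSummary",
    "Engine",
    "events_to_jsonl",
    "events_from_jsonl",
]

ALL_ALGORITHMS = "ALL"


class NotificationKind(Enum):
    CRITICAL_VALUE = "CRITICAL_VALUE"
    TTC_OVERDUE = "TTC_OVERDUE"


@dataclass(frozen=True)
class Notification:
    notification_id: str
    created_at: datetime
    patient_id: str
    algorithm_id: str
    kind: NotificationKind
    severity: Severity
    message: str
    dedup_key: tuple


@dataclass
class AlertEpisode:
    """Stateful record of one finding from trigger through control/escalation."""

    episode_id: str
    patient_id: str
    case_id: str
    algorithm_id: str
    severity: Severity
    trigger_result: LabResult
    ttc_deadline: datetime | None
    controlled: bool = False
    control_result: LabResult | None = None
    acknowledged_by: str | None = None
    acknowledged_at: datetime | None = None
    silenced: bool = False
    escalated: bool = False
    is_open: bool = True
    annotations: tuple[str, ...] = ()
    aki_stage: int | None = None

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.algorithm_id, self.trigger_result.measured_at)


@dataclass(frozen=True)
class EngineConfig:
    rulesets: tuple[RuleSet, ...] = field(
        default_factory=lambda: tuple(build_default_rulesets())
    )
    arm_suppression: bool = True
    retention: timedelta = timedelta(days=30)
    tick_seconds: int = 60
    max_clock_skew: timedelta | None = None  # future-timestamp guard, off by default

    def __post_init__(self) -> None:
        ids = [r.algorithm_id for r in self.rulesets]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate algorithm_id in rule configuration")

    @property
    def active_rules(self) -> tuple[RuleSet, ...]:
        return tuple(r for r in self.rulesets if r.active)


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    color: Severity
    checkmark: bool
    statuses: Mapping[str, Severity]
    silenced_algorithms: frozenset[str]


class Engine:
    """Reactive surveillance engine over a stream of laboratory results."""

    def __init__(self, config: EngineConfig | None = None):
        self.config = config or EngineConfig()
        self.clock: datetime | None = None
        self.notifications: list[Notification] = []
        self.call_log: dict[str, object] = {}  # notification_id -> CallRecord
        self.events: list[dict] = []  # canonical event log (deduplicated)
        self.audit: list[dict] = []  # append-only audit trail
        # history: (patient_id, Parameter) -> results sorted by (measured_at, seq)
        self._history: dict[tuple, list[tuple[datetime, int, LabResult]]] = {}
        # episodes: (patient_id, algorithm_id) -> timeline of episodes
        self._episodes: dict[tuple[str, str], list[AlertEpisode]] = {}
        self._red_seen: set[tuple] = set()  # episode keys whose emission was decided
        self._escalated: set[tuple] = set()
        self._seen_results: set[tuple] = set()
        self._acks: dict[str, tuple[str, datetime]] = {}
        self._silences: dict[str, set[str]] = {}
        self._patients: set[str] = set()
        self._seq = 0
        self._notif_seq = 0

    # -- helpers ----------------------------------------------------------

    def _rule(self, algorithm_id: str) -> RuleSet:
        for r in self.config.rulesets:
            if r.algorithm_id == algorithm_id:
                return r
        raise UnknownAlgorithmError(algorithm_id)

    def arm(self, patient_id: str) -> Arm:
        return assign_arm(patient_id)

    def is_silenced(self, patient_id: str, algorithm_id: str) -> bool:
        silenced = self._silences.get(patient_id, set())
        return ALL_ALGORITHMS in silenced or algorithm_id in silenced

    def _audit(self, kind: str, **data) -> None:
        self.audit.append({"kind": kind, **data})

    def current_episode(self, patient_id: str, algorithm_id: str) -> AlertEpisode | None:
        timeline = self._episodes.get((patient_id, algorithm_id))
        if timeline and timeline[-1].is_open:
            return timeline[-1]
        return None

    def all_episodes(self) -> list[AlertEpisode]:
        return [e for timeline in self._episodes.values() for e in timeline]

    # -- ingest -----------------------------------------------------------

    def ingest(self, result: LabResult) -> list[Notification]:
        """Process one result; returns notifications emitted by this call.

        Exact duplicates (same patient, parameter, time, value) are no-ops.
        Results older than the retention horizon are rejected.
        """
        if result.dedup_identity in self._seen_results:
            self._audit("duplicate_ignored", patient_id=result.patient_id,
                        measured_at=result.measured_at.isoformat())
            return []
        if (
            self.clock is not None
            and result.measured_at < self.clock - self.config.retention
        ):
            raise StaleResultError(
                f"result at {result.measured_at.isoformat()} older than retention "
                f"horizon ({self.config.retention}) behind clock {self.clock.isoformat()}"
            )
        if (
            self.config.max_clock_skew is not None
            and self.clock is not None
            and result.measured_at > self.clock + self.config.max_clock_skew
        ):
            raise StaleResultError(
                f"result at {result.measured_at.isoformat()} beyond clock skew limit"
            )

        self._seen_results.add(result.dedup_identity)
        self.events.append(_result_event(result))
        self._patients.add(result.patient_id)
        self._seq += 1
        key = (result.patient_id, result.parameter)
        timeline = self._history.setdefault(key, [])
        entry = (result.measured_at, self._seq, result)
        if timeline and result.measured_at < timeline[-1][0]:
            bisect.insort(timeline, entry)
            self._audit(
                "out_of_order_arrival",
                patient_id=result.patient_id,
                parameter=result.parameter.name,
                measured_at=result.measured_at.isoformat(),
            )
        else:
            timeline.append(entry)
        if self.clock is None or result.measured_at > self.clock:
            self.clock = result.measured_at

        emitted: list[Notification] = []
        for rule in self.config.active_rules:
            if rule.watches(result.parameter):
                emitted.extend(self._rebuild(result.patient_id, rule))
        return emitted

    def _results_for(self, patient_id: str, rule: RuleSet) -> list[LabResult]:
        entries: list[tuple[datetime, int, LabResult]] = []
        for p in rule.parameters:
            entries.extend(self._history.get((patient_id, p), []))
        entries.sort(key=lambda e: (e[0], e[1]))
        return [r for _, _, r in entries]

    def _severity_of(self, rule: RuleSet, results: Sequence[LabResult], i: int):
        """Severity of results[i] under the rule; returns (severity, aki_stage)."""
        if rule.kind == "aki":
            assessment = classify_aki(results[: i + 1])
            return severity_for_aki(assessment), assessment.stage
        return evaluate_threshold_rule(rule, results[i]), None

    def _rebuild(self, patient_id: str, rule: RuleSet) -> list[Notification]:
        """Recompute the episode timeline for one patient+algorithm.

        Single source of truth for episode semantics; notification and
        escalation flags survive rebuilds through persistent key sets.
        """
        results = self._results_for(patient_id, rule)
        timeline: list[AlertEpisode] = []
        emitted: list[Notification] = []
        episode: AlertEpisode | None = None
        for i, r in enumerate(results):
            severity, aki_stage = self._severity_of(rule, results, i)
            if episode is not None:
                episode.controlled = True
                episode.control_result = r
                episode.is_open = False
                episode = None
            if severity is Severity.GREEN:
                continue
            deadline = None
            if severity is Severity.RED and isinstance(rule.ttc, timedelta):
                deadline = r.measured_at + rule.ttc
            annotations = tuple(annotate_result(r.parameter, r.value))
            if aki_stage:
                annotations = (f"AKIN {aki_stage}",) + annotations
            episode = AlertEpisode(
                episode_id=f"{patient_id}:{rule.algorithm_id}:{r.measured_at.isoformat()}",
                patient_id=patient_id,
                case_id=r.case_id,
                algorithm_id=rule.algorithm_id,
                severity=severity,
                trigger_result=r,
                ttc_deadline=deadline,
                silenced=self.is_silenced(patient_id, rule.algorithm_id),
                annotations=annotations,
                aki_stage=aki_stage,
            )
            timeline.append(episode)
            if severity is Severity.RED and episode.key not in self._red_seen:
                self._red_seen.add(episode.key)
                self._acks.pop(patient_id, None)  # new RED trigger clears checkmark
                emitted.extend(
                    self._emit(episode, NotificationKind.CRITICAL_VALUE, r.measured_at)
                )
            if episode.key in self._escalated:
                episode.escalated = True
        # re-apply patient-level acknowledgment to surviving episodes
        ack = self._acks.get(patient_id)
        if ack is not None:
            actor, at = ack
            for e in timeline:
                if e.trigger_result.measured_at <= at:
                    e.acknowledged_by, e.acknowledged_at = actor, at
        self._episodes[(patient_id, rule.algorithm_id)] = timeline
        return emitted

    def _emit(
        self, episode: AlertEpisode, kind: NotificationKind, created_at: datetime
    ) -> list[Notification]:
        """Decide the output channel for a notification exactly once per key."""
        dedup_key = (
            episode.patient_id,
            episode.algorithm_id,
            episode.trigger_result.measured_at,
            kind.value,
        )
        suppressed_by = None
        if self.config.arm_suppression and self.arm(episode.patient_id) is Arm.CONTROL:
            suppressed_by = "control_arm"
        elif self.is_silenced(episode.patient_id, episode.algorithm_id):
            suppressed_by = "silenced"
        if suppressed_by is not None:
            self._audit(
                "notification_suppressed",
                reason=suppressed_by,
                patient_id=episode.patient_id,
                algorithm_id=episode.algorithm_id,
                notification_kind=kind.value,
                trigger_at=episode.trigger_result.measured_at.isoformat(),
            )
            return []
        self._notif_seq += 1
        rule = self._rule(episode.algorithm_id)
        trig = episode.trigger_result
        if kind is NotificationKind.CRITICAL_VALUE:
            message = (
                f"{rule.diagnosis}: {trig.parameter.value} "
                f"{trig.value:g} {trig.parameter.canonical_units} "
                f"at {trig.measured_at.isoformat()}"
            )
        else:
            message = (
                f"{rule.diagnosis}: no follow-up measurement within TTC "
                f"(trigger {trig.measured_at.isoformat()})"
            )
        if episode.annotations:
            message += " [" + "; ".join(episode.annotations) + "]"
        notification = Notification(
            notification_id=f"N{self._notif_seq:06d}",
            created_at=created_at,
            patient_id=episode.patient_id,
            algorithm_id=episode.algorithm_id,
            kind=kind,
            severity=episode.severity,
            message=message,
            dedup_key=dedup_key,
        )
        self.notifications.append(notification)
        return [notification]

    # -- tick -------------------------------------------------------------

    def tick(self, now: datetime) -> list[Notification]:
        """Advance the clock; escalate open uncontrolled episodes past deadline.

        Each episode escalates at most once.  Silenced and control-arm
        episodes are marked escalated without emitting (audit-only).
        """
        if self.clock is not None and now < self.clock:
            raise ClockRegressionError(
                f"tick at {now.isoformat()} before clock {self.clock.isoformat()}"
            )
        self.clock = now
        self.events.append({"type": "tick", "at": now.isoformat()})
        emitted: list[Notification] = []
        due = [
            timeline[-1]
            for timeline in self._episodes.values()
            if timeline
            and timeline[-1].is_open
            and timeline[-1].severity is Severity.RED
            and not timeline[-1].controlled
            and not timeline[-1].escalated
            and timeline[-1].ttc_deadline is not None
            and timeline[-1].ttc_deadline <= now
        ]
        # earliest-overdue first; patient/algorithm break ties deterministically
        due.sort(key=lambda e: (e.ttc_deadline, e.patient_id, e.algorithm_id))
        for episode in due:
            episode.escalated = True
            self._escalated.add(episode.key)
            emitted.extend(self._emit(episode, NotificationKind.TTC_OVERDUE, now))
        return emitted

    # -- acknowledgment and silencing -------------------------------------

    def acknowledge(self, patient_id: str, actor: str, at: datetime) -> None:
        """Record the clinician checkmark for a patient (colors unchanged)."""
        if patient_id not in self._patients:
            raise UnknownPatientError(patient_id)
        self._acks[patient_id] = (actor, at)
        self.events.append(
            {"type": "ack", "patient_id": patient_id, "actor": actor, "at": at.isoformat()}
        )
        for (pid, _), timeline in self._episodes.items():
            if pid != patient_id:
                continue
            for e in timeline:
                if e.is_open and e.trigger_result.measured_at <= at:
                    e.acknowledged_by, e.acknowledged_at = actor, at

    def set_silence(
        self, patient_id: str, algorithm_id: str = ALL_ALGORITHMS, flag: bool = True
    ) -> None:
        """Silence (or unsilence) notifications for a patient/algorithm.

        Silenced findings are still evaluated and logged; only emission stops.
        """
        if patient_id not in self._patients:
            raise UnknownPatientError(patient_id)
        if algorithm_id != ALL_ALGORITHMS:
            self._rule(algorithm_id)  # raises UnknownAlgorithmError
        silenced = self._silences.setdefault(patient_id, set())
        if flag:
            silenced.add(algorithm_id)
        else:
            silenced.discard(algorithm_id)
        self.events.append(
            {
                "type": "silence",
                "patient_id": patient_id,
                "algorithm_id": algorithm_id,
                "flag": flag,
            }
        )
        for (pid, algo), timeline in self._episodes.items():
            if pid == patient_id and (algorithm_id in (ALL_ALGORITHMS, algo)):
                for e in timeline:
                    if e.is_open:
                        e.silenced = self.is_silenced(pid, algo)

    # -- summaries --------------------------------------------------------

    def summarize_patient(self, patient_id: str) -> PatientSummary:
        """Overview color = maximum severity over current algorithm statuses."""
        statuses: dict[str, Severity] = {}
        for rule in self.config.active_rules:
            episode = self.current_episode(patient_id, rule.algorithm_id)
            statuses[rule.algorithm_id] = (
                episode.severity if episode is not None else Severity.GREEN
            )
        color = max(statuses.values(), default=Severity.GREEN)
        return PatientSummary(
            patient_id=patient_id,
            color=color,
            checkmark=patient_id in self._acks,
            statuses=statuses,
            silenced_algorithms=frozenset(self._silences.get(patient_id, ())),
        )

    @property
    def patients(self) -> list[str]:
        return sorted(self._patients)

    def snapshot(self) -> dict:
        """Comparable state digest (used by tests and the CLI state dump)."""
        return {
            "patients": {
                pid: {
                    "color": self.summarize_patient(pid).color.name,
                    "checkmark": pid in self._acks,
                    "statuses": {
                        a: s.name
                        for a, s in self.summarize_patient(pid).statuses.items()
                    },
                }
                for pid in self.patients
            },
            "episodes": sorted(
                (
                    e.patient_id,
                    e.algorithm_id,
                    e.trigger_result.measured_at.isoformat(),
                    e.severity.name,
                    e.controlled,
                    e.escalated,
                    e.is_open,
                )
                for e in self.all_episodes()
            ),
            "notifications": [
                (
                    n.patient_id,
                    n.algorithm_id,
                    n.kind.value,
                    n.dedup_key[2].isoformat(),
                )
                for n in self.notifications
            ],
        }

    # -- replay -----------------------------------------------------------

    @classmethod
    def replay(
        cls, events: Iterable[dict | LabResult], config: EngineConfig | None = None
    ) -> "Engine":
        """Rebuild an engine from scratch by applying a time-ordered event log."""
        engine = cls(config)
        for event in events:
            if isinstance(event, LabResult):
                engine.ingest(event)
                continue
            etype = event.get("type")
            if etype == "result":
                engine.ingest(_result_from_event(event))
            elif etype == "tick":
                engine.tick(datetime.fromisoformat(event["at"]))
            elif etype == "ack":
                engine.acknowledge(
                    event["patient_id"],
                    event["actor"],
                    datetime.fromisoformat(event["at"]),
                )
            elif etype == "silence":
                engine.set_silence(
                    event["patient_id"], event["algorithm_id"], event["flag"]
                )
            else:
                raise ConfigError(f"unknown event type {etype!r}")
        return engine


# ---------------------------------------------------------------------------
# Event (de)serialization


def _result_event(result: LabResult) -> dict:
    return {
        "type": "result",
        "measured_at": result.measured_at.isoformat(),
        "patient_id": result.patient_id,
        "case_id": result.case_id,
        "order_id": result.order_id,
        "parameter": result.parameter.name,
        "value": result.value,
        "units": result.parameter.canonical_units,
        "source": result.source.value,
    }


def _result_from_event(event: dict) -> LabResult:
    from .rules import Parameter

    return LabResult(
        measured_at=datetime.fromisoformat(event["measured_at"]),
        patient_id=event["patient_id"],
        case_id=event["case_id"],
        order_id=event["order_id"],
        parameter=Parameter[event["parameter"]],
        value=float(event["value"]),
        raw_units=event.get("units", ""),
        source=Source(event.get("source", "LAB")),
    )


def events_to_jsonl(events: Iterable[dict]) -> str:
    return "".join(json.dumps(e, sort_keys=True) + "\n" for e in events)


def events_from_jsonl(text: str) -> list[dict]:
    return [json.loads(line) for line in text.splitlines() if line.strip()]
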