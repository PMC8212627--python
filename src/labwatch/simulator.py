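"""Seeded synthetic ward streams with configurable critical-value prevalence.

Stands in for retrospective hospital data: every measurement is drawn
uniformly from either the reference interval or a bounded critical band
(with probability ``critical_prevalence``), and every critical value
schedules a follow-up after an arm-specific log-normal response delay —
intervention-arm clinicians respond faster by default, emulating the
direction (not magnitude) of the reported effect.  All randomness flows
from the single seed.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .arms import Arm, assign_arm
from .engine import Engine
from .errors import ConfigError, MismatchedLogsError
from .hl7_io import LabResult, MessageEnvelope, Source, write_oru_file
from .rules import Parameter

__all__ = [
    "NORMAL_RANGE",
    "CRITICAL_RANGE",
    "DelayDistribution",
    "SimulationConfig",
    "TtcOutcome",
    "assign_arm",
    "simulate_stream",
    "compute_ttc_outcomes",
    "generate_hl7_fixture",
    "stream_to_envelopes",
]

SIM_EPOCH = datetime(2021, 1, 1, 0, 0, 0)

#: Reference intervals (canonical units) used for non-critical draws.
NORMAL_RANGE: dict[Parameter, tuple[float, float]] = {
    Parameter.K: (3.5, 5.0),
    Parameter.NA: (135.0, 145.0),
    Parameter.CA_TOTAL: (2.2, 2.6),
    Parameter.CA_IONIZED: (1.15, 1.30),
    Parameter.LACTATE: (0.5, 2.0),
    Parameter.CREATININE: (60.0, 105.0),
}

#: Bounded critical bands, strictly beyond each rule threshold.
CRITICAL_RANGE: dict[Parameter, tuple[float, float]] = {
    Parameter.K: (1.5, 2.49),
    Parameter.NA: (110.0, 119.9),
    Parameter.CA_TOTAL: (3.51, 4.5),
    Parameter.CA_IONIZED: (2.01, 2.5),
    Parameter.LACTATE: (4.01, 10.0),
    Parameter.CREATININE: (300.0, 500.0),
}


class DelayDistribution(BaseModel):
    """Log-normal clinician response delay, parameterized by its median in hours."""

    model_config = ConfigDict(frozen=True)

    name: str = "lognormal"
    median_hours: float = Field(gt=0)
    sigma: float = Field(default=0.5, gt=0)

    @field_validator("name")
    @classmethod
    def _supported(cls, v: str) -> str:
        if v != "lognormal":
            raise ValueError(f"unsupported delay distribution {v!r}")
        return v

    def draw_hours(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(mean=np.log(self.median_hours), sigma=self.sigma))

    @property
    def mean_hours(self) -> float:
        return float(self.median_hours * np.exp(self.sigma**2 / 2))


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=20, gt=0)
    duration_hours: float = Field(default=72.0, gt=0)
    parameters: tuple[Parameter, ...] = (
        Parameter.K,
        Parameter.NA,
        Parameter.CA_TOTAL,
        Parameter.LACTATE,
    )
    measurements_per_day: float = Field(default=4.0, gt=0)
    critical_prevalence: float = Field(default=0.05, ge=0.0, le=1.0)
    control_delay: DelayDistribution = DelayDistribution(median_hours=8.0)
    intervention_delay: DelayDistribution = DelayDistribution(median_hours=3.0)
    seed: int = 0
    first_patient_number: int = 1000

    def delay_for(self, arm: Arm) -> DelayDistribution:
        return self.control_delay if arm is Arm.CONTROL else self.intervention_delay


def simulate_stream(config: SimulationConfig) -> list[LabResult]:
    """Generate a time-ordered synthetic result stream (reproducible from seed)."""
    rng = np.random.default_rng(config.seed)
    end = SIM_EPOCH + timedelta(hours=config.duration_hours)
    mean_gap_hours = 24.0 / config.measurements_per_day
    events: list[tuple[datetime, int, LabResult]] = []
    seq = 0
    order_n = 0
    for i in range(config.n_patients):
        pid = str(config.first_patient_number + i)
        case_id = f"C{pid}"
        arm = assign_arm(pid)
        for param in config.parameters:
            t = SIM_EPOCH + timedelta(hours=float(rng.exponential(mean_gap_hours)))
            while t < end:
                critical = bool(rng.random() < config.critical_prevalence)
                lo, hi = (CRITICAL_RANGE if critical else NORMAL_RANGE)[param]
                value = round(float(rng.uniform(lo, hi)), 2)
                order_n += 1
                seq += 1
                events.append(
                    (
                        t,
                        seq,
                        LabResult(
                            measured_at=t.replace(microsecond=0),
                            patient_id=pid,
                            case_id=case_id,
                            order_id=f"O{order_n:06d}",
                            parameter=param,
                            value=value,
                            raw_units=param.canonical_units,
                            source=Source.SIMULATED,
                        ),
                    )
                )
                if critical:
                    # clinician response: a follow-up after the arm's delay
                    gap = config.delay_for(arm).draw_hours(rng)
                else:
                    gap = float(rng.exponential(mean_gap_hours))
                t = t + timedelta(hours=gap)
    events.sort(key=lambda e: (e[0], e[1]))
    return [r for _, _, r in events]


@dataclass(frozen=True)
class TtcOutcome:
    """Per-arm time-to-control summary over RED episodes."""

    arm: Arm
    n_episodes: int
    n_controlled: int
    n_censored: int
    controlled_within_ttc: float | None  # over episodes with a TTC deadline
    mean_ttc_hours: float | None
    median_ttc_hours: float | None


def compute_ttc_outcomes(
    engine: Engine, event_log: Sequence[LabResult] | None = None
) -> dict[Arm, TtcOutcome]:
    """Aggregate observed time-to-control per trial arm from engine episodes.

    Observed TTC = follow-up time minus trigger time; episodes without a
    follow-up are censored at stream end.  If ``event_log`` is given it must
    be the stream the engine consumed (mismatch -> error).
    """
    if event_log is not None:
        missing = [
            r for r in event_log if r.dedup_identity not in engine._seen_results
        ]
        if missing:
            raise MismatchedLogsError(
                f"{len(missing)} event-log results unknown to the engine"
            )
    per_arm: dict[Arm, list] = {Arm.CONTROL: [], Arm.INTERVENTION: []}
    from .rules import Severity

    for episode in engine.all_episodes():
        if episode.severity is not Severity.RED:
            continue
        per_arm[assign_arm(episode.patient_id)].append(episode)
    out: dict[Arm, TtcOutcome] = {}
    for arm, episodes in per_arm.items():
        ttcs: list[float] = []
        n_controlled = 0
        within = 0
        with_deadline = 0
        for e in episodes:
            if e.controlled and e.control_result is not None:
                n_controlled += 1
                delta = e.control_result.measured_at - e.trigger_result.measured_at
                ttcs.append(delta.total_seconds() / 3600.0)
                if e.ttc_deadline is not None:
                    with_deadline += 1
                    if e.control_result.measured_at <= e.ttc_deadline:
                        within += 1
            elif e.ttc_deadline is not None:
                with_deadline += 1
        out[arm] = TtcOutcome(
            arm=arm,
            n_episodes=len(episodes),
            n_controlled=n_controlled,
            n_censored=len(episodes) - n_controlled,
            controlled_within_ttc=(within / with_deadline) if with_deadline else None,
            mean_ttc_hours=statistics.fmean(ttcs) if ttcs else None,
            median_ttc_hours=statistics.median(ttcs) if ttcs else None,
        )
    return out


def stream_to_envelopes(results: Sequence[LabResult]) -> list[MessageEnvelope]:
    """One ORU message per result, with deterministic sequential message ids."""
    return [
        MessageEnvelope(
            message_id=f"M{i:06d}",
            sent_at=r.measured_at,
            sender="labwatch-sim",
            results=(r,),
        )
        for i, r in enumerate(results, start=1)
    ]


def generate_hl7_fixture(config: SimulationConfig) -> str:
    """Serialize a simulated stream as an HL7 file; round-trips through the parser."""
    return write_oru_file(stream_to_envelopes(simulate_stream(config)))
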