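"""Dataflow latency model: worst-case end-to-end delay and delay attribution.

The pipeline is measurement -> communication server -> warehouse/engine ->
notification -> terminal.  Each hop has a configured polling maximum; the
worst-case end-to-end delay is their sum (85 minutes with the default
15/60/10-minute maxima).  Observed per-hop timestamps ("checkbox protocol")
are compared against the maxima to attribute a delay to one component.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, ResultValidationError

__all__ = [
    "LatencyConfig",
    "HopTimestamps",
    "HopLag",
    "AttributionReport",
    "worst_case_delay",
    "attribute_delay",
    "simulate_polling_delay",
    "load_latency_config",
    "read_hops_csv",
]

#: Pipeline stages in dataflow order.
STAGES = ("measured_at", "comm_server_at", "engine_at", "notified_at", "terminal_at")

#: Hop names; hop i spans STAGES[i] -> STAGES[i+1].
HOP_NAMES = ("comm_server", "warehouse_poll", "engine_internal", "terminal_poll")


def _default_hops() -> dict[str, timedelta]:
    return {
        "comm_server": timedelta(minutes=15),
        "warehouse_poll": timedelta(minutes=60),
        "engine_internal": timedelta(0),
        "terminal_poll": timedelta(minutes=10),
    }


@dataclass(frozen=True)
class LatencyConfig:
    """Per-hop polling maxima, in dataflow order."""

    hops: dict[str, timedelta] = field(default_factory=_default_hops)

    def __post_init__(self) -> None:
        for name, dur in self.hops.items():
            if dur < timedelta(0):
                raise ConfigError(f"hop {name}: negative duration {dur}")

    @property
    def terminal_poll_seconds(self) -> float:
        return self.hops["terminal_poll"].total_seconds()


@dataclass(frozen=True)
class HopTimestamps:
    """Observed timestamps along the pipeline; any suffix may be missing."""

    measured_at: datetime
    comm_server_at: datetime | None = None
    engine_at: datetime | None = None
    notified_at: datetime | None = None
    terminal_at: datetime | None = None

    def present(self) -> list[tuple[str, datetime]]:
        out = []
        for stage in STAGES:
            ts = getattr(self, stage)
            if ts is not None:
                out.append((stage, ts))
        return out


@dataclass(frozen=True)
class HopLag:
    hop: str
    start_stage: str
    end_stage: str
    lag: timedelta
    max_allowed: timedelta
    exceeded: bool


@dataclass(frozen=True)
class AttributionReport:
    lags: tuple[HopLag, ...]
    dominant: str
    any_exceeded: bool

    def to_json(self) -> dict:
        return {
            "dominant": self.dominant,
            "any_exceeded": self.any_exceeded,
            "hops": [
                {
                    "hop": h.hop,
                    "from": h.start_stage,
                    "to": h.end_stage,
                    "lag_minutes": h.lag.total_seconds() / 60.0,
                    "max_minutes": h.max_allowed.total_seconds() / 60.0,
                    "exceeded": h.exceeded,
                }
                for h in self.lags
            ],
        }


def worst_case_delay(config: LatencyConfig) -> timedelta:
    """Sum of hop maxima: the analytic worst-case measurement-to-display delay."""
    return sum(config.hops.values(), timedelta(0))


def attribute_delay(hops: HopTimestamps, config: LatencyConfig) -> AttributionReport:
    """Per-hop lags, EXCEEDED flags, and the dominant (argmax-lag) component.

    Ties break toward the earliest pipeline hop.  Requires at least two
    present timestamps in non-decreasing order.
    """
    present = hops.present()
    if len(present) < 2:
        raise ResultValidationError("need at least 2 hop timestamps to attribute delay")
    for (_, a), (_, b) in zip(present, present[1:]):
        if b < a:
            raise ResultValidationError(
                f"hop timestamps not monotone: {a.isoformat()} -> {b.isoformat()}"
            )
    lags: list[HopLag] = []
    for i, ((stage_a, a), (stage_b, b)) in enumerate(zip(present, present[1:])):
        hop = HOP_NAMES[STAGES.index(stage_a)]
        lag = b - a
        limit = config.hops.get(hop, timedelta(0))
        lags.append(
            HopLag(
                hop=hop,
                start_stage=stage_a,
                end_stage=stage_b,
                lag=lag,
                max_allowed=limit,
                exceeded=lag > limit,
            )
        )
    dominant = max(lags, key=lambda h: h.lag).hop  # max() keeps the earliest tie
    return AttributionReport(
        lags=tuple(lags),
        dominant=dominant,
        any_exceeded=any(h.exceeded for h in lags),
    )


def simulate_polling_delay(
    config: LatencyConfig, n: int, seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo end-to-end delays in minutes, each hop uniform on [0, max].

    The uniform-on-[0, max] hop model is a modelling choice; only the maxima
    are published.  max(sample) <= worst_case_delay by construction.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for dur in config.hops.values():
        total += rng.uniform(0.0, dur.total_seconds() / 60.0, size=n)
    return total


def load_latency_config(source) -> LatencyConfig:
    """Load hop maxima from YAML: mapping ``hop name -> minutes``."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("latency YAML must be a mapping of hop name to minutes")
    hops = dict(_default_hops())
    section = doc.get("latency", doc)
    for name, minutes in section.items():
        if name not in HOP_NAMES:
            raise ConfigError(f"unknown hop {name!r}; expected one of {HOP_NAMES}")
        hops[name] = timedelta(minutes=float(minutes))
    return LatencyConfig(hops=hops)


def read_hops_csv(stream) -> list[HopTimestamps]:
    """Read hop records: one row per measurement, ISO timestamp columns, blank = missing."""
    if isinstance(stream, str) and "\n" not in stream:
        with open(stream, "r", encoding="utf-8", newline="") as fh:
            return read_hops_csv(fh)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    if not reader.fieldnames or "measured_at" not in reader.fieldnames:
        raise ResultValidationError("hops CSV must have a measured_at column")
    out: list[HopTimestamps] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            kwargs = {}
            for stage in STAGES:
                raw = (row.get(stage) or "").strip()
                kwargs[stage] = datetime.fromisoformat(raw) if raw else None
            if kwargs["measured_at"] is None:
                raise ValueError("measured_at empty")
            out.append(HopTimestamps(**kwargs))
        except ValueError as exc:
            raise ResultValidationError(f"hops CSV line {lineno}: {exc}") from exc
    return out
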