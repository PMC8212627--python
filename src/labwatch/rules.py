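"""Stateless classification rules for critical laboratory values.

Five active algorithms ship by default (hypokalemia, hypercalcemia,
hyponatremia, hyperlactatemia, acute kidney injury) plus two inactive
stubs awaiting published rule sets.  Threshold rules are pure functions of
a single value; the kidney-injury rule classifies a creatinine history
against a rolling 7-day baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum, IntEnum
from typing import TYPE_CHECKING, Mapping, Sequence

import yaml

from .errors import ConfigError, ResultValidationError, RuleApplicationError

if TYPE_CHECKING:  # pragma: no cover
    from .hl7_io import LabResult

__all__ = [
    "Parameter",
    "Severity",
    "Comparator",
    "WarningBand",
    "IMMEDIATE",
    "RuleSet",
    "AkiCriterion",
    "AkiAssessment",
    "build_default_rulesets",
    "load_rulesets",
    "dump_rulesets",
    "evaluate_threshold_rule",
    "classify_aki",
    "severity_for_aki",
    "annotate_result",
]


class Parameter(Enum):
    """Supported analytes; values are the short wire codes used in HL7/CSV."""

    K = "K"
    NA = "NA"
    CA_TOTAL = "CA"
    CA_IONIZED = "CAI"
    LACTATE = "LACT"
    CREATININE = "CREA"

    @property
    def canonical_units(self) -> str:
        return "umol/L" if self is Parameter.CREATININE else "mmol/L"


class Severity(IntEnum):
    """Traffic-light severity; total order GREEN < YELLOW < RED."""

    GREEN = 0
    YELLOW = 1
    RED = 2

    def __str__(self) -> str:  # noqa: D105
        return self.name


@dataclass(frozen=True)
class Comparator:
    """A one-sided predicate ``value <op> threshold`` in canonical units."""

    op: str  # one of "<", ">", "<=", ">="
    threshold: float

    _OPS = {
        "<": lambda v, t: v < t,
        ">": lambda v, t: v > t,
        "<=": lambda v, t: v <= t,
        ">=": lambda v, t: v >= t,
    }

    def __post_init__(self) -> None:
        if self.op not in self._OPS:
            raise ConfigError(f"unknown comparator op {self.op!r}")

    def check(self, value: float) -> bool:
        return self._OPS[self.op](value, self.threshold)

    def __str__(self) -> str:
        return f"{self.op}{self.threshold:g}"


@dataclass(frozen=True)
class WarningBand:
    """Closed interval [low, high] mapped to YELLOW when no critical predicate holds.

    Warning bands are not part of the published rule tables; the shipped
    defaults are local choices and fully overridable in the rules YAML.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ConfigError(f"warning band low {self.low} > high {self.high}")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


class _ImmediateType:
    """Sentinel: the rule escalates at detection, no time-to-control timer."""

    _instance: "_ImmediateType | None" = None

    def __new__(cls) -> "_ImmediateType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "IMMEDIATE"


IMMEDIATE = _ImmediateType()


@dataclass(frozen=True)
class RuleSet:
    """One surveillance algorithm: predicate(s), warning band(s), TTC, diagnosis."""

    algorithm_id: str
    parameters: tuple[Parameter, ...]
    critical: Mapping[Parameter, Comparator] = field(default_factory=dict)
    warning: Mapping[Parameter, WarningBand] = field(default_factory=dict)
    ttc: timedelta | _ImmediateType | None = None
    diagnosis: str = ""
    active: bool = True
    kind: str = "threshold"  # "threshold" | "aki" | "stub"

    def __post_init__(self) -> None:
        if isinstance(self.ttc, timedelta) and self.ttc <= timedelta(0):
            raise ConfigError(f"{self.algorithm_id}: ttc must be positive or IMMEDIATE")
        for p, band in self.warning.items():
            crit = self.critical.get(p)
            if crit is None:
                continue
            # warning band must sit strictly on the safe side of the critical predicate
            if crit.check(band.low) and crit.check(band.high):
                raise ConfigError(
                    f"{self.algorithm_id}: warning band for {p.name} inside critical range"
                )

    @property
    def ttc_is_immediate(self) -> bool:
        return self.ttc is IMMEDIATE

    def watches(self, parameter: Parameter) -> bool:
        return parameter in self.parameters


class AkiCriterion(Enum):
    NONE = "NONE"
    DELTA_48H = "DELTA_48H"
    RATIO = "RATIO"
    ABSOLUTE = "ABSOLUTE"


@dataclass(frozen=True)
class AkiAssessment:
    """Kidney-injury staging outcome for the latest creatinine in a history."""

    stage: int
    baseline_value: float
    trigger_value: float
    criterion: AkiCriterion

    def __post_init__(self) -> None:
        if (self.stage == 0) != (self.criterion is AkiCriterion.NONE):
            raise ResultValidationError("stage 0 iff criterion NONE")


# Staging constants: 26.5 umol/L = 0.3 mg/dL, 354 umol/L = 4 mg/dL at 88.4 umol/L per mg/dL.
AKI_DELTA_UMOL_L = 26.5
AKI_ABSOLUTE_UMOL_L = 354.0
AKI_RATIO_STAGE1 = 1.5
AKI_RATIO_STAGE2 = 2.0
AKI_RATIO_STAGE3 = 3.0
AKI_BASELINE_WINDOW = timedelta(days=7)
AKI_DELTA_WINDOW = timedelta(hours=48)

MG_DL_TO_UMOL_L = 88.4


def build_default_rulesets() -> list[RuleSet]:
    """Return the default rule configuration: 5 active algorithms + 2 inactive stubs.

    Critical thresholds and TTC values follow the published rule table;
    warning (YELLOW) bands are local defaults, see :class:`WarningBand`.
    """
    return [
        RuleSet(
            algorithm_id="hypokalemia",
            parameters=(Parameter.K,),
            critical={Parameter.K: Comparator("<", 2.5)},
            warning={Parameter.K: WarningBand(2.5, 3.0)},
            ttc=timedelta(hours=6),
            diagnosis="Hypokalemia",
        ),
        RuleSet(
            algorithm_id="hypercalcemia",
            parameters=(Parameter.CA_TOTAL, Parameter.CA_IONIZED),
            critical={
                Parameter.CA_TOTAL: Comparator(">", 3.5),
                Parameter.CA_IONIZED: Comparator(">", 2.0),
            },
            warning={
                Parameter.CA_TOTAL: WarningBand(3.0, 3.5),
                Parameter.CA_IONIZED: WarningBand(1.6, 2.0),
            },
            ttc=timedelta(hours=12),
            diagnosis="Hypercalcemia",
        ),
        RuleSet(
            algorithm_id="hyponatremia",
            parameters=(Parameter.NA,),
            critical={Parameter.NA: Comparator("<", 120.0)},
            warning={Parameter.NA: WarningBand(120.0, 125.0)},
            ttc=timedelta(hours=12),
            diagnosis="Hyponatremia",
        ),
        RuleSet(
            algorithm_id="hyperlactatemia",
            parameters=(Parameter.LACTATE,),
            critical={Parameter.LACTATE: Comparator(">", 4.0)},
            warning={Parameter.LACTATE: WarningBand(2.5, 4.0)},
            ttc=timedelta(hours=6),
            diagnosis="Hyperlactatemia",
        ),
        RuleSet(
            algorithm_id="acute_kidney_injury",
            parameters=(Parameter.CREATININE,),
            ttc=IMMEDIATE,
            diagnosis="Acute kidney injury",
            kind="aki",
        ),
        RuleSet(
            algorithm_id="sepsis",
            parameters=(),
            diagnosis="Sepsis",
            active=False,
            kind="stub",
        ),
        RuleSet(
            algorithm_id="myocardial_infarction",
            parameters=(),
            diagnosis="Myocardial infarction",
            active=False,
            kind="stub",
        ),
    ]


def evaluate_threshold_rule(rule: RuleSet, result: "LabResult") -> Severity:
    """Classify one result under a simple-threshold rule.

    RED when the critical predicate holds, YELLOW when only the warning band
    holds, GREEN otherwise.  Boundary strictness follows the comparator
    exactly (e.g. K = 2.5 mmol/L is not critical under ``< 2.5``).
    """
    if rule.kind != "threshold":
        raise RuleApplicationError(f"{rule.algorithm_id} is not a simple-threshold rule")
    param = result.parameter
    if not rule.watches(param):
        raise RuleApplicationError(
            f"rule {rule.algorithm_id} does not watch parameter {param.name}"
        )
    value = result.value
    if value is None or not math.isfinite(value):
        raise ResultValidationError(f"non-finite value for {param.name}: {value!r}")
    crit = rule.critical.get(param)
    if crit is not None and crit.check(value):
        return Severity.RED
    band = rule.warning.get(param)
    if band is not None and band.contains(value):
        return Severity.YELLOW
    return Severity.GREEN


def _as_points(history: Sequence) -> list[tuple[datetime, float]]:
    points: list[tuple[datetime, float]] = []
    for item in history:
        if isinstance(item, tuple):
            t, v = item
        else:
            t, v = item.measured_at, item.value
        points.append((t, float(v)))
    return points


def classify_aki(
    history: Sequence, now: datetime | None = None
) -> AkiAssessment:
    """Stage the latest creatinine of a time-ordered history (values in umol/L).

    Baseline = minimum creatinine within the 7 days preceding the latest
    result (latest excluded).  A first-ever value has no baseline and cannot
    trigger.  Stage 1: rise >= 26.5 umol/L within 48 h, or latest/baseline
    >= 1.5.  Stage 2: ratio > 2.0.  Stage 3: ratio > 3.0, or latest >= 354
    umol/L together with an acute 48 h rise >= 26.5 umol/L.
    """
    points = _as_points(history)
    if not points:
        raise ResultValidationError("empty creatinine history")
    for t_prev, t_next in zip(points, points[1:]):
        if t_next[0] < t_prev[0]:
            raise ResultValidationError("creatinine history timestamps not ascending")
    latest_t, latest_v = points[-1]
    if latest_v <= 0 or any(v <= 0 for _, v in points):
        raise ResultValidationError("creatinine values must be > 0")

    prior = [
        (t, v)
        for (t, v) in points[:-1]
        if latest_t - t <= AKI_BASELINE_WINDOW
    ]
    if not prior:
        return AkiAssessment(0, latest_v, latest_v, AkiCriterion.NONE)

    baseline = min(v for _, v in prior)
    ratio = latest_v / baseline
    delta_48h = any(
        latest_t - t <= AKI_DELTA_WINDOW and latest_v - v >= AKI_DELTA_UMOL_L
        for (t, v) in prior
    )

    if ratio > AKI_RATIO_STAGE3:
        return AkiAssessment(3, baseline, latest_v, AkiCriterion.RATIO)
    if latest_v >= AKI_ABSOLUTE_UMOL_L and delta_48h:
        return AkiAssessment(3, baseline, latest_v, AkiCriterion.ABSOLUTE)
    if ratio > AKI_RATIO_STAGE2:
        return AkiAssessment(2, baseline, latest_v, AkiCriterion.RATIO)
    if ratio >= AKI_RATIO_STAGE1:
        return AkiAssessment(1, baseline, latest_v, AkiCriterion.RATIO)
    if delta_48h:
        return AkiAssessment(1, baseline, latest_v, AkiCriterion.DELTA_48H)
    return AkiAssessment(0, baseline, latest_v, AkiCriterion.NONE)


DEFAULT_AKI_SEVERITY: Mapping[int, Severity] = {
    0: Severity.GREEN,
    1: Severity.YELLOW,
    2: Severity.RED,
    3: Severity.RED,
}


def severity_for_aki(
    assessment: AkiAssessment,
    mapping: Mapping[int, Severity] = DEFAULT_AKI_SEVERITY,
) -> Severity:
    """Map a kidney-injury stage to a traffic-light color (configurable)."""
    return mapping[assessment.stage]


# Sub-bands recorded as free-text annotations on an alert, never as a
# separate severity level.
_ANNOTATION_BANDS: dict[Parameter, list[tuple[float, str]]] = {
    Parameter.K: [
        (1.9, "acutely life-threatening hypokalemia (K <= 1.9 mmol/L)"),
        (2.0, "severe hypokalemia (K <= 2.0 mmol/L)"),
    ],
}


def annotate_result(parameter: Parameter, value: float) -> list[str]:
    """Return sub-band annotations for a value (e.g. severe hypokalemia)."""
    for cutoff, text in _ANNOTATION_BANDS.get(parameter, []):
        if value <= cutoff:
            return [text]
    return []


# ---------------------------------------------------------------------------
# YAML rule configuration


def _comparator_to_yaml(c: Comparator) -> dict:
    return {"op": c.op, "threshold": c.threshold}


def dump_rulesets(rulesets: Sequence[RuleSet]) -> str:
    """Serialize rule sets to the YAML configuration format."""
    docs = []
    for r in rulesets:
        entry: dict = {
            "algorithm_id": r.algorithm_id,
            "parameters": [p.name for p in r.parameters],
            "kind": r.kind,
            "diagnosis": r.diagnosis,
            "active": r.active,
        }
        if r.critical:
            entry["critical"] = {
                p.name: _comparator_to_yaml(c) for p, c in r.critical.items()
            }
        if r.warning:
            entry["warning"] = {
                p.name: {"low": b.low, "high": b.high} for p, b in r.warning.items()
            }
        if r.ttc is IMMEDIATE:
            entry["ttc_hours"] = "immediate"
        elif isinstance(r.ttc, timedelta):
            entry["ttc_hours"] = r.ttc.total_seconds() / 3600.0
        else:
            entry["ttc_hours"] = None
        docs.append(entry)
    return yaml.safe_dump({"rulesets": docs}, sort_keys=False)


def _param(name: str) -> Parameter:
    """Resolve a parameter by enum member name or wire code."""
    try:
        return Parameter[name]
    except KeyError:
        try:
            return Parameter(name)
        except ValueError:
            raise ConfigError(f"unknown parameter {name!r}") from None


def load_rulesets(source) -> list[RuleSet]:
    """Load rule sets from a YAML path, file object, or string."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "rulesets" not in doc:
        raise ConfigError("rules YAML must contain a top-level 'rulesets' list")
    out: list[RuleSet] = []
    for entry in doc["rulesets"]:
        try:
            params = tuple(_param(p) for p in entry.get("parameters", []))
            critical = {
                _param(p): Comparator(spec["op"], float(spec["threshold"]))
                for p, spec in (entry.get("critical") or {}).items()
            }
            warning = {
                _param(p): WarningBand(float(spec["low"]), float(spec["high"]))
                for p, spec in (entry.get("warning") or {}).items()
            }
            raw_ttc = entry.get("ttc_hours")
            ttc: timedelta | _ImmediateType | None
            if raw_ttc is None:
                ttc = None
            elif isinstance(raw_ttc, str) and raw_ttc.lower() == "immediate":
                ttc = IMMEDIATE
            else:
                ttc = timedelta(hours=float(raw_ttc))
            out.append(
                RuleSet(
                    algorithm_id=entry["algorithm_id"],
                    parameters=params,
                    critical=critical,
                    warning=warning,
                    ttc=ttc,
                    diagnosis=entry.get("diagnosis", ""),
                    active=bool(entry.get("active", True)),
                    kind=entry.get("kind", "threshold"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad rule entry {entry!r}: {exc}") from exc
    return out
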