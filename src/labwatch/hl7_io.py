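"""Read/write laboratory results as simplified HL7 v2 ORU^R01 and as CSV.

The HL7 dialect is v2.3-style pipe-delimited text: only MSH, PID, PV1, OBR
and OBX segments are consumed, unknown segments are ignored, and one
ORU^R01 message maps to one :class:`MessageEnvelope`.  Six core fields are
validated on every result: measurement timestamp, patient id, case id,
order id, parameter and value.  Unit conversion to canonical units happens
here, never inside the rules.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from datetime import datetime
from enum import Enum
from typing import Iterable, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigError, ParseError, ResultValidationError, UnitError
from .rules import MG_DL_TO_UMOL_L, Parameter

__all__ = [
    "Source",
    "LabResult",
    "MessageEnvelope",
    "parse_oru_message",
    "parse_oru_file",
    "write_oru_message",
    "write_oru_file",
    "read_results_csv",
    "write_results_csv",
    "convert_to_canonical",
    "load_code_table",
    "CSV_COLUMNS",
]


class Source(Enum):
    LAB = "LAB"
    POCT = "POCT"
    SIMULATED = "SIMULATED"


class LabResult(BaseModel):
    """One timestamped measurement of one parameter for one patient/case/order."""

    model_config = ConfigDict(frozen=True)

    measured_at: datetime
    patient_id: str
    case_id: str
    order_id: str
    parameter: Parameter
    value: float
    raw_units: str = ""
    source: Source = Source.LAB

    @field_validator("patient_id", "case_id", "order_id")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("identifier must be non-empty")
        return v

    @field_validator("value")
    @classmethod
    def _finite_positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"value must be finite and > 0, got {v!r}")
        return v

    @model_validator(mode="before")
    @classmethod
    def _default_units(cls, data):
        if isinstance(data, dict) and not data.get("raw_units"):
            param = data.get("parameter")
            if isinstance(param, str):
                param = Parameter.__members__.get(param) or Parameter(param)
            if isinstance(param, Parameter):
                data = {**data, "raw_units": param.canonical_units}
        return data

    @property
    def dedup_identity(self) -> tuple:
        """Identity used for exact-duplicate suppression on ingest."""
        return (self.patient_id, self.parameter, self.measured_at, self.value)


class MessageEnvelope(BaseModel):
    model_config = ConfigDict(frozen=True)

    message_id: str
    sent_at: datetime
    sender: str = "labwatch"
    results: tuple[LabResult, ...]

    @field_validator("results")
    @classmethod
    def _non_empty_results(cls, v):
        if not v:
            raise ValueError("envelope must contain at least one result")
        return v


# ---------------------------------------------------------------------------
# Units

# Per-parameter accepted units -> multiplicative factor to canonical units.
# Canonical: mmol/L everywhere except creatinine (umol/L).
_UNIT_FACTORS: dict[Parameter, dict[str, float]] = {
    Parameter.K: {"mmol/l": 1.0, "meq/l": 1.0},
    Parameter.NA: {"mmol/l": 1.0, "meq/l": 1.0},
    Parameter.CA_TOTAL: {"mmol/l": 1.0},
    Parameter.CA_IONIZED: {"mmol/l": 1.0},
    Parameter.LACTATE: {"mmol/l": 1.0},
    Parameter.CREATININE: {"umol/l": 1.0, "µmol/l": 1.0, "mg/dl": MG_DL_TO_UMOL_L},
}


def convert_to_canonical(parameter: Parameter, value: float, units: str) -> float:
    """Convert a value to the parameter's canonical units.

    Raises :class:`UnitError` for units with no known conversion.
    """
    key = (units or parameter.canonical_units).strip().lower()
    factors = _UNIT_FACTORS[parameter]
    if key not in factors:
        raise UnitError(
            f"no conversion from {units!r} to {parameter.canonical_units} "
            f"for {parameter.name}"
        )
    return value * factors[key]


# ---------------------------------------------------------------------------
# Parameter code table

# Default wire-code table; overridable via YAML (load_code_table).
DEFAULT_CODE_TABLE: dict[str, Parameter] = {
    "K": Parameter.K,
    "POTASSIUM": Parameter.K,
    "NA": Parameter.NA,
    "SODIUM": Parameter.NA,
    "CA": Parameter.CA_TOTAL,
    "CALCIUM": Parameter.CA_TOTAL,
    "CAI": Parameter.CA_IONIZED,
    "CA_ION": Parameter.CA_IONIZED,
    "LACT": Parameter.LACTATE,
    "LACTATE": Parameter.LACTATE,
    "CREA": Parameter.CREATININE,
    "CREATININE": Parameter.CREATININE,
}
# Accept enum member names too (CA_TOTAL, CA_IONIZED, ...).
DEFAULT_CODE_TABLE.update({p.name: p for p in Parameter})


def load_code_table(source) -> dict[str, Parameter]:
    """Load a ``code -> parameter`` table from YAML (mapping of code to member name)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("code table YAML must be a mapping")
    try:
        return {str(k).upper(): Parameter[str(v)] for k, v in doc.items()}
    except KeyError as exc:
        raise ConfigError(f"unknown parameter name in code table: {exc}") from exc


# ---------------------------------------------------------------------------
# HL7 timestamps

_HL7_TS_FORMATS = ("%Y%m%d%H%M%S", "%Y%m%d%H%M", "%Y%m%d")


def parse_hl7_ts(text: str, context: str) -> datetime:
    raw = text.strip().split(".")[0].split("+")[0].split("-")[0]
    for fmt in _HL7_TS_FORMATS:
        try:
            return datetime.strptime(raw, fmt)
        except ValueError:
            continue
    raise ParseError(f"{context}: unparseable HL7 timestamp {text!r}")


def format_hl7_ts(dt: datetime) -> str:
    return dt.strftime("%Y%m%d%H%M%S")


# ---------------------------------------------------------------------------
# HL7 parsing


def _split_segments(text: str) -> list[list[str]]:
    lines = [ln for ln in text.replace("\r\n", "\n").replace("\r", "\n").split("\n")]
    return [ln.split("|") for ln in lines if ln.strip()]


def _field(fields: list[str], idx: int) -> str:
    return fields[idx] if idx < len(fields) else ""


def _first_component(value: str) -> str:
    return value.split("^")[0]


def parse_oru_message(
    text: str,
    *,
    code_table: dict[str, Parameter] | None = None,
    strict: bool = False,
    source: Source = Source.LAB,
) -> MessageEnvelope:
    """Parse one pipe-delimited ORU^R01 message into a :class:`MessageEnvelope`.

    Field mapping: PID-3 -> patient_id, PV1-19 -> case_id, OBR-2 -> order_id,
    OBX-3 -> parameter (via code table), OBX-5 -> value, OBX-6 -> units,
    OBX-14 (fallback OBR-7) -> measured_at.  Unknown parameter codes are
    skipped with a warning unless ``strict``.
    """
    table = code_table or DEFAULT_CODE_TABLE
    segments = _split_segments(text)
    if not segments or segments[0][0] != "MSH":
        raise ParseError("MSH segment missing or not first")
    msh = segments[0]
    message_id = _field(msh, 9)
    if not message_id:
        raise ParseError("MSH-10 empty (message control id)")
    sent_raw = _field(msh, 6)
    sender = _field(msh, 3) or "unknown"

    patient_id = ""
    case_id = ""
    order_id = ""
    obr_ts: datetime | None = None
    saw_pid = saw_obr = False
    results: list[LabResult] = []

    for seg in segments[1:]:
        kind = seg[0]
        if kind == "PID":
            saw_pid = True
            patient_id = _first_component(_field(seg, 3)).strip()
            if not patient_id:
                raise ParseError("PID-3 empty (patient id)")
        elif kind == "PV1":
            case_id = _first_component(_field(seg, 19)).strip()
        elif kind == "OBR":
            saw_obr = True
            order_id = _first_component(_field(seg, 2)).strip()
            if not order_id:
                raise ParseError("OBR-2 empty (order id)")
            raw = _field(seg, 7)
            obr_ts = parse_hl7_ts(raw, "OBR-7") if raw else None
        elif kind == "OBX":
            if not saw_pid:
                raise ParseError("OBX before PID segment")
            if not saw_obr:
                raise ParseError("OBX before OBR segment")
            code = _first_component(_field(seg, 3)).strip().upper()
            if code not in table:
                if strict:
                    raise ParseError(f"OBX-3 unknown parameter code {code!r}")
                warnings.warn(f"skipping OBX with unknown parameter code {code!r}")
                continue
            parameter = table[code]
            raw_value = _field(seg, 5).strip()
            if not raw_value:
                raise ParseError("OBX-5 empty (value)")
            try:
                value = float(raw_value)
            except ValueError:
                if _field(seg, 2) == "NM" or strict:
                    raise ParseError(f"OBX-5 non-numeric value {raw_value!r}")
                continue  # non-numeric observation, not ours
            units = _field(seg, 6).strip()
            ts_raw = _field(seg, 14).strip()
            if ts_raw:
                measured_at = parse_hl7_ts(ts_raw, "OBX-14")
            elif obr_ts is not None:
                measured_at = obr_ts
            else:
                raise ParseError("OBX-14 and OBR-7 both empty (measurement time)")
            if not case_id:
                raise ParseError("PV1-19 empty (case id)")
            src_raw = _field(seg, 15).strip().upper()
            obx_source = (
                Source[src_raw] if src_raw in Source.__members__ else source
            )
            try:
                canonical = convert_to_canonical(parameter, value, units)
                results.append(
                    LabResult(
                        measured_at=measured_at,
                        patient_id=patient_id,
                        case_id=case_id,
                        order_id=order_id,
                        parameter=parameter,
                        value=canonical,
                        raw_units=units or parameter.canonical_units,
                        source=obx_source,
                    )
                )
            except (UnitError, ValueError) as exc:
                raise ParseError(f"OBX for {parameter.name}: {exc}") from exc
    if not saw_pid:
        raise ParseError("PID segment missing")
    if not saw_obr:
        raise ParseError("OBR segment missing")
    if not results:
        raise ParseError("message contains no usable OBX result")
    sent_at = parse_hl7_ts(sent_raw, "MSH-7") if sent_raw else results[0].measured_at
    return MessageEnvelope(
        message_id=message_id, sent_at=sent_at, sender=sender, results=tuple(results)
    )


def parse_oru_file(
    text: str, **kwargs
) -> list[MessageEnvelope]:
    """Parse a file containing one or more ORU messages (split at MSH segments)."""
    normalized = text.replace("\r\n", "\n").replace("\r", "\n")
    chunks: list[list[str]] = []
    for line in normalized.split("\n"):
        if not line.strip():
            continue
        if line.startswith("MSH|"):
            chunks.append([line])
        elif chunks:
            chunks[-1].append(line)
        else:
            raise ParseError("content before first MSH segment")
    return [parse_oru_message("\n".join(chunk), **kwargs) for chunk in chunks]


# ---------------------------------------------------------------------------
# HL7 writing


def _format_value(v: float) -> str:
    return repr(v) if not v.is_integer() else str(int(v))


def write_oru_message(envelope: MessageEnvelope) -> str:
    """Serialize an envelope to pipe-delimited ORU^R01 text.

    Deterministic segment order: MSH, PID, PV1, then one OBR per order id
    run with its OBX segments.  ``parse_oru_message`` accepts the output and
    round-trips every result field.
    """
    first = envelope.results[0]
    lines = [
        "MSH|^~\\&|{sender}|||{ts}|{ts}||ORU^R01|{mid}|P|2.3".format(
            sender=envelope.sender,
            ts=format_hl7_ts(envelope.sent_at),
            mid=envelope.message_id,
        ),
        f"PID|1||{first.patient_id}",
        "PV1|1" + "|" * 17 + f"|{first.case_id}",
    ]
    obr_n = 0
    obx_n = 0
    current_order: str | None = None
    for r in envelope.results:
        if r.patient_id != first.patient_id or r.case_id != first.case_id:
            raise ResultValidationError(
                "one envelope carries results of a single patient/case"
            )
        if r.order_id != current_order:
            obr_n += 1
            obx_n = 0
            current_order = r.order_id
            lines.append(
                f"OBR|{obr_n}|{r.order_id}|||||{format_hl7_ts(r.measured_at)}"
            )
        obx_n += 1
        # OBX-15 (producer id) carries the result source so it round-trips
        lines.append(
            "OBX|{n}|NM|{code}||{value}|{units}|||||F|||{ts}|{src}".format(
                n=obx_n,
                code=r.parameter.value,
                value=_format_value(r.value),
                units=r.parameter.canonical_units,
                ts=format_hl7_ts(r.measured_at),
                src=r.source.value,
            )
        )
    return "\n".join(lines) + "\n"


def write_oru_file(envelopes: Iterable[MessageEnvelope]) -> str:
    return "".join(write_oru_message(e) for e in envelopes)


# ---------------------------------------------------------------------------
# CSV fixture format

CSV_COLUMNS = (
    "measured_at",
    "patient_id",
    "case_id",
    "order_id",
    "parameter",
    "value",
    "units",
)


def read_results_csv(stream) -> list[LabResult]:
    """Read the CSV fixture format; same validation as the HL7 path.

    Errors carry the 1-based line number of the offending row.
    """
    if isinstance(stream, str) and "\n" not in stream:
        with open(stream, "r", encoding="utf-8", newline="") as fh:
            return read_results_csv(fh)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ParseError(f"CSV header missing columns: {sorted(missing)}")
    out: list[LabResult] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            code = row["parameter"].strip().upper()
            if code not in DEFAULT_CODE_TABLE:
                raise ParseError(f"unknown parameter code {code!r}")
            parameter = DEFAULT_CODE_TABLE[code]
            value = float(row["value"])
            units = (row.get("units") or "").strip()
            canonical = convert_to_canonical(parameter, value, units)
            raw_source = (row.get("source") or "LAB").strip().upper()
            out.append(
                LabResult(
                    measured_at=datetime.fromisoformat(row["measured_at"].strip()),
                    patient_id=row["patient_id"].strip(),
                    case_id=row["case_id"].strip(),
                    order_id=row["order_id"].strip(),
                    parameter=parameter,
                    value=canonical,
                    raw_units=units or parameter.canonical_units,
                    source=Source[raw_source],
                )
            )
        except (ParseError, UnitError, ValueError, KeyError) as exc:
            raise ParseError(f"CSV line {lineno}: {exc}") from exc
    return out


def write_results_csv(results: Sequence[LabResult], stream=None) -> str:
    """Write results in the CSV fixture format; returns the text."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS + ("source",))
    for r in results:
        writer.writerow(
            (
                r.measured_at.isoformat(),
                r.patient_id,
                r.case_id,
                r.order_id,
                r.parameter.value,
                _format_value(r.value),
                r.parameter.canonical_units,
                r.source.value,
            )
        )
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text
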