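"""Random small event streams shared by the engine property tests."""

from datetime import datetime, timedelta

from labwatch.engine import Engine, EngineConfig
from labwatch.hl7_io import LabResult, Source
from labwatch.rules import Parameter

START = datetime(2021, 3, 1, 0, 0, 0)

# Value pools straddle the GREEN/YELLOW/RED boundaries of every rule.
VALUE_POOLS = {
    Parameter.K: [1.8, 2.2, 2.4, 2.5, 2.7, 3.2, 4.0],
    Parameter.NA: [112.0, 118.0, 119.9, 120.0, 123.0, 130.0, 140.0],
    Parameter.LACTATE: [0.9, 2.6, 3.9, 4.0, 4.1, 6.0],
    Parameter.CA_TOTAL: [2.4, 3.2, 3.5, 3.6, 4.0],
    Parameter.CA_IONIZED: [1.2, 1.7, 2.0, 2.1, 2.3],
    Parameter.CREATININE: [70.0, 90.0, 110.0, 150.0, 250.0, 400.0],
}

PATIENT_POOL = ["1001", "1002", "1003", "1004"]  # mixed parity

ALGORITHMS = [
    "ALL",
    "hypokalemia",
    "hyponatremia",
    "hyperlactatemia",
    "hypercalcemia",
    "acute_kidney_injury",
]


def random_events(rng, n_events=12, with_admin=True):
    """Generate an in-order event log with native-typed dicts (oracle shape)."""
    params = list(VALUE_POOLS)
    patients = list(rng.choice(PATIENT_POOL, size=int(rng.integers(1, 4)), replace=False))
    t = START
    events = []
    seen_patients = []
    for _ in range(n_events):
        t = t + timedelta(minutes=int(rng.integers(10, 600)))
        roll = float(rng.random())
        if roll < 0.65 or not seen_patients:
            pid = str(rng.choice(patients))
            param = params[int(rng.integers(0, len(params)))]
            value = float(rng.choice(VALUE_POOLS[param]))
            events.append(
                {"type": "result", "at": t, "patient_id": pid,
                 "parameter": param, "value": value}
            )
            if pid not in seen_patients:
                seen_patients.append(pid)
        elif roll < 0.82:
            events.append({"type": "tick", "at": t})
        elif roll < 0.91 and with_admin:
            events.append(
                {"type": "silence",
                 "patient_id": str(rng.choice(seen_patients)),
                 "algorithm_id": str(rng.choice(ALGORITHMS)),
                 "flag": bool(rng.random() < 0.7)}
            )
        else:
            events.append(
                {"type": "ack", "patient_id": str(rng.choice(seen_patients)),
                 "actor": "nurse", "at": t}
            )
    # drain all TTC timers well past the longest deadline
    events.append({"type": "tick", "at": t + timedelta(hours=13)})
    return events


def _to_result(ev, order_n):
    return LabResult(
        measured_at=ev["at"],
        patient_id=ev["patient_id"],
        case_id=f"C{ev['patient_id']}",
        order_id=f"O{order_n:05d}",
        parameter=ev["parameter"],
        value=ev["value"],
        source=Source.SIMULATED,
    )


def apply_events(events, config=None, duplicate_every=None):
    """Feed native events into a fresh engine; optionally re-ingest every
    ``duplicate_every``-th result immediately (exercises dedup)."""
    engine = Engine(config or EngineConfig())
    order_n = 0
    n_results = 0
    for ev in events:
        if ev["type"] == "result":
            order_n += 1
            n_results += 1
            r = _to_result(ev, order_n)
            engine.ingest(r)
            if duplicate_every and n_results % duplicate_every == 0:
                engine.ingest(r)
        elif ev["type"] == "tick":
            engine.tick(ev["at"])
        elif ev["type"] == "ack":
            engine.acknowledge(ev["patient_id"], ev["actor"], ev["at"])
        elif ev["type"] == "silence":
            engine.set_silence(ev["patient_id"], ev["algorithm_id"], ev["flag"])
    return engine
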