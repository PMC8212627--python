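# labwatch

A self-contained surveillance engine for critical laboratory values. It
consumes streams of laboratory results (simplified HL7 v2 ORU^R01, a CSV
fixture format, or a built-in seeded ward simulator), applies explicit
critical-value rule sets with time-to-control (TTC) escalation timers,
maintains traffic-light patient states, and emits auditable notifications —
no hospital integration required.

## What it does

- **Rules** (`labwatch.rules`): five active algorithms — hypokalemia
  (K < 2.5 mmol/L, TTC 6 h), hypercalcemia (total Ca > 3.5 or ionized
  Ca > 2.0 mmol/L, 12 h), hyponatremia (Na < 120 mmol/L, 12 h),
  hyperlactatemia (lactate > 4 mmol/L, 6 h) and acute kidney injury
  (creatinine staged 1–3 against a rolling 7-day baseline, immediate) —
  plus two inactive stubs (sepsis, myocardial infarction). Thresholds,
  warning bands and TTCs are configurable via YAML
  (`src/labwatch/data/default_rules.yaml`).
- **IO** (`labwatch.hl7_io`): pipe-delimited ORU^R01 parsing/writing
  (MSH/PID/PV1/OBR/OBX) and a CSV fixture format, both validating the six
  core fields (timestamp, patient id, case id, order id, parameter, value)
  and converting units to canonical form at ingest.
- **Engine** (`labwatch.engine`): event-sourced state with per-patient,
  per-algorithm alert episodes, exactly-once TTC escalation via explicit
  `tick()`, duplicate-message idempotency, checkmark acknowledgment,
  per-patient/per-algorithm silencing, and control-vs-intervention arm
  suppression by patient-id parity (odd = control, even = intervention).
- **Reporting** (`labwatch.reporting`): ward overview rows (traffic-light
  summary = max severity; empty/STALE column past 2× the 600-second
  terminal poll), per-patient reports, phone-list export and call
  documentation with the two feedback questions.
- **Latency** (`labwatch.latency`): worst-case end-to-end delay from hop
  polling maxima (15 + 60 + 10 = 85 minutes by default), Monte-Carlo
  polling-delay simulation, and per-hop delay attribution from observed
  timestamps.
- **Simulator** (`labwatch.simulator`): seeded synthetic ward streams with
  configurable critical-value prevalence and per-arm clinician response
  delays, plus per-arm time-to-control outcome statistics.

## CLI

```sh
# run the engine over a message file and export all reports
labwatch run --input ward.hl7 --format hl7 --out out/
labwatch run --input results.csv --format csv --out out/ --drain-hours 8

# seeded simulation: events.jsonl, fixture.hl7, results.csv, ttc_outcomes.csv
labwatch simulate --seed 42 --out sim/

# attribute observed notification delays to pipeline components
labwatch audit --hops hops.csv

# replay an event log and print one patient's report
labwatch report --state out/events.jsonl --patient 1002
```

Every run writes a `provenance.json` header (version, seed, config hash).

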