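# Default rule configuration: 5 active algorithms + 2 inactive stubs.
# Critical thresholds and TTC follow the published rule table; warning
# (YELLOW) bands are local defaults and may be overridden freely.
rulesets:
- algorithm_id: hypokalemia
  parameters: [K]
  kind: threshold
  diagnosis: Hypokalemia
  active: true
  critical:
    K: {op: "<", threshold: 2.5}
  warning:
    K: {low: 2.5, high: 3.0}
  ttc_hours: 6
- algorithm_id: hypercalcemia
  parameters: [CA_TOTAL, CA_IONIZED]
  kind: threshold
  diagnosis: Hypercalcemia
  active: true
  critical:
    CA_TOTAL: {op: ">", threshold: 3.5}
    CA_IONIZED: {op: ">", threshold: 2.0}
  warning:
    CA_TOTAL: {low: 3.0, high: 3.5}
    CA_IONIZED: {low: 1.6, high: 2.0}
  ttc_hours: 12
- algorithm_id: hyponatremia
  parameters: [NA]
  kind: threshold
  diagnosis: Hyponatremia
  active: true
  critical:
    NA: {op: "<", threshold: 120.0}
  warning:
    NA: {low: 120.0, high: 125.0}
  ttc_hours: 12
- algorithm_id: hyperlactatemia
  parameters: [LACTATE]
  kind: threshold
  diagnosis: Hyperlactatemia
  active: true
  critical:
    LACTATE: {op: ">", threshold: 4.0}
  warning:
    LACTATE: {low: 2.5, high: 4.0}
  ttc_hours: 6
- algorithm_id: acute_kidney_injury
  parameters: [CREATININE]
  kind: aki
  diagnosis: Acute kidney injury
  active: true
  ttc_hours: immediate
- algorithm_id: sepsis
  parameters: []
  kind: stub
  diagnosis: Sepsis
  active: false
  ttc_hours: null
- algorithm_id: myocardial_infarction
  parameters: []
  kind: stub
  diagnosis: Myocardial infarction
  active: false
  ttc_hours: null
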