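"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the engine's incremental rebuild machinery: the
stream oracle is a plain single pass over an in-order, deduplicated event
log, and the kidney-injury oracle enumerates every (candidate prior value,
criterion) pair directly.
"""

from datetime import timedelta

from labwatch.arms import Arm, assign_arm
from labwatch.rules import Severity


def aki_stage_oracle(points):
    """Brute-force staging: enumerate all (prior value, criterion) pairs.

    ``points`` is a time-ascending list of (datetime, value) with values in
    umol/L.  Returns the stage of the last point.
    """
    t_last, v_last = points[-1]
    window = [
        (t, v) for t, v in points[:-1] if (t_last - t) <= timedelta(days=7)
    ]
    if not window:
        return 0
    baseline = min(v for _, v in window)
    stage = 0
    for t, v in window:
        if (t_last - t) <= timedelta(hours=48) and (v_last - v) >= 26.5:
            stage = max(stage, 1)
            if v_last >= 354.0:
                stage = max(stage, 3)
    ratio = v_last / baseline
    if ratio >= 1.5:
        stage = max(stage, 1)
    if ratio > 2.0:
        stage = max(stage, 2)
    if ratio > 3.0:
        stage = max(stage, 3)
    return stage


_AKI_SEVERITY = {0: Severity.GREEN, 1: Severity.YELLOW, 2: Severity.RED, 3: Severity.RED}


def _severity(rule, histories, pid, param, value):
    if rule.kind == "aki":
        return _AKI_SEVERITY[aki_stage_oracle(histories[(pid, param)])]
    crit = rule.critical.get(param)
    if crit is not None and crit.check(value):
        return Severity.RED
    band = rule.warning.get(param)
    if band is not None and band.contains(value):
        return Severity.YELLOW
    return Severity.GREEN


def run_oracle(events, rulesets, arm_suppression=True):
    """Single-pass reference run over an in-order deduplicated event log.

    Events are dicts shaped like the engine's canonical log entries but
    with native values: ``{"type": "result", "at": dt, "patient_id": str,
    "parameter": Parameter, "value": float}``, ``{"type": "tick", "at": dt}``,
    ``{"type": "ack", ...}``, ``{"type": "silence", ...}``.

    Returns (notification tuples, summary colors, checkmarks, escalation
    counts per episode key).
    """
    active = [r for r in rulesets if r.active]
    histories = {}  # (pid, param) -> [(t, v)]
    open_episodes = {}  # (pid, algo) -> dict
    silenced = {}  # pid -> set of algo ids / "ALL"
    checkmark = {}
    notifications = []
    escalations = {}

    def allowed(pid, algo):
        if arm_suppression and assign_arm(pid) is Arm.CONTROL:
            return False
        sil = silenced.get(pid, set())
        return "ALL" not in sil and algo not in sil

    for ev in events:
        if ev["type"] == "result":
            pid, param, value, t = ev["patient_id"], ev["parameter"], ev["value"], ev["at"]
            histories.setdefault((pid, param), []).append((t, value))
            for rule in active:
                if param not in rule.parameters:
                    continue
                key = (pid, rule.algorithm_id)
                open_episodes.pop(key, None)  # any new watched result controls
                sev = _severity(rule, histories, pid, param, value)
                if sev is Severity.GREEN:
                    continue
                deadline = None
                if sev is Severity.RED and isinstance(rule.ttc, timedelta):
                    deadline = t + rule.ttc
                open_episodes[key] = {
                    "severity": sev,
                    "trigger_at": t,
                    "deadline": deadline,
                    "escalated": False,
                }
                if sev is Severity.RED:
                    checkmark.pop(pid, None)
                    if allowed(pid, rule.algorithm_id):
                        notifications.append(
                            (pid, rule.algorithm_id, "CRITICAL_VALUE", t)
                        )
        elif ev["type"] == "tick":
            now = ev["at"]
            due = [
                ((pid, algo), ep)
                for (pid, algo), ep in open_episodes.items()
                if ep["severity"] is Severity.RED
                and not ep["escalated"]
                and ep["deadline"] is not None
                and ep["deadline"] <= now
            ]
            due.sort(key=lambda item: (item[1]["deadline"], item[0][0], item[0][1]))
            for (pid, algo), ep in due:
                ep["escalated"] = True
                ekey = (pid, algo, ep["trigger_at"])
                escalations[ekey] = escalations.get(ekey, 0) + 1
                if allowed(pid, algo):
                    notifications.append((pid, algo, "TTC_OVERDUE", ep["trigger_at"]))
        elif ev["type"] == "ack":
            checkmark[ev["patient_id"]] = True
        elif ev["type"] == "silence":
            sil = silenced.setdefault(ev["patient_id"], set())
            if ev["flag"]:
                sil.add(ev["algorithm_id"])
            else:
                sil.discard(ev["algorithm_id"])
        else:
            raise AssertionError(f"unknown oracle event {ev['type']!r}")

    patients = sorted({pid for (pid, _) in histories})
    colors = {}
    for pid in patients:
        sev = Severity.GREEN
        for rule in active:
            ep = open_episodes.get((pid, rule.algorithm_id))
            if ep is not None:
                sev = max(sev, ep["severity"])
        colors[pid] = sev
    return notifications, colors, checkmark, escalations


def engine_notification_tuples(engine):
    """Project engine notifications onto the oracle's comparison shape."""
    return [
        (n.patient_id, n.algorithm_id, n.kind.value, n.dedup_key[2])
        for n in engine.notifications
    ]
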