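from datetime import datetime, timedelta

import numpy as np
import pytest

from labwatch.arms import Arm
from labwatch.engine import (
    Engine,
    EngineConfig,
    NotificationKind,
    events_from_jsonl,
    events_to_jsonl,
)
from labwatch.errors import (
    ClockRegressionError,
    StaleResultError,
    UnknownAlgorithmError,
    UnknownPatientError,
)
from labwatch.rules import Parameter, Severity

from .conftest import make_result
from .oracle import engine_notification_tuples, run_oracle
from .streams import apply_events, random_events

T0 = datetime(2021, 3, 1, 8, 0)
H = timedelta(hours=1)

# "1002" -> INTERVENTION, "1001" -> CONTROL (trailing-integer parity)
INTERVENTION = "1002"
CONTROL = "1001"


def red_k(at=T0, patient_id=INTERVENTION, value=2.3, order_id="O1"):
    return make_result(parameter=Parameter.K, value=value, at=at,
                       patient_id=patient_id, order_id=order_id)


class TestIngest:
    def test_red_opens_episode_and_notifies(self):
        engine = Engine()
        emitted = engine.ingest(red_k())
        assert [n.kind for n in emitted] == [NotificationKind.CRITICAL_VALUE]
        episode = engine.current_episode(INTERVENTION, "hypokalemia")
        assert episode is not None and episode.severity is Severity.RED
        assert episode.ttc_deadline == T0 + 6 * H

    def test_duplicate_is_noop(self):
        engine = Engine()
        engine.ingest(red_k())
        before = engine.snapshot()
        assert engine.ingest(red_k()) == []
        assert engine.snapshot() == before

    def test_followup_controls_and_recomputes_green(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.ingest(red_k(at=T0 + 3 * H, value=4.0, order_id="O2"))
        assert engine.current_episode(INTERVENTION, "hypokalemia") is None
        assert engine.summarize_patient(INTERVENTION).color is Severity.GREEN
        assert engine.tick(T0 + 10 * H) == []  # no escalation ever fires

    def test_still_critical_followup_opens_fresh_episode(self):
        engine = Engine()
        engine.ingest(red_k())
        emitted = engine.ingest(red_k(at=T0 + 3 * H, value=2.2, order_id="O2"))
        assert [n.kind for n in emitted] == [NotificationKind.CRITICAL_VALUE]
        episode = engine.current_episode(INTERVENTION, "hypokalemia")
        assert episode.trigger_result.measured_at == T0 + 3 * H
        assert episode.ttc_deadline == T0 + 9 * H  # TTC clock restarted
        episodes = [e for e in engine.all_episodes() if e.algorithm_id == "hypokalemia"]
        assert len(episodes) == 2 and episodes[0].controlled

    def test_control_arm_logged_but_not_notified(self):
        engine = Engine()
        assert engine.ingest(red_k(patient_id=CONTROL)) == []
        assert engine.notifications == []
        assert engine.current_episode(CONTROL, "hypokalemia") is not None
        assert any(a["kind"] == "notification_suppressed" for a in engine.audit)

    def test_arm_suppression_can_be_disabled(self):
        engine = Engine(EngineConfig(arm_suppression=False))
        assert len(engine.ingest(red_k(patient_id=CONTROL))) == 1

    def test_stale_result_rejected(self):
        engine = Engine(EngineConfig(retention=timedelta(days=7)))
        engine.ingest(red_k())
        with pytest.raises(StaleResultError):
            engine.ingest(red_k(at=T0 - timedelta(days=8), order_id="O9"))

    def test_yellow_episode_no_notification(self):
        engine = Engine()
        assert engine.ingest(red_k(value=2.7)) == []
        episode = engine.current_episode(INTERVENTION, "hypokalemia")
        assert episode.severity is Severity.YELLOW
        assert episode.ttc_deadline is None

    def test_severe_hypokalemia_annotation(self):
        engine = Engine()
        (n,) = engine.ingest(red_k(value=1.95))
        assert "severe hypokalemia" in n.message
        episode = engine.current_episode(INTERVENTION, "hypokalemia")
        assert any("severe" in a for a in episode.annotations)

    def test_multi_parameter_rule_controls_across_parameters(self):
        engine = Engine()
        engine.ingest(make_result(parameter=Parameter.CA_TOTAL, value=3.8, at=T0))
        engine.ingest(
            make_result(parameter=Parameter.CA_IONIZED, value=1.2, at=T0 + H, order_id="O2")
        )
        assert engine.current_episode(INTERVENTION, "hypercalcemia") is None

    def test_aki_episode_from_creatinine_history(self):
        engine = Engine()
        engine.ingest(make_result(parameter=Parameter.CREATININE, value=100.0, at=T0))
        emitted = engine.ingest(
            make_result(parameter=Parameter.CREATININE, value=210.0,
                        at=T0 + timedelta(days=2), order_id="O2")
        )
        assert [n.kind for n in emitted] == [NotificationKind.CRITICAL_VALUE]
        episode = engine.current_episode(INTERVENTION, "acute_kidney_injury")
        assert episode.aki_stage == 2
        assert "AKIN 2" in episode.annotations
        assert episode.ttc_deadline is None  # IMMEDIATE rule: no timer

    def test_out_of_order_arrival_recorded_and_consistent(self):
        engine = Engine()
        engine.ingest(red_k(at=T0 + 2 * H, value=4.0, order_id="O2"))
        engine.ingest(red_k(at=T0, value=2.3, order_id="O1"))
        # sorted history: RED at T0 controlled by GREEN at T0+2h
        assert engine.current_episode(INTERVENTION, "hypokalemia") is None
        assert any(a["kind"] == "out_of_order_arrival" for a in engine.audit)
        replayed = Engine.replay(sorted(engine.events, key=lambda e: e.get("at", e.get("measured_at"))))
        assert replayed.snapshot()["patients"] == engine.snapshot()["patients"]


class TestTick:
    def test_escalates_exactly_at_deadline(self):
        engine = Engine()
        engine.ingest(red_k())
        assert engine.tick(T0 + timedelta(hours=5, minutes=59)) == []
        emitted = engine.tick(T0 + 6 * H)
        assert [n.kind for n in emitted] == [NotificationKind.TTC_OVERDUE]
        assert engine.tick(T0 + 7 * H) == []  # exactly once

    def test_controlled_episode_never_escalates(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.ingest(red_k(at=T0 + 3 * H, value=4.2, order_id="O2"))
        assert engine.tick(T0 + 10 * H) == []

    def test_immediate_rule_never_ttc_overdue(self):
        engine = Engine()
        engine.ingest(make_result(parameter=Parameter.CREATININE, value=100.0, at=T0))
        engine.ingest(
            make_result(parameter=Parameter.CREATININE, value=320.0,
                        at=T0 + timedelta(days=1), order_id="O2")
        )
        assert engine.tick(T0 + timedelta(days=30)) == []

    def test_clock_regression_rejected(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.tick(T0 + H)
        with pytest.raises(ClockRegressionError):
            engine.tick(T0)


class TestAcknowledge:
    def test_checkmark_set_color_unchanged(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.acknowledge(INTERVENTION, "Dr. A", T0 + H)
        summary = engine.summarize_patient(INTERVENTION)
        assert summary.checkmark and summary.color is Severity.RED

    def test_new_red_trigger_clears_checkmark(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.acknowledge(INTERVENTION, "Dr. A", T0 + H)
        engine.ingest(red_k(at=T0 + 2 * H, value=2.1, order_id="O2"))
        assert not engine.summarize_patient(INTERVENTION).checkmark

    def test_all_green_ack_recorded(self):
        engine = Engine()
        engine.ingest(red_k(value=4.5))
        engine.acknowledge(INTERVENTION, "Dr. A", T0 + H)
        summary = engine.summarize_patient(INTERVENTION)
        assert summary.checkmark and summary.color is Severity.GREEN

    def test_unknown_patient_raises(self):
        with pytest.raises(UnknownPatientError):
            Engine().acknowledge("nobody", "x", T0)


class TestSilence:
    def test_silence_all_suppresses_but_logs(self):
        engine = Engine()
        engine.ingest(make_result(parameter=Parameter.LACTATE, value=1.0, at=T0))
        engine.set_silence(INTERVENTION, "ALL", True)
        emitted = engine.ingest(
            make_result(parameter=Parameter.LACTATE, value=6.0, at=T0 + H, order_id="O2")
        )
        assert emitted == [] and engine.notifications == []
        episode = engine.current_episode(INTERVENTION, "hyperlactatemia")
        assert episode is not None and episode.silenced
        assert engine.summarize_patient(INTERVENTION).color is Severity.RED

    def test_unsilence_restores_notifications(self):
        engine = Engine()
        engine.ingest(red_k(value=4.0))
        engine.set_silence(INTERVENTION, "ALL", True)
        engine.set_silence(INTERVENTION, "ALL", False)
        assert len(engine.ingest(red_k(at=T0 + H, order_id="O2"))) == 1

    def test_silence_scoped_to_algorithm(self):
        engine = Engine()
        engine.ingest(red_k(value=4.0))
        engine.set_silence(INTERVENTION, "hypokalemia", True)
        emitted = engine.ingest(
            make_result(parameter=Parameter.NA, value=115.0, at=T0 + H, order_id="O2")
        )
        assert [n.algorithm_id for n in emitted] == ["hyponatremia"]
        assert engine.ingest(red_k(at=T0 + 2 * H, order_id="O3")) == []

    def test_unknown_algorithm_raises(self):
        engine = Engine()
        engine.ingest(red_k())
        with pytest.raises(UnknownAlgorithmError):
            engine.set_silence(INTERVENTION, "no_such_algo", True)

    def test_unknown_patient_raises(self):
        with pytest.raises(UnknownPatientError):
            Engine().set_silence("nobody", "ALL", True)


class TestSummarize:
    def test_hierarchy_red_dominates(self):
        engine = Engine()
        engine.ingest(red_k())  # RED
        engine.ingest(
            make_result(parameter=Parameter.NA, value=123.0, at=T0, order_id="O2")
        )  # YELLOW
        assert engine.summarize_patient(INTERVENTION).color is Severity.RED

    def test_hierarchy_yellow_over_green(self):
        engine = Engine()
        engine.ingest(make_result(parameter=Parameter.NA, value=123.0, at=T0))
        assert engine.summarize_patient(INTERVENTION).color is Severity.YELLOW

    def test_unknown_patient_all_green(self):
        summary = Engine().summarize_patient("ghost")
        assert summary.color is Severity.GREEN and not summary.checkmark
        assert set(summary.statuses.values()) == {Severity.GREEN}


class TestReplay:
    def test_replay_empty_is_empty(self):
        engine = Engine.replay([])
        assert engine.patients == [] and engine.notifications == []

    def test_replay_jsonl_roundtrip(self):
        engine = Engine()
        engine.ingest(red_k())
        engine.tick(T0 + 6 * H)
        engine.acknowledge(INTERVENTION, "Dr. A", T0 + 7 * H)
        events = events_from_jsonl(events_to_jsonl(engine.events))
        replayed = Engine.replay(events)
        assert replayed.snapshot() == engine.snapshot()

    def test_replay_with_duplicated_suffix_identical(self):
        rng = np.random.default_rng(7)
        events = random_events(rng, n_events=15)
        engine = apply_events(events)
        log = engine.events
        resubmitted = [e for e in log[-6:] if e["type"] == "result"]
        replayed = Engine.replay(log + resubmitted)
        assert replayed.snapshot() == engine.snapshot()

    def test_determinism_identical_logs(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        e1 = apply_events(random_events(rng1))
        e2 = apply_events(random_events(rng2))
        assert e1.snapshot() == e2.snapshot()
        assert [n.message for n in e1.notifications] == [n.message for n in e2.notifications]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(60))
    def test_engine_matches_single_pass_oracle(self, seed, rulesets):
        rng = np.random.default_rng(seed)
        events = random_events(rng, n_events=int(rng.integers(5, 20)))
        engine = apply_events(events)
        notifications, colors, checkmarks, _ = run_oracle(events, rulesets)
        assert engine_notification_tuples(engine) == notifications
        for pid, color in colors.items():
            assert engine.summarize_patient(pid).color is color
            assert engine.summarize_patient(pid).checkmark == checkmarks.get(pid, False)

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent_under_duplicates(self, seed):
        rng1, rng2 = np.random.default_rng(seed), np.random.default_rng(seed)
        clean = apply_events(random_events(rng1))
        noisy = apply_events(random_events(rng2), duplicate_every=2)
        assert noisy.snapshot() == clean.snapshot()

    @pytest.mark.parametrize("seed", range(20))
    def test_exactly_once_escalation(self, seed):
        rng = np.random.default_rng(100 + seed)
        engine = apply_events(random_events(rng, n_events=18))
        per_key = {}
        for n in engine.notifications:
            if n.kind is NotificationKind.TTC_OVERDUE:
                per_key[n.dedup_key] = per_key.get(n.dedup_key, 0) + 1
        assert all(count == 1 for count in per_key.values())
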