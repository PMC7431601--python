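"""Scenario loading, response assessment, tracing and the alert procedure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotrace.exceptions import ConfigurationError, EmptySessionError, ParameterError
from neurotrace.tracing import (
    CockpitLog,
    ScenarioEvent,
    assess_response,
    default_scenario,
    emulate_alert_procedure,
    load_scenario,
    scenario_to_dicts,
    trace_neuroadaptive,
    trace_normative,
)


def _log(duration=120.0, rate=20.0, **initial):
    initial = initial or {"altitude_select": 250.0}
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    return CockpitLog(t, {k: np.full(n, v) for k, v in initial.items()})


def _set(log, param, t_change, value):
    idx = int(np.searchsorted(log.times_s, t_change, side="left"))
    log.params[param][idx:] = value
    return log


ALT_EVENT = ScenarioEvent("atc", "ATC", 10.0, (("altitude_select", 300.0),))


class TestScenario:
    def test_default_scenario_matches_script(self):
        events = {e.event_id: e for e in default_scenario()}
        assert events["engine_fire"].onset_s == 1000.0  # 16:40
        assert events["fuel_imbalance"].analysis_included is False
        analyzable = [e for e in default_scenario() if e.analyzable]
        assert len(analyzable) == 10  # 8 ATC + fuel pump caution + fire warning
        assert sum(e.kind == "spurious" for e in default_scenario()) == 4

    def test_shipped_yaml_equals_coded_default(self):
        from importlib.resources import files

        path = files("neurotrace").joinpath("data/default_scenario.yaml")
        loaded = load_scenario(str(path))
        assert scenario_to_dicts(loaded) == scenario_to_dicts(default_scenario())

    def test_empty_event_list_raises(self):
        with pytest.raises(EmptySessionError):
            load_scenario({"events": []})

    def test_spurious_event_with_required_change_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioEvent("bad", "spurious", 5.0, (("altitude_select", 1.0),))


class TestAssessResponse:
    def test_correct_value_within_window_is_adequate(self):
        log = _set(_log(), "altitude_select", 22.0, 300.0)  # onset 10 + 12 s
        a = assess_response(ALT_EVENT, log)
        assert a.category == "adequate"
        assert a.latency_s == pytest.approx(12.0, abs=0.051)

    def test_wrong_value_is_commission(self):
        log = _set(_log(), "altitude_select", 20.0, 280.0)
        assert assess_response(ALT_EVENT, log).category == "commission"

    def test_no_change_is_omission(self):
        a = assess_response(ALT_EVENT, _log())
        assert a.category == "omission" and a.latency_s is None

    def test_late_change_beyond_limit_is_omission(self):
        log = _set(_log(), "altitude_select", 40.0, 300.0)  # latency 30 s > 25
        assert assess_response(ALT_EVENT, log).category == "omission"

    def test_limit_boundary_is_inclusive(self):
        log = _set(_log(), "altitude_select", 35.0, 300.0)  # exactly 25 s
        assert assess_response(ALT_EVENT, log).category == "adequate"
        assert (
            assess_response(ALT_EVENT, log, inclusive_limit=False).category == "omission"
        )

    def test_first_change_decides_despite_later_correction(self):
        log = _set(_log(), "altitude_select", 15.0, 280.0)
        _set(log, "altitude_select", 20.0, 300.0)
        assert assess_response(ALT_EVENT, log).category == "commission"

    def test_two_parameter_event_needs_both_changes(self):
        ev = ScenarioEvent(
            "atc1", "ATC", 10.0, (("altitude_select", 280.0), ("speed_select", 220.0))
        )
        log = _log(altitude_select=250.0, speed_select=250.0)
        _set(log, "altitude_select", 15.0, 280.0)
        assert assess_response(ev, log).category == "omission"  # speed missing
        _set(log, "speed_select", 20.0, 220.0)
        a = assess_response(ev, log)
        assert a.category == "adequate" and a.latency_s == pytest.approx(10.0, abs=0.051)

    def test_missing_parameter_channel_raises(self):
        with pytest.raises(ConfigurationError):
            assess_response(ALT_EVENT, _log(speed_select=250.0))


def _outcome_fixture():
    events = [
        ScenarioEvent(f"e{i}", "ATC", 10.0 + 30 * i, (("altitude_select", 300.0),))
        for i in range(5)
    ]
    from neurotrace.tracing import ResponseAssessment

    cats = ["adequate", "adequate", "adequate", "commission", "omission"]
    assessments = {
        e.event_id: ResponseAssessment(
            e.event_id, c, latency_s=5.0 if c != "omission" else None
        )
        for e, c in zip(events, cats)
    }
    return events, assessments


class TestTracers:
    def test_normative_accuracy_counts_adequate_only(self):
        events, assessments = _outcome_fixture()
        outcomes, acc = trace_normative(events, assessments)
        assert acc == pytest.approx(3 / 5)
        assert [o.reason for o in outcomes] == [
            "adequate-response", "adequate-response", "adequate-response",
            "unexplained-commission", "unexplained-omission",
        ]

    def test_excluded_events_never_enter_denominator(self):
        events, assessments = _outcome_fixture()
        events.append(
            ScenarioEvent("excl", "caution", 500.0, (("fuel_x_feed", 1.0),),
                          analysis_included=False)
        )
        _, acc = trace_normative(events, assessments)
        assert acc == pytest.approx(3 / 5)

    def test_gate_never_fires_when_all_scores_relevant(self):
        events, assessments = _outcome_fixture()
        scores = {e.event_id: 1.8 for e in events}
        norm, norm_acc = trace_normative(events, assessments)
        neuro, neuro_acc = trace_neuroadaptive(events, assessments, scores)
        assert neuro_acc == norm_acc
        assert [o.classification_correct for o in neuro] == [
            o.classification_correct for o in norm
        ]

    def test_seven_adequate_three_omissions_two_gated_gives_090(self):
        from neurotrace.tracing import ResponseAssessment

        events = [
            ScenarioEvent(f"e{i}", "ATC", 10.0 + 30 * i, (("altitude_select", 300.0),))
            for i in range(10)
        ]
        cats = ["adequate"] * 7 + ["omission"] * 3
        assessments = {
            e.event_id: ResponseAssessment(e.event_id, c,
                                           latency_s=5.0 if c == "adequate" else None)
            for e, c in zip(events, cats)
        }
        scores = {e.event_id: 1.8 for e in events}
        scores["e7"] = scores["e8"] = 1.2  # two omissions decoded as unattended
        _, acc = trace_neuroadaptive(events, assessments, scores)
        assert acc == pytest.approx(0.9)

    def test_adequate_response_is_correct_even_if_scored_irrelevant(self):
        events, assessments = _outcome_fixture()
        scores = {e.event_id: 1.2 for e in events}
        outcomes, _ = trace_neuroadaptive(events, assessments, scores)
        assert outcomes[0].classification_correct
        assert outcomes[0].reason == "adequate-response"

    def test_boundary_score_counts_as_relevant(self):
        events, assessments = _outcome_fixture()
        scores = {e.event_id: 1.5 for e in events}
        outcomes, _ = trace_neuroadaptive(events, assessments, scores)
        assert outcomes[4].classification_correct is False  # omission not gated

    def test_missing_score_raises(self):
        events, assessments = _outcome_fixture()
        with pytest.raises(ParameterError):
            trace_neuroadaptive(events, assessments, {})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from(["adequate", "commission", "omission"]),
                 min_size=1, max_size=12),
        st.data(),
    )
    def test_neuroadaptive_dominates_normative(self, cats, data):
        from neurotrace.tracing import ResponseAssessment

        events = [
            ScenarioEvent(f"e{i}", "ATC", 10.0 * (i + 1), (("altitude_select", 300.0),))
            for i in range(len(cats))
        ]
        assessments = {
            e.event_id: ResponseAssessment(e.event_id, c,
                                           latency_s=None if c == "omission" else 4.0)
            for e, c in zip(events, cats)
        }
        scores = {
            e.event_id: data.draw(st.floats(1.0, 2.0), label=e.event_id) for e in events
        }
        norm, norm_acc = trace_normative(events, assessments)
        neuro, neuro_acc = trace_neuroadaptive(events, assessments, scores)
        assert neuro_acc >= norm_acc
        # partition: one outcome per analyzable event, reasons exhaustive
        assert len(norm) == len(neuro) == len(events)
        assert all(
            o.reason in {"adequate-response", "gated-irrelevant",
                         "unexplained-omission", "unexplained-commission"}
            for o in neuro
        )


class TestAlertProcedure:
    def test_eight_phases_ending_with_verification_at_limit(self):
        ev = next(e for e in default_scenario() if e.event_id == "fuel_pump")
        steps = emulate_alert_procedure(ev)
        assert len(steps) == 8
        assert steps[0].phase == "aural-detect" and steps[0].t_s == ev.onset_s
        assert steps[-1].phase == "verify-response"
        assert steps[-1].t_s == ev.onset_s + 25.0

    def test_phase_order_identical_for_all_alert_kinds(self):
        orders = set()
        for e in default_scenario():
            orders.add(tuple(s.phase for s in emulate_alert_procedure(e)))
        assert len(orders) == 1

    def test_verification_reads_the_assessed_parameter(self):
        for e in default_scenario():
            if not e.analyzable:
                continue
            steps = emulate_alert_procedure(e)
            assert steps[-1].detail == e.required_changes[0][0]

    def test_trace_is_deterministic(self):
        ev = default_scenario()[0]
        assert emulate_alert_procedure(ev) == emulate_alert_procedure(ev)
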