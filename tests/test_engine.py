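"""Deadline arithmetic, event folding and the two-window alerting rules."""

import pytest

from sepwatch import MonitorConfig, apply_event, element_deadline, poll, run_engine
from sepwatch.engine import EncounterState, OutOfWindowError
from sepwatch.events import BundleElement, ClinicalEvent, Encounter

from conftest import T0, at, make_events

BC = BundleElement.BLOOD_CULTURES
IL = BundleElement.INITIAL_LACTATE
ABX = BundleElement.ANTIBIOTICS
RL = BundleElement.REPEAT_LACTATE


@pytest.fixture
def config():
    return MonitorConfig()


@pytest.fixture
def state(config):
    return EncounterState.new("E1", T0, config)


class TestElementDeadline:
    @pytest.mark.parametrize("element", [BC, IL, ABX])
    def test_three_hour_elements_due_at_180_minutes(self, element, config):
        assert element_deadline(element, T0, None, config) == at(180)

    def test_repeat_lactate_due_at_six_hours_when_elevated(self, config):
        assert element_deadline(RL, T0, 3.1, config) == at(360)

    @pytest.mark.parametrize("initial", [None, 1.4, 2.0])
    def test_repeat_lactate_absent_unless_above_threshold(self, initial, config):
        # 2.0 is the threshold itself: "elevated" means strictly above
        assert element_deadline(RL, T0, initial, config) is None


class TestApplyEvent:
    def test_antibiotic_completion(self, state, config):
        ev = ClinicalEvent("E1", at(150), "antibiotic_administered")
        apply_event(state, ev, config)
        status = state.statuses[ABX]
        assert status.state == "complete" and status.completion_time == at(150)

    def test_completion_is_idempotent_first_event_wins(self, state, config):
        apply_event(state, ClinicalEvent("E1", at(100), "antibiotic_administered"), config)
        apply_event(state, ClinicalEvent("E1", at(140), "antibiotic_administered"), config)
        assert state.statuses[ABX].completion_time == at(100)

    def test_two_draw_lactate_timeline(self, state, config):
        apply_event(
            state,
            ClinicalEvent("E1", at(90), "lactate_resulted", {"value": 3.1, "draw_index": 1}),
            config,
        )
        assert state.statuses[IL].completion_time == at(90)
        assert state.statuses[RL].state == "pending"
        assert state.statuses[RL].deadline == at(360)
        apply_event(
            state,
            ClinicalEvent("E1", at(300), "lactate_resulted", {"value": 1.8, "draw_index": 2}),
            config,
        )
        assert state.statuses[RL].completion_time == at(300)

    def test_normal_initial_lactate_leaves_repeat_not_required(self, state, config):
        apply_event(
            state,
            ClinicalEvent("E1", at(90), "lactate_resulted", {"value": 1.4, "draw_index": 1}),
            config,
        )
        assert state.statuses[RL].state == "not_required"
        assert state.statuses[RL].deadline is None

    def test_clinical_event_before_t0_rejected(self, state, config):
        with pytest.raises(OutOfWindowError):
            apply_event(state, ClinicalEvent("E1", at(-10), "antibiotic_administered"), config)

    def test_arrival_before_t0_passes_through(self, state, config):
        apply_event(state, ClinicalEvent("E1", at(-30), "ed_arrival"), config)


class TestPoll:
    def _complete_all_by(self, state, config, minute):
        for kind in ("blood_culture_ordered", "antibiotic_administered"):
            apply_event(state, ClinicalEvent("E1", at(minute), kind), config)
        apply_event(
            state,
            ClinicalEvent("E1", at(minute), "lactate_resulted",
                          {"value": 1.2, "draw_index": 1}),
            config,
        )

    def test_no_alert_when_all_complete_before_lead_window(self, state, config):
        self._complete_all_by(state, config, 110)
        for k in range(0, 24):
            state, alert = poll(state, at(15 * k), config)
            assert alert is None

    def test_w3_alert_fires_at_first_tick_of_lead_hour(self, state, config):
        apply_event(state, ClinicalEvent("E1", at(50), "blood_culture_ordered"), config)
        apply_event(
            state,
            ClinicalEvent("E1", at(55), "lactate_resulted", {"value": 1.2, "draw_index": 1}),
            config,
        )
        state, alert = poll(state, at(105), config)
        assert alert is None
        state, alert = poll(state, at(120), config)
        assert alert is not None
        assert alert.window == "W3"
        assert alert.deficient_elements == (ABX,)
        assert alert.alert_index == 1

    def test_w6_alert_for_outstanding_repeat_lactate(self, state, config):
        self._complete_all_by(state, config, 50)
        # elevated draw overrides: re-create with elevated initial lactate
        state = EncounterState.new("E1", T0, config)
        for kind in ("blood_culture_ordered", "antibiotic_administered"):
            apply_event(state, ClinicalEvent("E1", at(50), kind), config)
        apply_event(
            state,
            ClinicalEvent("E1", at(55), "lactate_resulted", {"value": 3.5, "draw_index": 1}),
            config,
        )
        state, alert = poll(state, at(285), config)
        assert alert is None
        state, alert = poll(state, at(300), config)
        assert alert is not None
        assert alert.window == "W6"
        assert alert.deficient_elements == (RL,)

    def test_w6_lists_overdue_three_hour_elements_too(self, state, config):
        apply_event(
            state,
            ClinicalEvent("E1", at(55), "lactate_resulted", {"value": 3.5, "draw_index": 1}),
            config,
        )
        state, alert = poll(state, at(120), config)
        assert alert.window == "W3"
        assert alert.deficient_elements == (BC, ABX)
        state, alert = poll(state, at(300), config)
        assert alert.window == "W6"
        assert alert.deficient_elements == (BC, ABX, RL)

    def test_required_but_undue_repeat_never_on_w3_page(self, state, config):
        # elevated initial lactate at t0+55: the repeat is required but its
        # lead hour opens only at t0+300, so the W3 page must not list it
        apply_event(
            state,
            ClinicalEvent("E1", at(55), "lactate_resulted", {"value": 3.5, "draw_index": 1}),
            config,
        )
        apply_event(state, ClinicalEvent("E1", at(56), "blood_culture_ordered"), config)
        state, alert = poll(state, at(120), config)
        assert alert.deficient_elements == (ABX,)

    def test_page_cap_silences_third_deficiency(self, config):
        state = EncounterState.new("E1", T0, config)
        apply_event(
            state,
            ClinicalEvent("E1", at(55), "lactate_resulted", {"value": 3.5, "draw_index": 1}),
            config,
        )
        fired = []
        for k in range(0, 24):
            state, alert = poll(state, at(15 * k), config)
            if alert:
                fired.append(alert)
        assert len(fired) == 2
        assert [a.window for a in fired] == ["W3", "W6"]

    def test_non_tick_time_rejected(self, state, config):
        with pytest.raises(ValueError, match="poll tick"):
            poll(state, at(7), config)


class TestRunEngine:
    def test_empty_log_no_encounters(self, config):
        alerts, states = run_engine([], [], config)
        assert alerts == [] and states == {}

    def test_single_encounter_timeline(self, config):
        """Cultures on time, antibiotics inside the lead hour, and a repeat
        lactate resulting after its own lead hour opens: the engine pages for
        the antibiotics at t0+120 and for the repeat draw at t0+300."""
        events = make_events("E1", [
            (0, "bpa_accepted", None),
            (60, "blood_culture_ordered", None),
            (90, "lactate_resulted", {"value": 3.1, "draw_index": 1}),
            (150, "antibiotic_administered", None),
            (320, "lactate_resulted", {"value": 1.9, "draw_index": 2}),
        ])
        alerts, states = run_engine(events, [Encounter("E1", t0=T0)], config)
        assert [(a.window, a.fire_time, a.deficient_elements) for a in alerts] == [
            ("W3", at(120), (ABX,)),
            ("W6", at(300), (RL,)),
        ]
        assert states["E1"].statuses[RL].completion_time == at(320)

    def test_event_at_tick_applied_before_evaluation(self, config):
        events = make_events("E1", [
            (0, "bpa_accepted", None),
            (50, "blood_culture_ordered", None),
            (55, "lactate_resulted", {"value": 1.2, "draw_index": 1}),
            (120, "antibiotic_administered", None),
        ])
        alerts, _ = run_engine(events, [Encounter("E1", t0=T0)], config)
        assert alerts == []

    def test_deterministic_replay(self, config):
        events = make_events("E1", [
            (0, "bpa_accepted", None),
            (90, "lactate_resulted", {"value": 3.5, "draw_index": 1}),
        ])
        encounters = [Encounter("E1", t0=T0)]
        first, _ = run_engine(events, encounters, config)
        second, _ = run_engine(events, encounters, config)
        assert first == second


class TestMonitorConfig:
    def test_poll_interval_must_divide_lead_time(self):
        with pytest.raises(ValueError):
            MonitorConfig(poll_interval=25)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            MonitorConfig(lead_time=200)

    def test_yaml_round_trip(self):
        cfg = MonitorConfig.from_yaml("poll_interval: 5\nlead_time: 60\n")
        assert cfg.poll_interval == 5 and cfg.lead_time == 60
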