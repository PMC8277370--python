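"""Generator determinism, parameter plumbing and fixture self-consistency."""

import io

import pytest

from sepwatch import (
    GeneratorParams,
    MonitorConfig,
    generate_cohort,
    run_engine,
    table2_fixture,
    validate_events,
    write_event_log,
)
from sepwatch.events import BundleElement


def serialize(events):
    buf = io.StringIO()
    write_event_log(events, buf)
    return buf.getvalue()


class TestGenerateCohort:
    def test_same_seed_identical_logs(self):
        a = generate_cohort(GeneratorParams(n_encounters=50, seed=7))
        b = generate_cohort(GeneratorParams(n_encounters=50, seed=7))
        assert serialize(a.events) == serialize(b.events)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorParams(n_encounters=50, seed=7))
        b = generate_cohort(GeneratorParams(n_encounters=50, seed=8))
        assert serialize(a.events) != serialize(b.events)

    def test_generated_log_passes_validation(self):
        fx = generate_cohort(GeneratorParams(n_encounters=200, seed=3))
        assert validate_events(sorted(fx.events, key=lambda e: e.time)) == []
        assert all(e.t0 is not None for e in fx.encounters)

    def test_prompt_completion_yields_no_alerts(self):
        params = GeneratorParams(
            n_encounters=1,
            seed=1,
            completion_median_min={e: 30.0 for e in BundleElement},
            completion_sigma={e: 0.01 for e in BundleElement},
            never_complete_prob={e: 0.0 for e in BundleElement},
            p_lactate_elevated=0.0,
        )
        fx = generate_cohort(params)
        alerts, _ = run_engine(fx.events, fx.encounters, MonitorConfig())
        assert alerts == []

    def test_never_completed_antibiotics_alert_every_encounter(self):
        params = GeneratorParams(
            n_encounters=20,
            seed=11,
            never_complete_prob={
                BundleElement.BLOOD_CULTURES: 0.0,
                BundleElement.INITIAL_LACTATE: 0.0,
                BundleElement.ANTIBIOTICS: 1.0,
                BundleElement.REPEAT_LACTATE: 0.0,
            },
            completion_median_min={e: 30.0 for e in BundleElement},
            completion_sigma={e: 0.01 for e in BundleElement},
            p_lactate_elevated=0.0,
        )
        fx = generate_cohort(params)
        alerts, _ = run_engine(fx.events, fx.encounters, MonitorConfig())
        w3 = {a.encounter_id for a in alerts if a.window == "W3"}
        assert len(w3) == 20
        assert all(
            BundleElement.ANTIBIOTICS in a.deficient_elements
            for a in alerts
            if a.window == "W3"
        )

    @pytest.mark.parametrize("kwargs", [
        {"n_encounters": 0},
        {"p_lactate_elevated": 1.5},
        {"study_days": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorParams(**kwargs)


class TestRolloutFixture:
    def test_fixture_is_deterministic(self):
        assert serialize(table2_fixture().events) == serialize(table2_fixture().events)

    def test_fixture_log_is_clean(self):
        fx = table2_fixture()
        assert validate_events(fx.events) == []

    def test_cohort_shape(self, rollout_replay):
        fx = rollout_replay["fixture"]
        assert len(fx.encounters) == 711
        assert len({e.patient_id for e in fx.encounters}) == 648
        assert len([s for s in fx.shifts if s.role == "attending"]) == 647
        assert fx.metadata["n_ed_encounters"] == 15770

    def test_alert_and_page_census_from_engine_replay(self, rollout_replay):
        alerts = rollout_replay["alerts"]
        pages = rollout_replay["pages"]
        assert len(alerts) == 317
        assert len(pages) == 634
        assert len({a.encounter_id for a in alerts}) == 272
        both = [
            enc for enc in {a.encounter_id for a in alerts}
            if sum(a.encounter_id == enc for a in alerts) == 2
        ]
        assert len(both) == 45

    def test_deficiency_census(self, rollout_replay):
        deficiencies = rollout_replay["deficiencies"]
        assert len(deficiencies) == 327
        by_element = {
            element: [d for d in deficiencies if d.element is element]
            for element in BundleElement
        }
        assert len(by_element[BundleElement.BLOOD_CULTURES]) == 68
        assert len(by_element[BundleElement.ANTIBIOTICS]) == 136
        assert len(by_element[BundleElement.INITIAL_LACTATE]) == 17
        assert len(by_element[BundleElement.REPEAT_LACTATE]) == 106
        assert sum(d.adherent for d in deficiencies) == 125
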