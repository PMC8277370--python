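"""Shared fixtures: tiny log builders, the rollout-fixture replay, and an
independent 1-minute-resolution alerting oracle used for cross-checks."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from sepwatch import MonitorConfig, run_engine, table2_fixture
from sepwatch.events import BundleElement, ClinicalEvent, Encounter, extract_assignments
from sepwatch.metrics import build_deficiencies, cohort_metrics
from sepwatch.paging import dispatch

T0 = datetime(2020, 1, 14, 10, 0, tzinfo=timezone.utc)


def at(minutes: int, base: datetime = T0) -> datetime:
    return base + timedelta(minutes=minutes)


def make_events(encounter_id: str, rows, base: datetime = T0):
    """rows: (offset_minutes, kind, payload) triples."""
    return [
        ClinicalEvent(encounter_id, at(off, base), kind, payload or {})
        for off, kind, payload in rows
    ]


@pytest.fixture(scope="session")
def monitor_config() -> MonitorConfig:
    return MonitorConfig()


@pytest.fixture(scope="session")
def rollout_replay():
    """Engine -> routing -> metrics run over the deterministic rollout fixture."""
    fx = table2_fixture()
    alerts, states = run_engine(fx.events, fx.encounters)
    assignments = extract_assignments(fx.events)
    pages = dispatch(
        alerts, assignments, fx.shifts, {e.encounter_id: e for e in fx.encounters}
    )
    deficiencies = build_deficiencies(alerts, states)
    report = cohort_metrics(
        fx.encounters,
        alerts,
        pages,
        fx.shifts,
        deficiencies=deficiencies,
        study_days=fx.metadata["study_days"],
        n_ed_encounters=fx.metadata["n_ed_encounters"],
    )
    return {
        "fixture": fx,
        "alerts": alerts,
        "states": states,
        "pages": pages,
        "deficiencies": deficiencies,
        "report": report,
    }


# ---------------------------------------------------------------------------
# Brute-force oracle: re-derives the alert set from raw events at 1-minute
# resolution, independent of the engine's state machine.
# ---------------------------------------------------------------------------

_THREE_HOUR = (
    BundleElement.BLOOD_CULTURES,
    BundleElement.INITIAL_LACTATE,
    BundleElement.ANTIBIOTICS,
)


def brute_force_alerts(
    events: list[ClinicalEvent],
    encounter: Encounter,
    threshold: float = 2.0,
):
    """All (window, fire_minute, elements) an every-minute checker would fire.

    Completion minutes are read straight off the event list; each minute of
    the 6-hour window is scanned and an alert fires the first minute a
    window's check finds a pending element whose lead hour has opened.
    """
    t0 = encounter.t0
    mine = sorted(
        (e for e in events if e.encounter_id == encounter.encounter_id),
        key=lambda e: e.time,
    )

    def minute(ev):
        return int((ev.time - t0).total_seconds() // 60)

    done: dict[BundleElement, int] = {}
    lactates = [e for e in mine if e.kind == "lactate_resulted"]
    for e in mine:
        m = minute(e)
        if e.kind == "blood_culture_ordered":
            done.setdefault(BundleElement.BLOOD_CULTURES, m)
        elif e.kind == "antibiotic_administered":
            done.setdefault(BundleElement.ANTIBIOTICS, m)
    repeat_required_at = None
    if lactates:
        first = lactates[0]
        done[BundleElement.INITIAL_LACTATE] = minute(first)
        if float(first.payload["value"]) > threshold:
            repeat_required_at = minute(first)
            if len(lactates) > 1:
                done[BundleElement.REPEAT_LACTATE] = minute(lactates[1])

    fired = []
    fired_windows = set()
    for m in range(0, 360):
        if len(fired) >= 2:
            break
        pending3 = [e for e in _THREE_HOUR if done.get(e) is None or done[e] > m]
        due3 = [e for e in pending3 if m >= 120]
        repeat_pending_due = (
            repeat_required_at is not None
            and repeat_required_at <= m
            and (done.get(BundleElement.REPEAT_LACTATE) is None
                 or done[BundleElement.REPEAT_LACTATE] > m)
            and m >= 300
        )
        if "W6" not in fired_windows and 300 <= m < 360:
            elements = list(due3) + (
                [BundleElement.REPEAT_LACTATE] if repeat_pending_due else []
            )
            if elements:
                fired.append(("W6", m, frozenset(elements)))
                fired_windows.add("W6")
                continue
        if "W3" not in fired_windows and 120 <= m < 180 and due3:
            fired.append(("W3", m, frozenset(due3)))
            fired_windows.add("W3")
    return fired
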