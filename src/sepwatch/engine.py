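"""Deadline state machine and alert generation.

Each monitored encounter carries four SEP-1 element statuses against a clock
that starts at BPA acceptance (t0).  The engine re-checks every encounter on a
15-minute poll anchored at its own t0 and fires at most two alerts:

* a W3 alert at the first tick at or after ``t0 + 120`` min (one lead hour
  before the 3-hour deadline) if any 3-hour element is still pending, and
* a W6 alert at the first tick at or after ``t0 + 300`` min if any required
  element is still pending — a due repeat lactate and/or 3-hour elements that
  remain incomplete.

An alert lists every pending required element whose own lead window has
opened; an element completed at least one lead hour before its deadline is
therefore never paged on.  Monitoring stops at the end of the 6-hour window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

import yaml

from .events import (
    ELEMENT_ORDER,
    BundleElement,
    ClinicalEvent,
    Encounter,
    minutes_between,
)

__all__ = [
    "MonitorConfig",
    "ElementStatus",
    "Alert",
    "EncounterState",
    "OutOfWindowError",
    "element_deadline",
    "apply_event",
    "poll",
    "run_engine",
]


class OutOfWindowError(ValueError):
    """A clinical event dated before the encounter's sepsis clock zero."""


@dataclass(frozen=True)
class MonitorConfig:
    """Tunable monitoring parameters; defaults match the deployed rollout.

    All durations are whole minutes.  ``lactate_elevated_threshold`` is the
    mmol/L cut-off above which the initial lactate makes a repeat draw
    mandatory (2.0 is the CMS SEP-1 convention).
    """

    poll_interval: int = 15
    lead_time: int = 60
    window_3h: int = 180
    window_6h: int = 360
    max_alerts_per_encounter: int = 2
    lactate_elevated_threshold: float = 2.0
    monitored_elements: tuple[BundleElement, ...] = ELEMENT_ORDER

    def __post_init__(self) -> None:
        if not (0 < self.lead_time < self.window_3h < self.window_6h):
            raise ValueError("require 0 < lead_time < window_3h < window_6h")
        if self.poll_interval <= 0 or self.lead_time % self.poll_interval:
            raise ValueError("poll_interval must divide lead_time")
        if self.max_alerts_per_encounter < 0:
            raise ValueError("max_alerts_per_encounter must be >= 0")

    @classmethod
    def from_yaml(cls, source) -> "MonitorConfig":
        data = yaml.safe_load(source.read() if hasattr(source, "read") else source) or {}
        if "monitored_elements" in data:
            data["monitored_elements"] = tuple(
                BundleElement(name) for name in data["monitored_elements"]
            )
        return cls(**data)


@dataclass
class ElementStatus:
    """Where one bundle element stands for one encounter."""

    element: BundleElement
    state: str = "pending"  # pending | complete | not_required
    completion_time: Optional[datetime] = None
    deadline: Optional[datetime] = None


@dataclass(frozen=True)
class Alert:
    """A deficiency detection at one poll tick (fans out to pages later)."""

    encounter_id: str
    fire_time: datetime
    window: str  # "W3" | "W6"
    deficient_elements: tuple[BundleElement, ...]
    alert_index: int  # 1 or 2 within the encounter

    @property
    def window_deadline_minutes(self) -> int:
        return 180 if self.window == "W3" else 360


@dataclass
class EncounterState:
    """Mutable per-encounter monitoring state."""

    encounter_id: str
    t0: datetime
    statuses: dict[BundleElement, ElementStatus]
    alerts_fired: list[Alert] = field(default_factory=list)
    monitoring_active: bool = True
    lactate_draws: int = 0
    initial_lactate: Optional[float] = None

    @classmethod
    def new(cls, encounter_id: str, t0: datetime, config: MonitorConfig) -> "EncounterState":
        statuses = {}
        for element in config.monitored_elements:
            if element.conditional:
                statuses[element] = ElementStatus(element, state="not_required")
            else:
                statuses[element] = ElementStatus(
                    element, deadline=t0 + timedelta(minutes=config.window_3h)
                )
        return cls(encounter_id, t0, statuses)

    def fired_window(self, window: str) -> bool:
        return any(a.window == window for a in self.alerts_fired)


def element_deadline(
    element: BundleElement,
    t0: datetime,
    initial_lactate: Optional[float],
    config: MonitorConfig,
) -> Optional[datetime]:
    """Deadline for one element, or None while it is not (yet) required.

    The three 3-hour elements are due at ``t0 + 180`` min unconditionally; the
    repeat lactate is due at ``t0 + 360`` min only once an initial lactate has
    resulted above the elevation threshold.
    """
    if not element.conditional:
        return t0 + timedelta(minutes=config.window_3h)
    if initial_lactate is not None and initial_lactate > config.lactate_elevated_threshold:
        return t0 + timedelta(minutes=config.window_6h)
    return None


def _complete(status: ElementStatus, when: datetime) -> None:
    if status.state != "complete":  # first satisfying event wins
        status.state = "complete"
        status.completion_time = when


def apply_event(
    state: EncounterState, event: ClinicalEvent, config: MonitorConfig
) -> EncounterState:
    """Fold one event into the element statuses (idempotent completions)."""
    if event.encounter_id != state.encounter_id:
        raise ValueError("event does not belong to this encounter")
    passthrough = {
        "ed_arrival",
        "bpa_accepted",
        "provider_assigned",
        "provider_unassigned",
        "shift_start",
        "shift_end",
        "transfer",
        "ed_departure",
    }
    if event.time < state.t0:
        if event.kind in passthrough:
            return state
        raise OutOfWindowError(
            f"{event.kind} for {event.encounter_id} at {event.time} precedes t0 {state.t0}"
        )
    if event.kind == "blood_culture_ordered":
        _complete(state.statuses[BundleElement.BLOOD_CULTURES], event.time)
    elif event.kind == "antibiotic_administered":
        _complete(state.statuses[BundleElement.ANTIBIOTICS], event.time)
    elif event.kind == "lactate_resulted":
        state.lactate_draws += 1
        value = float(event.payload.get("value", 0.0))
        if state.lactate_draws == 1:
            state.initial_lactate = value
            _complete(state.statuses[BundleElement.INITIAL_LACTATE], event.time)
            repeat = state.statuses.get(BundleElement.REPEAT_LACTATE)
            if repeat is not None and value > config.lactate_elevated_threshold:
                repeat.state = "pending"
                repeat.deadline = state.t0 + timedelta(minutes=config.window_6h)
        else:
            repeat = state.statuses.get(BundleElement.REPEAT_LACTATE)
            if repeat is not None and repeat.state == "pending":
                _complete(repeat, event.time)
    return state


def _due_pending(state: EncounterState, now: datetime, config: MonitorConfig):
    """Pending required elements whose lead window has opened at ``now``."""
    out = []
    for element in config.monitored_elements:
        status = state.statuses[element]
        if status.state != "pending" or status.deadline is None:
            continue
        if minutes_between(now, status.deadline) >= -config.lead_time:
            out.append(element)
    return tuple(sorted(out, key=ELEMENT_ORDER.index))


def poll(
    state: EncounterState, now: datetime, config: MonitorConfig
) -> tuple[EncounterState, Optional[Alert]]:
    """Evaluate one poll tick; fire at most one alert.

    ``now`` must be a tick on the encounter's own grid (t0 + k * poll
    interval).  The W3 check opens at ``t0 + window_3h - lead_time`` and the
    W6 check at ``t0 + window_6h - lead_time``; each window alerts at most
    once, and the per-encounter cap is enforced last.
    """
    elapsed = minutes_between(now, state.t0)
    if elapsed % config.poll_interval:
        raise ValueError(f"{now} is not a poll tick for t0={state.t0}")
    if elapsed >= config.window_6h:
        state.monitoring_active = False
        return state, None
    if not state.monitoring_active:
        return state, None
    if len(state.alerts_fired) >= config.max_alerts_per_encounter:
        return state, None

    window: Optional[str] = None
    if elapsed >= config.window_6h - config.lead_time and not state.fired_window("W6"):
        window = "W6"
    elif (
        config.window_3h - config.lead_time <= elapsed < config.window_3h
        and not state.fired_window("W3")
    ):
        window = "W3"
    if window is None:
        return state, None

    deficient = _due_pending(state, now, config)
    if window == "W3":
        # only 3-hour elements can trip the early check
        deficient = tuple(e for e in deficient if not e.conditional)
    if not deficient:
        return state, None
    alert = Alert(
        encounter_id=state.encounter_id,
        fire_time=now,
        window=window,
        deficient_elements=deficient,
        alert_index=len(state.alerts_fired) + 1,
    )
    state.alerts_fired.append(alert)
    return state, alert


def run_engine(
    events: Iterable[ClinicalEvent],
    encounters: Iterable[Encounter],
    config: MonitorConfig = MonitorConfig(),
) -> tuple[list[Alert], dict[str, EncounterState]]:
    """Replay a validated log: interleave events with per-encounter poll ticks.

    Events dated at a tick are applied before the tick is evaluated, so a
    completion stamped at the poll minute suppresses the page.  The result is
    deterministic for a given log; alerts come back sorted by fire time.
    """
    by_encounter: dict[str, list[ClinicalEvent]] = {}
    for ev in events:
        by_encounter.setdefault(ev.encounter_id, []).append(ev)

    alerts: list[Alert] = []
    states: dict[str, EncounterState] = {}
    for enc in encounters:
        if enc.t0 is None:
            continue
        state = EncounterState.new(enc.encounter_id, enc.t0, config)
        stream = by_encounter.get(enc.encounter_id, [])
        horizon = enc.t0 + timedelta(minutes=config.window_6h)
        i = 0
        tick = enc.t0
        while tick < horizon:
            while i < len(stream) and stream[i].time <= tick:
                apply_event(state, stream[i], config)
                i += 1
            state, alert = poll(state, tick, config)
            if alert is not None:
                alerts.append(alert)
            tick += timedelta(minutes=config.poll_interval)
        # fold the remaining events so late completions are visible to the
        # adherence metric (pages can no longer fire, but resolution times can
        # land after the monitoring horizon)
        while i < len(stream):
            apply_event(state, stream[i], config)
            i += 1
        state.monitoring_active = False
        states[enc.encounter_id] = state
    alerts.sort(key=lambda a: (a.fire_time, a.encounter_id, a.alert_index))
    return alerts, states
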