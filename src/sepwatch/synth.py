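"""Synthetic ED encounter streams and the deterministic rollout fixture.

Two generators live here:

* :func:`generate_cohort` — a seeded stochastic stream of monitored ED
  encounters with configurable completion-time distributions, used for
  property testing and load experiments.  Defaults mirror the rollout
  conditions the engine was built for: 711 encounters over a 48-day window,
  demographic margins of roughly 58% over 65 years, 55% male and 28% ICU
  admission.
* :func:`table2_fixture` — a fully deterministic 711-encounter cohort whose
  engine -> routing -> metrics replay reproduces the rollout-phase paging
  arithmetic: 272 paged / 439 unpaged encounters, 317 alerts fanning out to
  634 pages, 327 element deficiencies split 68/17/136/106 across cultures /
  initial lactate / antibiotics / repeat lactate with 18/4/17/86 resolved
  within the post-page hour, and 647 attending shifts.  Every timeline is the
  simplest one consistent with those counts; nothing downstream is
  hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .events import BundleElement, ClinicalEvent, Encounter, Shift

__all__ = ["GeneratorParams", "Fixture", "generate_cohort", "table2_fixture"]

_MINUTE = timedelta(minutes=1)

#: 3-hour elements in generation order.
_EARLY = (
    BundleElement.BLOOD_CULTURES,
    BundleElement.INITIAL_LACTATE,
    BundleElement.ANTIBIOTICS,
)

_COMPLETION_KIND = {
    BundleElement.BLOOD_CULTURES: "blood_culture_ordered",
    BundleElement.ANTIBIOTICS: "antibiotic_administered",
}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs for the stochastic cohort generator.

    Completion delays (minutes after t0) are log-normal per element —
    non-negative and right-skewed, the usual shape of task-completion times —
    parameterised by median and log-scale sigma, with an independent
    probability of never completing inside the monitored window.  When
    ``on_time_prob`` is set for an element it overrides the log-normal: the
    element completes comfortably before its lead window opens with that
    probability and otherwise lands late (or never), which makes the
    per-element alerting probability exactly 1 - p.
    """

    n_encounters: int = 711
    study_days: int = 48
    seed: int = 0
    start: datetime = datetime(2020, 1, 13, tzinfo=timezone.utc)
    completion_median_min: dict = field(
        default_factory=lambda: {
            BundleElement.BLOOD_CULTURES: 45.0,
            BundleElement.INITIAL_LACTATE: 50.0,
            BundleElement.ANTIBIOTICS: 100.0,
            BundleElement.REPEAT_LACTATE: 270.0,
        }
    )
    completion_sigma: dict = field(
        default_factory=lambda: {
            BundleElement.BLOOD_CULTURES: 0.6,
            BundleElement.INITIAL_LACTATE: 0.5,
            BundleElement.ANTIBIOTICS: 0.6,
            BundleElement.REPEAT_LACTATE: 0.25,
        }
    )
    never_complete_prob: dict = field(
        default_factory=lambda: {
            BundleElement.BLOOD_CULTURES: 0.04,
            BundleElement.INITIAL_LACTATE: 0.02,
            BundleElement.ANTIBIOTICS: 0.08,
            BundleElement.REPEAT_LACTATE: 0.12,
        }
    )
    p_lactate_elevated: float = 0.30
    pct_over_65: float = 0.582
    pct_male: float = 0.546
    pct_icu: float = 0.278
    n_attendings: int = 20
    n_responders: int = 40
    shift_length_hours: int = 8
    frac_with_responder: float = 1.0
    on_time_prob: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")
        probs = [
            self.p_lactate_elevated,
            self.pct_over_65,
            self.pct_male,
            self.pct_icu,
            self.frac_with_responder,
            *self.never_complete_prob.values(),
            *(self.on_time_prob or {}).values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.completion_median_min.values()):
            raise ValueError("completion medians must be positive")


@dataclass
class Fixture:
    """A generated cohort ready for the engine."""

    events: list[ClinicalEvent]
    encounters: list[Encounter]
    shifts: list[Shift]
    metadata: dict


def _draw_delay(rng: np.random.Generator, params: GeneratorParams, element: BundleElement):
    """Completion delay in minutes after t0, or None for never-completed."""
    early = element is not BundleElement.REPEAT_LACTATE
    if params.on_time_prob and element in params.on_time_prob:
        lead_open = 120 if early else 300
        if rng.random() < params.on_time_prob[element]:
            return int(rng.integers(20, lead_open - 10))
        if rng.random() < params.never_complete_prob.get(element, 0.0):
            return None
        # late but before the monitoring horizon closes the 3-h story for
        # the repeat draw (the initial lactate must result before t0+300)
        hi = 290 if early else 420
        return int(rng.integers(lead_open + 10, hi))
    if rng.random() < params.never_complete_prob.get(element, 0.0):
        return None
    median = params.completion_median_min[element]
    sigma = params.completion_sigma[element]
    return max(1, int(round(median * float(np.exp(sigma * rng.standard_normal())))))


def generate_cohort(params: GeneratorParams) -> Fixture:
    """Draw a reproducible synthetic cohort (same params + seed => same log)."""
    rng = np.random.default_rng(params.seed)
    window_min = params.study_days * 1440
    events: list[ClinicalEvent] = []
    encounters: list[Encounter] = []

    for i in range(params.n_encounters):
        enc_id = f"E{i + 1:05d}"
        pid = f"P{i + 1:05d}"
        t0 = params.start + int(rng.integers(0, window_min)) * _MINUTE
        over65 = rng.random() < params.pct_over_65
        age = int(rng.integers(66, 96)) if over65 else int(rng.integers(18, 66))
        sex = "male" if rng.random() < params.pct_male else "female"
        icu = bool(rng.random() < params.pct_icu)
        los = float(np.round(2.0 + rng.gamma(shape=2.5, scale=2.5), 1))
        encounters.append(
            Encounter(enc_id, t0=t0, patient_id=pid, age=age, sex=sex,
                      icu_admitted=icu, ed_los_hours=los)
        )
        events.append(
            ClinicalEvent(
                enc_id, t0 - 30 * _MINUTE, "ed_arrival",
                {"patient_id": pid, "age": age, "sex": sex},
            )
        )
        events.append(ClinicalEvent(enc_id, t0, "bpa_accepted", {}))
        events.append(
            ClinicalEvent(
                enc_id, t0, "provider_assigned",
                {"provider_id": f"A{int(rng.integers(params.n_attendings)) + 1:02d}",
                 "role": "attending"},
            )
        )
        if rng.random() < params.frac_with_responder:
            events.append(
                ClinicalEvent(
                    enc_id, t0, "provider_assigned",
                    {"provider_id": f"R{int(rng.integers(params.n_responders)) + 1:02d}",
                     "role": "resident"},
                )
            )

        elevated = rng.random() < params.p_lactate_elevated
        lactate_time: Optional[int] = None
        for element in _EARLY:
            delay = _draw_delay(rng, params, element)
            if delay is None:
                continue
            if element is BundleElement.INITIAL_LACTATE:
                lactate_time = delay
                value = (
                    float(np.round(2.1 + rng.gamma(2.0, 1.0), 1))
                    if elevated
                    else float(np.round(0.5 + 1.4 * rng.random(), 1))
                )
                events.append(
                    ClinicalEvent(
                        enc_id, t0 + delay * _MINUTE, "lactate_resulted",
                        {"value": value, "draw_index": 1},
                    )
                )
            else:
                events.append(
                    ClinicalEvent(enc_id, t0 + delay * _MINUTE, _COMPLETION_KIND[element], {})
                )
        if elevated and lactate_time is not None:
            delay = _draw_delay(rng, params, BundleElement.REPEAT_LACTATE)
            if delay is not None:
                delay = max(delay, lactate_time + 5)
                events.append(
                    ClinicalEvent(
                        enc_id, t0 + delay * _MINUTE, "lactate_resulted",
                        {"value": float(np.round(0.8 + 1.0 * rng.random(), 1)),
                         "draw_index": 2},
                    )
                )
        events.append(
            ClinicalEvent(enc_id, t0 + int(round(los * 60)) * _MINUTE, "ed_departure", {})
        )

    shifts = _roster_shifts(
        params.start, params.study_days, params.n_attendings, params.shift_length_hours
    )
    events.sort(key=lambda e: e.time)
    return Fixture(events, encounters, shifts, {"study_days": params.study_days,
                                                "seed": params.seed})


def _roster_shifts(start: datetime, study_days: int, n_attendings: int,
                   shift_length_hours: int) -> list[Shift]:
    """Continuous attending coverage: back-to-back shifts, rotating roster."""
    shifts: list[Shift] = []
    length = shift_length_hours * 60
    t = 0
    j = 0
    horizon = study_days * 1440
    while t < horizon:
        end = min(t + length, horizon)
        shifts.append(
            Shift(f"A{j % n_attendings + 1:02d}", "attending",
                  start + t * _MINUTE, start + end * _MINUTE)
        )
        t = end
        j += 1
    return shifts


# ---------------------------------------------------------------------------
# Deterministic rollout fixture
# ---------------------------------------------------------------------------

#: (class, detail) per encounter; order fixes encounter ids.
def _fixture_specs() -> list[tuple[str, object]]:
    specs: list[tuple[str, object]] = []
    specs += [("clean", None)] * 439
    specs += [("w3", (BundleElement.BLOOD_CULTURES, True))] * 18
    specs += [("w3", (BundleElement.BLOOD_CULTURES, False))] * 40
    specs += [("w3", (BundleElement.ANTIBIOTICS, True))] * 17
    specs += [("w3", (BundleElement.ANTIBIOTICS, False))] * 64
    specs += [("w3", (BundleElement.INITIAL_LACTATE, True))] * 4
    specs += [("w3", (BundleElement.INITIAL_LACTATE, False))] * 13
    specs += [("w3pair", None)] * 10
    specs += [("w6", True)] * 55
    specs += [("w6", False)] * 6
    specs += [("both", True)] * 31
    specs += [("both", False)] * 14
    assert len(specs) == 711
    return specs


def table2_fixture() -> Fixture:
    """The deterministic 711-encounter rollout cohort (no randomness).

    Encounter timelines fall into six classes:

    ========  =====  ==========================================================
    class     count  story
    ========  =====  ==========================================================
    clean       439  every element done ~1 h into the window; no page
    w3          156  one 3-h element late (done at t0+150 if resolved within
                     the post-page hour, t0+200 if not); single W3 page
    w3pair       10  cultures *and* antibiotics late (t0+200); one W3 page
                     listing both
    w6           61  3-h elements on time, initial lactate elevated; repeat
                     drawn at t0+330 (adherent) or never; single W6 page
    both         45  antibiotics late (t0+200) *and* elevated initial lactate
                     with the repeat at t0+330 or never; W3 + W6 pages
    ========  =====  ==========================================================

    711 encounters are spread over 48 days (14-15/day); 63 of the 648 distinct
    patients contribute two encounters.  647 attending shifts tile the window.
    """
    start = datetime(2020, 1, 13, tzinfo=timezone.utc)
    specs = _fixture_specs()
    events: list[ClinicalEvent] = []
    encounters: list[Encounter] = []

    for i, (klass, detail) in enumerate(specs):
        enc_id = f"E{i + 1:04d}"
        p = i if i < 63 else i - 63  # patients 0..62 revisit once
        pid = f"P{p + 1:04d}"
        day, slot = i % 48, i // 48
        t0 = start + (day * 1440 + 8 * 60 + slot * 45) * _MINUTE

        age = 70 if p < 377 else 45
        sex = "female" if p >= 354 else "male"
        icu = p < 180
        los = 5.0 if p < 236 else (8.0 if p < 575 else None)
        encounters.append(
            Encounter(enc_id, t0=t0, patient_id=pid, age=age, sex=sex,
                      icu_admitted=icu, ed_los_hours=los)
        )

        def ev(offset_min: int, kind: str, payload: Optional[dict] = None) -> None:
            events.append(ClinicalEvent(enc_id, t0 + offset_min * _MINUTE, kind,
                                        payload or {}))

        ev(-30, "ed_arrival", {"patient_id": pid, "age": age, "sex": sex})
        ev(0, "bpa_accepted")
        ev(0, "provider_assigned", {"provider_id": f"R{i % 40 + 1:02d}", "role": "resident"})
        ev(0, "provider_assigned", {"provider_id": f"A{i % 20 + 1:02d}", "role": "attending"})

        # element completion offsets (minutes after t0); None = never
        bc, lac1, abx = 50, 55, 60
        lac1_value, lac2 = 1.2, None
        if klass == "w3":
            element, adherent = detail  # type: ignore[misc]
            late = 150 if adherent else 200
            if element is BundleElement.BLOOD_CULTURES:
                bc = late
            elif element is BundleElement.ANTIBIOTICS:
                abx = late
            else:
                lac1, lac1_value = late, 1.4
        elif klass == "w3pair":
            bc = abx = 200
        elif klass == "w6":
            lac1_value = 3.5
            lac2 = 330 if detail else None
        elif klass == "both":
            abx, lac1_value = 200, 3.5
            lac2 = 330 if detail else None

        ev(bc, "blood_culture_ordered")
        ev(lac1, "lactate_resulted", {"value": lac1_value, "draw_index": 1})
        ev(abx, "antibiotic_administered")
        if lac2 is not None:
            ev(lac2, "lactate_resulted", {"value": 1.8, "draw_index": 2})
        ev(420, "ed_departure")

    # 647 attending shifts tiling the 48-day window: 8-hour shifts started
    # every 106 minutes across a 20-attending roster (646*106+480 < 48*1440).
    shifts = [
        Shift(f"A{j % 20 + 1:02d}", "attending",
              start + (j * 106) * _MINUTE, start + (j * 106 + 480) * _MINUTE)
        for j in range(647)
    ]

    events.sort(key=lambda e: e.time)
    return Fixture(
        events,
        encounters,
        shifts,
        {"study_days": 48, "n_ed_encounters": 15770, "name": "table2"},
    )
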