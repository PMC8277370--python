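"""Cohort outcome measures: alert burden, etiology and post-alert adherence.

These are the quantities a quality-improvement team reads off a monitoring
period: how many encounters were paged at all, how many pages each attending
shift absorbed (the alarm-fatigue surrogate), which bundle element drove each
deficiency, and how often a paged deficiency was resolved within the hour
after the page.

Attribution rule: each (encounter, element) deficiency is counted once,
against the first alert that listed it — a deficiency still present on the
second page is not double-counted.  Percentages are rounded half-up to one
decimal on the 0-100 scale, ratios to two decimals, matching how such
programme reports are conventionally printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .engine import Alert, EncounterState, MonitorConfig
from .events import ELEMENT_ORDER, BundleElement, Encounter, Shift
from .paging import Page

__all__ = [
    "DeficiencyRecord",
    "MetricsReport",
    "build_deficiencies",
    "cohort_metrics",
    "pilot_survey_summary",
]

ADHERENCE_WINDOW_MIN = 60  # completion within the hour after the page counts


def round1(num: float | int, den: float | int) -> Optional[float]:
    """num/den as a percentage, one decimal, half-up; None on zero denominator."""
    if not den:
        return None
    q = Decimal(num) / Decimal(den) * 100
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round2(num: float | int, den: float | int) -> Optional[float]:
    if not den:
        return None
    q = Decimal(num) / Decimal(den)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DeficiencyRecord:
    """One paged (encounter, element) deficiency and its resolution."""

    encounter_id: str
    element: BundleElement
    fire_time: datetime  # first alert listing this element
    deadline: Optional[datetime]
    resolved_time: Optional[datetime]
    adherent: bool


def build_deficiencies(
    alerts: Sequence[Alert],
    states: Mapping[str, EncounterState],
    config: MonitorConfig = MonitorConfig(),
) -> list[DeficiencyRecord]:
    """One record per (encounter, element), attributed to its first alert.

    A deficiency is adherent when the element was completed within 60 minutes
    of that first page — the operational success definition, kept even when
    tick quantisation fires the page later than deadline minus lead.
    """
    seen: set[tuple[str, BundleElement]] = set()
    records: list[DeficiencyRecord] = []
    for alert in sorted(alerts, key=lambda a: (a.fire_time, a.encounter_id)):
        state = states[alert.encounter_id]
        for element in alert.deficient_elements:
            key = (alert.encounter_id, element)
            if key in seen:
                continue
            seen.add(key)
            status = state.statuses[element]
            resolved = status.completion_time
            adherent = resolved is not None and resolved <= alert.fire_time + timedelta(
                minutes=ADHERENCE_WINDOW_MIN
            )
            records.append(
                DeficiencyRecord(
                    alert.encounter_id,
                    element,
                    alert.fire_time,
                    status.deadline,
                    resolved,
                    adherent,
                )
            )
    return records


@dataclass
class MetricsReport:
    """Machine-readable monitoring-period report."""

    n_ed_encounters: Optional[int]
    n_monitored: int
    n_paged_encounters: int
    pct_paged: Optional[float]
    n_unpaged_encounters: int
    pct_unpaged: Optional[float]
    n_pages: int
    pages_per_monitored: Optional[float]
    n_attending_shifts: Optional[int]
    pages_per_attending_shift: Optional[float]
    n_alerts: int
    n_deficiencies: int
    etiology: dict[str, dict]  # element -> {count, pct}
    adherence: dict[str, dict]  # element -> {count, denominator, rate}
    overall_adherence: dict
    demographics: dict
    encounters_per_day: dict

    def to_dict(self) -> dict:
        return {
            "n_ed_encounters": self.n_ed_encounters,
            "n_monitored": self.n_monitored,
            "n_paged_encounters": self.n_paged_encounters,
            "pct_paged": self.pct_paged,
            "n_unpaged_encounters": self.n_unpaged_encounters,
            "pct_unpaged": self.pct_unpaged,
            "n_pages": self.n_pages,
            "pages_per_monitored": self.pages_per_monitored,
            "n_attending_shifts": self.n_attending_shifts,
            "pages_per_attending_shift": self.pages_per_attending_shift,
            "n_alerts": self.n_alerts,
            "n_deficiencies": self.n_deficiencies,
            "etiology": self.etiology,
            "adherence": self.adherence,
            "overall_adherence": self.overall_adherence,
            "demographics": self.demographics,
            "encounters_per_day": self.encounters_per_day,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_markdown(self) -> str:
        def fmt(x):
            return "—" if x is None else x

        lines = [
            "# Monitoring period report",
            "",
            "| Measure | Value |",
            "|---|---|",
            f"| ED encounters | {fmt(self.n_ed_encounters)} |",
            f"| Encounters in active monitoring | {self.n_monitored} |",
            f"| Total pages | {self.n_pages} |",
            f"| Pages per monitored encounter | {fmt(self.pages_per_monitored)} |",
            f"| Pages per attending shift | {fmt(self.pages_per_attending_shift)} |",
            f"| Encounters with at least one page, n (%) | {self.n_paged_encounters} ({fmt(self.pct_paged)}) |",
            f"| Encounters with no pages, n (%) | {self.n_unpaged_encounters} ({fmt(self.pct_unpaged)}) |",
            "",
            f"## Alert etiology (n={self.n_deficiencies}), n (%)",
            "",
            "| Element | n (%) |",
            "|---|---|",
        ]
        for element in ELEMENT_ORDER:
            e = self.etiology.get(element.value)
            if e:
                lines.append(f"| {element.label.capitalize()} | {e['count']} ({fmt(e['pct'])}) |")
        lines += ["", "## Post-alert successful adherence, n (%)", ""]
        if self.overall_adherence.get("rate") is None:
            lines.append("No paged deficiencies in this period.")
        else:
            lines += ["| Element | n (%) |", "|---|---|"]
            lines.append(
                f"| Total | {self.overall_adherence['count']} ({self.overall_adherence['rate']}) |"
            )
            for element in ELEMENT_ORDER:
                a = self.adherence.get(element.value)
                if a:
                    lines.append(
                        f"| {element.label.capitalize()} | {a['count']} ({fmt(a['rate'])}) |"
                    )
        demo = self.demographics
        if demo.get("n_patients"):
            lines += [
                "",
                f"## Patient demographics (N={demo['n_patients']}), n (%)",
                "",
                "| Characteristic | n (%) |",
                "|---|---|",
            ]
            for label, key in [
                ("Age 18-65", "age_18_65"),
                ("Age >65", "age_over_65"),
                ("Female", "sex_female"),
                ("Male", "sex_male"),
                ("ICU admission", "icu_admitted"),
                ("ED LOS <=6 h", "ed_los_le_6h"),
                ("ED LOS >6 h", "ed_los_gt_6h"),
                ("ED LOS unknown", "ed_los_unknown"),
            ]:
                bin_ = demo.get(key)
                if bin_ is not None:
                    lines.append(f"| {label} | {bin_['count']} ({fmt(bin_['pct'])}) |")
        return "\n".join(lines) + "\n"


def _demographics(encounters: Sequence[Encounter]) -> dict:
    """Patient-level demographic bins (an encounter list may repeat patients)."""
    patients: dict[str, Encounter] = {}
    for enc in encounters:
        pid = enc.patient_id or enc.encounter_id
        patients.setdefault(pid, enc)
    n = len(patients)
    if n == 0:
        return {"n_patients": 0}

    def bin_(count: int) -> dict:
        return {"count": count, "pct": round1(count, n)}

    ages = [p.age for p in patients.values() if p.age is not None]
    sexes = [p.sex for p in patients.values() if p.sex]
    los = [p.ed_los_hours for p in patients.values()]
    out = {"n_patients": n}
    if ages:
        out["age_18_65"] = bin_(sum(1 for a in ages if a <= 65))
        out["age_over_65"] = bin_(sum(1 for a in ages if a > 65))
    if sexes:
        out["sex_female"] = bin_(sum(1 for s in sexes if s == "female"))
        out["sex_male"] = bin_(sum(1 for s in sexes if s == "male"))
    icu = [p.icu_admitted for p in patients.values() if p.icu_admitted is not None]
    if icu:
        out["icu_admitted"] = bin_(sum(icu))
    if any(l is not None for l in los):
        out["ed_los_le_6h"] = bin_(sum(1 for l in los if l is not None and l <= 6))
        out["ed_los_gt_6h"] = bin_(sum(1 for l in los if l is not None and l > 6))
        out["ed_los_unknown"] = bin_(sum(1 for l in los if l is None))
    return out


def _encounters_per_day(encounters: Sequence[Encounter], study_days: Optional[int]) -> dict:
    times = sorted(e.t0 for e in encounters if e.t0 is not None)
    if not times:
        return {"mean": None, "sd": None}
    first_day = times[0].date()
    if study_days is None:
        study_days = (times[-1].date() - first_day).days + 1
    counts = [0] * study_days
    for t in times:
        idx = (t.date() - first_day).days
        if 0 <= idx < study_days:
            counts[idx] += 1
    n = len(counts)
    mean = sum(counts) / n
    sd = (sum((c - mean) ** 2 for c in counts) / (n - 1)) ** 0.5 if n > 1 else None
    return {
        "mean": float(Decimal(mean).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)),
        "sd": None if sd is None else float(Decimal(sd).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)),
        "study_days": study_days,
    }


def cohort_metrics(
    encounters: Sequence[Encounter],
    alerts: Sequence[Alert],
    pages: Sequence[Page],
    shifts: Optional[Sequence[Shift]] = None,
    deficiencies: Optional[Sequence[DeficiencyRecord]] = None,
    study_days: Optional[int] = None,
    n_ed_encounters: Optional[int] = None,
) -> MetricsReport:
    """Populate the full monitoring-period report.

    ``deficiencies`` defaults to first-alert attribution computed upstream by
    :func:`build_deficiencies`; zero denominators surface as absent (None)
    fields rather than zeros.
    """
    monitored = [e for e in encounters if e.t0 is not None]
    n_monitored = len(monitored)
    paged_ids = {p.alert.encounter_id for p in pages}
    n_paged = len(paged_ids)
    n_unpaged = n_monitored - n_paged
    n_pages = len(pages)
    attending_shifts = (
        [s for s in shifts if s.role == "attending"] if shifts is not None else None
    )
    n_shifts = len(attending_shifts) if attending_shifts is not None else None

    deficiencies = list(deficiencies or [])
    n_def = len(deficiencies)
    etiology: dict[str, dict] = {}
    adherence: dict[str, dict] = {}
    for element in ELEMENT_ORDER:
        recs = [d for d in deficiencies if d.element is element]
        if not recs and n_def == 0:
            continue
        n_elem = len(recs)
        n_adh = sum(d.adherent for d in recs)
        etiology[element.value] = {"count": n_elem, "pct": round1(n_elem, n_def)}
        adherence[element.value] = {
            "count": n_adh,
            "denominator": n_elem,
            "rate": round1(n_adh, n_elem),
        }
    n_adherent = sum(d.adherent for d in deficiencies)
    overall = {
        "count": n_adherent,
        "denominator": n_def,
        "rate": round1(n_adherent, n_def),
    }

    return MetricsReport(
        n_ed_encounters=n_ed_encounters,
        n_monitored=n_monitored,
        n_paged_encounters=n_paged,
        pct_paged=round1(n_paged, n_monitored),
        n_unpaged_encounters=n_unpaged,
        pct_unpaged=round1(n_unpaged, n_monitored),
        n_pages=n_pages,
        pages_per_monitored=round2(n_pages, n_monitored),
        n_attending_shifts=n_shifts,
        pages_per_attending_shift=(
            round2(n_pages, n_shifts) if n_shifts else None
        ),
        n_alerts=len(alerts),
        n_deficiencies=n_def,
        etiology=etiology,
        adherence=adherence,
        overall_adherence=overall,
        demographics=_demographics(monitored),
        encounters_per_day=_encounters_per_day(monitored, study_days),
    )


def pilot_survey_summary(responses: Iterable[int]) -> dict:
    """Summarise 1-5 helpfulness ratings; 'helpful' means a rating of 3+.

    Returns per-level counts and the percentage rating >= 3 (None when there
    are no responses).
    """
    responses = list(responses)
    for r in responses:
        if not isinstance(r, int) or not 1 <= r <= 5:
            raise ValueError(f"rating {r!r} outside 1..5")
    counts = {level: sum(1 for r in responses if r == level) for level in range(1, 6)}
    n = len(responses)
    helpful = sum(counts[level] for level in (3, 4, 5))
    return {
        "n": n,
        "counts": counts,
        "n_helpful": helpful,
        "pct_helpful": None if n == 0 else round(100 * helpful / n),
    }
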