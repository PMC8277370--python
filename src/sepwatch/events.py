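"""Event-log schema, domain types, readers/writers and validation.

The canonical interchange format is JSON-lines: one clinical event per line,
``{"encounter_id": str, "time": ISO-8601 UTC, "kind": str, "payload": {...}}``.
Timestamps are absolute UTC at minute resolution and all window arithmetic
downstream is done in integer minutes, so nothing here ever touches floats.

An encounter enters active monitoring when a sepsis best-practice alert (BPA)
is accepted by a provider; that acceptance time is the sepsis clock zero
(``t0``) for every bundle deadline.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import IO, Iterable, Optional

__all__ = [
    "EVENT_KINDS",
    "ROLES",
    "RESPONDING_ROLES",
    "BundleElement",
    "ClinicalEvent",
    "Encounter",
    "ProviderAssignment",
    "Shift",
    "Violation",
    "EventLogError",
    "ValidationError",
    "parse_time",
    "format_time",
    "minutes_between",
    "read_event_log",
    "write_event_log",
    "read_encounters_csv",
    "write_encounters_csv",
    "validate_events",
    "extract_shifts",
    "extract_assignments",
]

EVENT_KINDS = frozenset(
    {
        "ed_arrival",
        "bpa_accepted",
        "blood_culture_ordered",
        "lactate_resulted",
        "antibiotic_administered",
        "provider_assigned",
        "provider_unassigned",
        "shift_start",
        "shift_end",
        "transfer",
        "ed_departure",
    }
)

#: Event kinds that mark a monitored clinical fact; an encounter carrying any
#: of these must also carry a bpa_accepted event.
CLINICAL_KINDS = frozenset(
    {"blood_culture_ordered", "lactate_resulted", "antibiotic_administered"}
)

ROLES = frozenset({"attending", "resident", "np", "pa"})
RESPONDING_ROLES = frozenset({"resident", "np", "pa"})


class EventLogError(ValueError):
    """Malformed event log (bad JSON, bad timestamp, unknown kind)."""


class ValidationError(ValueError):
    """Structurally parseable log that breaks a monitoring precondition."""


class BundleElement(enum.Enum):
    """The four monitored SEP-1 bundle elements.

    Blood cultures, the initial lactate and antibiotics are due 3 hours after
    sepsis onset (t0); the repeat lactate is due at 6 hours and only when the
    initial lactate is elevated.  Display order follows the care sequence.
    """

    BLOOD_CULTURES = "blood_cultures"
    INITIAL_LACTATE = "initial_lactate"
    ANTIBIOTICS = "antibiotics"
    REPEAT_LACTATE = "repeat_lactate"

    @property
    def window_hours(self) -> int:
        return 6 if self is BundleElement.REPEAT_LACTATE else 3

    @property
    def conditional(self) -> bool:
        return self is BundleElement.REPEAT_LACTATE

    @property
    def label(self) -> str:
        return {
            BundleElement.BLOOD_CULTURES: "blood cultures",
            BundleElement.INITIAL_LACTATE: "initial lactate",
            BundleElement.ANTIBIOTICS: "antibiotics",
            BundleElement.REPEAT_LACTATE: "repeat lactate",
        }[self]


#: Fixed ordering used in page text and reports.
ELEMENT_ORDER = (
    BundleElement.BLOOD_CULTURES,
    BundleElement.INITIAL_LACTATE,
    BundleElement.ANTIBIOTICS,
    BundleElement.REPEAT_LACTATE,
)


def parse_time(value: str) -> datetime:
    """Parse an ISO-8601 timestamp into an aware UTC datetime.

    Accepts a trailing ``Z`` or an explicit offset; naive stamps are taken as
    UTC.  Seconds/microseconds are truncated to minute resolution.
    """
    try:
        dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    except (ValueError, AttributeError, TypeError) as exc:
        raise EventLogError(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).replace(second=0, microsecond=0)


def format_time(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%MZ")


def minutes_between(later: datetime, earlier: datetime) -> int:
    """Whole minutes from ``earlier`` to ``later`` (negative if reversed)."""
    return int((later - earlier).total_seconds() // 60)


@dataclass(frozen=True)
class ClinicalEvent:
    """One time-stamped fact about an encounter."""

    encounter_id: str
    time: datetime
    kind: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "encounter_id": self.encounter_id,
                "time": format_time(self.time),
                "kind": self.kind,
                "payload": self.payload,
            },
            sort_keys=True,
        )


@dataclass
class Encounter:
    """A monitored ED encounter; ``t0`` is the BPA-acceptance time."""

    encounter_id: str
    t0: Optional[datetime] = None
    patient_id: Optional[str] = None
    age: Optional[int] = None
    sex: Optional[str] = None
    icu_admitted: Optional[bool] = None
    ed_los_hours: Optional[float] = None
    arrival: Optional[datetime] = None


@dataclass
class ProviderAssignment:
    """Half-open assignment interval [start, end); end is None while active."""

    encounter_id: str
    provider_id: str
    role: str
    start: datetime
    end: Optional[datetime] = None

    def covers(self, t: datetime) -> bool:
        return self.start <= t and (self.end is None or t < self.end)


@dataclass(frozen=True)
class Shift:
    """One provider shift record, [start, end)."""

    provider_id: str
    role: str
    start: datetime
    end: datetime


@dataclass(frozen=True)
class Violation:
    """A single invariant breach found by :func:`validate_events`."""

    encounter_id: str
    message: str
    event_index: Optional[int] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (event #{self.event_index})" if self.event_index is not None else ""
        return f"[{self.encounter_id}] {self.message}{loc}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_event_log(
    source: IO[str] | Iterable[str] | str,
) -> tuple[list[ClinicalEvent], list[Encounter]]:
    """Read a JSON-lines event log.

    Returns events stably sorted by (time, input order) and the Encounter
    records materialised from arrival/BPA events.  Any encounter with a
    monitored clinical event but no ``bpa_accepted`` raises
    :class:`ValidationError` — such a log cannot be replayed against the
    bundle clock.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    events: list[ClinicalEvent] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise EventLogError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
        if not isinstance(obj, dict):
            raise EventLogError(f"line {lineno}: expected a JSON object")
        try:
            enc = obj["encounter_id"]
            time = parse_time(obj["time"])
            kind = obj["kind"]
        except KeyError as exc:
            raise EventLogError(f"line {lineno}: missing field {exc.args[0]!r}") from exc
        except EventLogError as exc:
            raise EventLogError(f"line {lineno}: {exc}") from exc
        if kind not in EVENT_KINDS:
            raise EventLogError(f"line {lineno}: unknown event kind {kind!r}")
        events.append(ClinicalEvent(str(enc), time, kind, obj.get("payload") or {}))

    events.sort(key=lambda e: e.time)  # stable: equal-time keeps input order

    encounters: dict[str, Encounter] = {}
    needs_bpa: set[str] = set()
    for ev in events:
        if ev.kind in ("shift_start", "shift_end") and not ev.encounter_id:
            continue  # roster events need not belong to an encounter
        enc = encounters.setdefault(ev.encounter_id, Encounter(ev.encounter_id))
        if ev.kind == "ed_arrival":
            enc.arrival = ev.time
            for key in ("patient_id", "sex"):
                if key in ev.payload:
                    setattr(enc, key, ev.payload[key])
            if "age" in ev.payload:
                enc.age = int(ev.payload["age"])
        elif ev.kind == "bpa_accepted" and enc.t0 is None:
            enc.t0 = ev.time
        elif ev.kind in CLINICAL_KINDS:
            needs_bpa.add(ev.encounter_id)

    missing = sorted(e for e in needs_bpa if encounters[e].t0 is None)
    if missing:
        raise ValidationError(
            "monitored encounter(s) missing bpa_accepted: " + ", ".join(missing)
        )
    return events, list(encounters.values())


def write_event_log(events: Iterable[ClinicalEvent], sink: IO[str]) -> None:
    for ev in events:
        sink.write(ev.to_json())
        sink.write("\n")


def read_encounters_csv(source: IO[str] | str) -> dict[str, dict]:
    """Read the optional demographics sidecar; returns encounter_id -> fields."""
    if isinstance(source, str):
        source = io.StringIO(source)
    out: dict[str, dict] = {}
    for row in csv.DictReader(source):
        rec: dict = {"patient_id": row.get("patient_id") or None}
        rec["age"] = int(row["age"]) if row.get("age") else None
        rec["sex"] = row.get("sex") or None
        icu = (row.get("icu_admitted") or "").strip().lower()
        rec["icu_admitted"] = {"true": True, "1": True, "false": False, "0": False}.get(
            icu
        )
        los = (row.get("ed_los_hours") or "").strip()
        rec["ed_los_hours"] = float(los) if los else None
        out[row["encounter_id"]] = rec
    return out


def write_encounters_csv(encounters: Iterable[Encounter], sink: IO[str]) -> None:
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(
        ["encounter_id", "patient_id", "age", "sex", "icu_admitted", "ed_los_hours"]
    )
    for enc in encounters:
        writer.writerow(
            [
                enc.encounter_id,
                enc.patient_id or "",
                enc.age if enc.age is not None else "",
                enc.sex or "",
                "" if enc.icu_admitted is None else str(enc.icu_admitted).lower(),
                "" if enc.ed_los_hours is None else f"{enc.ed_los_hours:g}",
            ]
        )


def merge_demographics(encounters: list[Encounter], sidecar: dict[str, dict]) -> None:
    for enc in encounters:
        rec = sidecar.get(enc.encounter_id)
        if not rec:
            continue
        for key, value in rec.items():
            if value is not None:
                setattr(enc, key, value)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_events(events: list[ClinicalEvent]) -> list[Violation]:
    """Return every invariant breach; an empty list means the log is clean.

    Violations are data, not exceptions: a monitoring pipeline wants the full
    list, and a clean log is simply the empty list.
    """
    violations: list[Violation] = []
    last_time: dict[str, datetime] = {}
    draws: dict[str, list[int]] = {}
    bpa_count: dict[str, int] = {}

    for idx, ev in enumerate(events):
        prev = last_time.get(ev.encounter_id)
        if prev is not None and ev.time < prev:
            violations.append(
                Violation(ev.encounter_id, "events out of time order", idx)
            )
        last_time[ev.encounter_id] = ev.time

        if ev.kind == "lactate_resulted":
            value = ev.payload.get("value")
            if not isinstance(value, (int, float)) or value <= 0:
                violations.append(
                    Violation(ev.encounter_id, f"lactate value {value!r} not > 0", idx)
                )
            draw = ev.payload.get("draw_index")
            if not isinstance(draw, int) or draw < 1:
                violations.append(
                    Violation(ev.encounter_id, f"draw_index {draw!r} not >= 1", idx)
                )
            else:
                draws.setdefault(ev.encounter_id, []).append(draw)
        elif ev.kind in (
            "provider_assigned",
            "provider_unassigned",
            "shift_start",
            "shift_end",
        ):
            role = ev.payload.get("role")
            if role not in ROLES:
                violations.append(
                    Violation(ev.encounter_id, f"unknown provider role {role!r}", idx)
                )
            if not ev.payload.get("provider_id"):
                violations.append(
                    Violation(ev.encounter_id, "missing provider_id", idx)
                )
        elif ev.kind == "bpa_accepted":
            bpa_count[ev.encounter_id] = bpa_count.get(ev.encounter_id, 0) + 1

    for enc_id, seq in draws.items():
        expected = list(range(1, len(seq) + 1))
        if sorted(seq) != expected:
            violations.append(
                Violation(enc_id, f"lactate draw_index sequence {sorted(seq)} has gaps")
            )
    for enc_id, n in bpa_count.items():
        if n > 1:
            violations.append(Violation(enc_id, f"{n} bpa_accepted events (expected 1)"))
    return violations


# ---------------------------------------------------------------------------
# Derived collections
# ---------------------------------------------------------------------------


def extract_shifts(events: Iterable[ClinicalEvent]) -> list[Shift]:
    """Pair shift_start/shift_end events into Shift records (per provider)."""
    open_shifts: dict[tuple[str, str], datetime] = {}
    shifts: list[Shift] = []
    for ev in events:
        if ev.kind not in ("shift_start", "shift_end"):
            continue
        key = (ev.payload.get("provider_id", ""), ev.payload.get("role", ""))
        if ev.kind == "shift_start":
            open_shifts[key] = ev.time
        else:
            start = open_shifts.pop(key, None)
            if start is not None:
                shifts.append(Shift(key[0], key[1], start, ev.time))
    # a dangling shift_start is an open shift; close it at its own start + 24 h
    for (pid, role), start in open_shifts.items():
        shifts.append(Shift(pid, role, start, start + timedelta(hours=24)))
    shifts.sort(key=lambda s: (s.start, s.provider_id))
    return shifts


def read_shifts_csv(source: IO[str] | str) -> list[Shift]:
    if isinstance(source, str):
        source = io.StringIO(source)
    shifts = [
        Shift(
            row["provider_id"],
            row["role"],
            parse_time(row["start"]),
            parse_time(row["end"]),
        )
        for row in csv.DictReader(source)
    ]
    shifts.sort(key=lambda s: (s.start, s.provider_id))
    return shifts


def write_shifts_csv(shifts: Iterable[Shift], sink: IO[str]) -> None:
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(["provider_id", "role", "start", "end"])
    for s in shifts:
        writer.writerow([s.provider_id, s.role, format_time(s.start), format_time(s.end)])


def extract_assignments(
    events: Iterable[ClinicalEvent],
) -> dict[str, list[ProviderAssignment]]:
    """Chain provider_assigned/unassigned events into assignment intervals.

    A new assignment for an (encounter, role) closes any assignment still open
    for that role — the roles hand off rather than overlap.
    """
    by_encounter: dict[str, list[ProviderAssignment]] = {}
    open_by_role: dict[tuple[str, str], ProviderAssignment] = {}
    for ev in events:
        if ev.kind == "provider_assigned":
            key = (ev.encounter_id, ev.payload.get("role", ""))
            current = open_by_role.get(key)
            if current is not None and current.end is None:
                current.end = ev.time
            assignment = ProviderAssignment(
                ev.encounter_id,
                ev.payload.get("provider_id", ""),
                ev.payload.get("role", ""),
                ev.time,
            )
            open_by_role[key] = assignment
            by_encounter.setdefault(ev.encounter_id, []).append(assignment)
        elif ev.kind == "provider_unassigned":
            key = (ev.encounter_id, ev.payload.get("role", ""))
            current = open_by_role.get(key)
            if current is not None and current.end is None:
                current.end = ev.time
    return by_encounter
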