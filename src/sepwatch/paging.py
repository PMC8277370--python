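"""Resolve alerts to page recipients and render the pager text.

Every alert is delivered to the encounter's active responding clinician (the
resident, NP or PA placing orders) and to the supervising attending; bedside
nurses carry no pagers and are never recipients.  If no responding clinician
is assigned at fire time the attending is paged alone.  Pages carry no
queuing delay: send time equals the alert's fire time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import IO, Iterable, Mapping, Optional

from .engine import Alert
from .events import (
    ELEMENT_ORDER,
    RESPONDING_ROLES,
    Encounter,
    ProviderAssignment,
    Shift,
    format_time,
)

__all__ = ["Page", "RoutingError", "recipients_for", "render_page", "dispatch"]

_ROLE_SORT = {"resident": 0, "np": 0, "pa": 0, "attending": 1}


class RoutingError(ValueError):
    """No deliverable recipient for an alert."""


@dataclass(frozen=True)
class Page:
    """One alert delivered to one provider."""

    alert: Alert
    recipient_provider_id: str
    recipient_role: str
    send_time: datetime
    message: str


def _active(
    assignments: Iterable[ProviderAssignment], t: datetime, roles
) -> Optional[ProviderAssignment]:
    """Most recently started assignment in ``roles`` covering ``t``."""
    best: Optional[ProviderAssignment] = None
    for a in assignments:
        if a.role in roles and a.covers(t):
            if best is None or a.start > best.start:
                best = a
    return best


def recipients_for(
    alert: Alert,
    assignments: Mapping[str, list[ProviderAssignment]],
    shifts: Optional[list[Shift]] = None,
) -> list[tuple[str, str]]:
    """Recipient (provider_id, role) pairs for one alert.

    The responding clinician is resolved first so the pair order matches the
    care hierarchy the pages address: order-placer, then supervisor.  After a
    transfer the current assignment wins, so pages follow the patient.  When
    the encounter carries no attending assignment the attending is resolved
    from the shift roster active at fire time, if one was supplied.
    """
    here = assignments.get(alert.encounter_id, [])
    recipients: list[tuple[str, str]] = []
    responder = _active(here, alert.fire_time, RESPONDING_ROLES)
    if responder is not None:
        recipients.append((responder.provider_id, responder.role))
    attending = _active(here, alert.fire_time, {"attending"})
    if attending is not None:
        recipients.append((attending.provider_id, "attending"))
    elif shifts:
        on_duty = [
            s
            for s in shifts
            if s.role == "attending" and s.start <= alert.fire_time < s.end
        ]
        if on_duty:
            recipients.append((on_duty[-1].provider_id, "attending"))
    if not any(role == "attending" for _, role in recipients):
        raise RoutingError(
            f"no attending for {alert.encounter_id} at {format_time(alert.fire_time)}"
        )
    return recipients


def render_page(
    alert: Alert,
    encounter: Encounter,
    patient_name: str = "",
    mrn: str = "",
    pilot_format: bool = False,
) -> str:
    """Render the fixed-template pager text.

    One clause per deficient element, in the fixed care order; the rollout
    format shows patient name and MRN, the pilot format MRN only.  The text
    states the deficiency and deadline without prescribing an action.
    """
    elements = sorted(alert.deficient_elements, key=ELEMENT_ORDER.index)
    missing = ", ".join(e.label for e in elements)
    deadline = encounter.t0 + timedelta(minutes=alert.window_deadline_minutes)
    who = f"MRN {mrn}" if pilot_format else f"{patient_name} | MRN {mrn}"
    return f"SEPSIS ALERT | {who} | DUE {deadline.strftime('%H:%M')} | MISSING: {missing}"


def dispatch(
    alerts: Iterable[Alert],
    assignments: Mapping[str, list[ProviderAssignment]],
    shifts: Optional[list[Shift]],
    encounters: Mapping[str, Encounter],
    patient_display: Optional[Mapping[str, tuple[str, str]]] = None,
    pilot_format: bool = False,
) -> list[Page]:
    """Fan every alert out to its recipient set.

    ``patient_display`` maps encounter_id to (name, MRN) strings; absent
    entries fall back to the patient identifier.  Output order is stable:
    (send_time, encounter_id, responder before attending).
    """
    pages: list[Page] = []
    for alert in alerts:
        enc = encounters[alert.encounter_id]
        name, mrn = (patient_display or {}).get(
            alert.encounter_id,
            (enc.patient_id or enc.encounter_id, enc.patient_id or enc.encounter_id),
        )
        message = render_page(alert, enc, name, mrn, pilot_format=pilot_format)
        for provider_id, role in recipients_for(alert, assignments, shifts):
            pages.append(Page(alert, provider_id, role, alert.fire_time, message))
    pages.sort(
        key=lambda p: (
            p.send_time,
            p.alert.encounter_id,
            p.alert.alert_index,
            _ROLE_SORT[p.recipient_role],
        )
    )
    return pages


def write_pages_csv(pages: Iterable[Page], sink: IO[str]) -> None:
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(
        [
            "send_time",
            "encounter_id",
            "alert_index",
            "window",
            "elements",
            "provider_id",
            "role",
            "message",
        ]
    )
    for p in pages:
        writer.writerow(
            [
                format_time(p.send_time),
                p.alert.encounter_id,
                p.alert.alert_index,
                p.alert.window,
                ";".join(e.value for e in p.alert.deficient_elements),
                p.recipient_provider_id,
                p.recipient_role,
                p.message,
            ]
        )
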