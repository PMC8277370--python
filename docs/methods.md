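# Methods and design notes

## The monitoring procedure

An encounter enters active monitoring when a provider accepts the EHR's
sepsis best-practice alert (BPA); that acceptance time is the sepsis clock
zero `t0`. The engine does not implement the BPA itself (Sepsis-3/SOFA
screening) — BPA acceptance is consumed as an input event, so the cohort
definition lives upstream of this package.

Four SEP-1 elements are tracked: blood cultures, initial lactate and
antibiotics against a 3-hour deadline, and a repeat lactate against a 6-hour
deadline that becomes binding only once an initial lactate has resulted
above the elevation threshold (default 2.0 mmol/L, the usual SEP-1
convention; configurable). "Completion" of blood cultures means the order
event — whether the log's producer stamps order placement or specimen
collection is deliberately left to the producer.

Polling is per-encounter, every 15 minutes on a grid anchored at `t0`
(`t0, t0+15, …`). Anchoring at `t0` rather than a global wall-clock grid is
a deliberate choice: it makes the first W3 check land exactly at
`t0 + 120 min` for every encounter and makes replays deterministic; a
hospital-side implementation with a shared poller would differ from this one
by at most one poll interval per alert, which is exactly the slack the
oracle-equivalence test allows.

Alert rules, in the order they are evaluated at a tick:

* **W6** (first tick in `[t0+300, t0+360)`, at most once): fires if any
  required element is pending — the due repeat lactate and/or still-missing
  3-hour elements — and lists all of them.
* **W3** (first tick in `[t0+120, t0+180)`, at most once): fires if any
  3-hour element is pending and lists the pending 3-hour elements.
* A hard cap of two alerts per encounter (the alarm-fatigue bound); since
  each window fires at most once the cap binds only in degenerate
  configurations.

An alert lists a pending element only once that element's own lead window
has opened (`deadline − 60 min ≤ now`). Consequences worth stating
explicitly:

* An element completed at least a full lead hour before its deadline is
  never mentioned on any page ("completion silence").
* A repeat lactate that is already known to be required at the W3 check is
  *not* listed there — it is not yet deficient; it gets its own W6 page if
  still outstanding.
* If the initial lactate has not resulted by the W6 check, the repeat is
  treated as not-yet-required and not alerted (the initial lactate itself,
  being a pending 3-hour element, is). This is the conservative reading of a
  conditional requirement whose condition is still unknown.
* Events time-stamped exactly at a tick are applied before the tick is
  evaluated, and an element completed exactly at its deadline counts as on
  time (half-open intervals `[start, end)`, inclusive deadlines).

Monitoring stops at `t0 + 360 min` regardless of ED disposition; transfers
and admissions inside the window do not stop it (pages follow the patient
via the current provider assignment). Timestamps are UTC at minute
resolution and all window arithmetic is integer minutes — the windows (180,
360, 60, 15) are all whole minutes, so no float time ever appears.

## Routing and page content

Each alert pages the encounter's active responding clinician (resident, NP
or PA — the order-placer) and the supervising attending; nurses carry no
pagers and are never recipients. Resolution is assignment-based: the most
recently started assignment covering the fire time wins, so a handoff one
minute before the page routes to the successor. If no responding clinician
is assigned the attending is paged alone; if the encounter has no attending
assignment the attending on the shift roster at fire time is used, and if
none exists the router raises a named error rather than dropping the page
silently. Send time equals fire time — no queuing model.

Page text is a fixed ASCII template
(`SEPSIS ALERT | <name> | MRN <mrn> | DUE <HH:MM> | MISSING: <elements>`,
elements in care order), versioned config rather than a correctness surface.
A pilot-format flag renders the MRN without the patient name. The text
names the deficiency and its deadline and deliberately contains no
prescriptive directive, since withholding bundle care can be clinically
appropriate as the diagnostic picture evolves.

## Metrics definitions

* **Alert** — one deficiency detection at a poll tick. **Page** — delivery
  of one alert to one recipient; one alert usually fans out to two pages.
* **Etiology / deficiency records** — each (encounter, element) deficiency
  is attributed once, to the *first* alert that listed it. Without this
  rule an element pending at both pages would be double-counted and the
  per-element adherence denominators would not tile the total.
* **Post-alert successful adherence** — completion of a paged element within
  60 minutes of the first page listing it. The 60-minute window is kept
  even when tick quantisation fires the page later than `deadline − lead`;
  the operational definition takes precedence over the SEP-1 deadline.
* **Pages per attending shift** — total pages divided by the count of
  attending shift records overlapping the period; shifts are first-class
  inputs because no shift census can be derived from the event log itself.
* Percentages are rounded half-up to one decimal on the 0–100 scale, ratios
  to two decimals, matching how such programme reports are printed; zero
  denominators surface as absent values, never as zeros.
* Demographics are computed per unique patient (an encounter list may repeat
  patients), with an explicit "unknown" ED length-of-stay bin rather than a
  forced sum.

## Synthetic cohorts

`GeneratorParams` defaults describe the monitored-period conditions the
engine was built around: 711 encounters over a 48-day window, ~58% of
patients over 65, ~55% male, ~28% ICU admission, and a 30% elevated initial
lactate share (the published period constrains this only loosely — at least
~15% via the repeat-lactate deficiency count — so 30%, a typical elevated
share among BPA-confirmed sepsis suspects, is the documented default).
Completion delays are log-normal per element (non-negative, right-skewed,
the usual shape of task-completion times; medians 45/50/100/270 minutes for
cultures / initial lactate / antibiotics / repeat lactate), each with an
independent never-completed probability. Arrivals are uniform over the
window; every encounter gets an attending assignment and (by default) a
responding clinician at `t0`; an 8-hour attending shift roster tiles the
window. Identical parameters and seed reproduce the log byte for byte.

When `on_time_prob` is set for an element the log-normal is bypassed: the
element completes comfortably before its lead window opens with probability
`p`, otherwise late or never. This makes the per-element alerting
probability exactly `1 − p` and is what the parameter-recovery test
exercises (observed unalerted fraction within three binomial standard
errors of `p` at n = 1000 for `p ∈ {0.5, 0.8, 0.95}`).

What the generator does **not** emulate: BPA false-positive/negative
behaviour, provider behaviour change in response to pages (completion times
are drawn independently of alerting), intra-encounter team handoffs, care
pathways after the 6-hour window, and any outcome (mortality, LOS) model.
Green tests therefore certify the engine's rule arithmetic and metric
definitions, not clinical effectiveness.

## The deterministic rollout fixture

`table2_fixture()` constructs, with no randomness, a 711-encounter cohort
whose engine → routing → metrics replay yields the published
monitoring-period table: 272 paged / 439 unpaged encounters, 317 alerts ×
2 recipients = 634 pages, 327 element-deficiency instances split
68/17/136/106 (cultures / initial lactate / antibiotics / repeat lactate)
with 18/4/17/86 resolved in the post-page hour, 647 attending shifts
(the smallest roster count for which 634 pages round to 0.98 per shift),
and Table-1-shaped demographics over 648 unique patients.

The timelines are the simplest ones consistent with those counts: an
element that resolves adherently completes 30 minutes after its page
(`t0+150` for W3 elements, `t0+330` for the repeat lactate); a non-adherent
3-hour element completes at `t0+200` (late but inside the window, so the
second page never re-lists it); a non-adherent repeat lactate never
results. Six timeline classes cover the cohort (all-on-time; one late
3-hour element; a cultures+antibiotics pair, giving the ten two-element
pages that reconcile 317 alerts with 327 deficiencies; repeat-lactate-only;
and late-antibiotics-plus-repeat, the 45 encounters carrying both a W3 and
a W6 page). The alert split across classes (166/10/61/45) is one of several
integer solutions consistent with the published margins; the counts
themselves are all produced by actually replaying the fixture, never
hard-coded in any report.

Because the fixture log is ~5,800 events it is generated in code on demand
(by the `--fixture` flag, the tests and the acceptance script) rather than
shipped as a data file.

## Numerical and degenerate-input choices

* Stable sort by time with input order as tie-break makes replays
  deterministic; two runs over the same log are byte-identical.
* `poll()` rejects off-grid times; `run_engine` only generates on-grid
  ticks, and events after the monitoring horizon are still folded into the
  final state so late completions are visible to the adherence metric.
* Validation returns the full violation list as data (non-monotone times,
  non-positive lactate, draw-index gaps, unknown roles, duplicate BPA);
  only a monitored encounter with no BPA event at all is a hard error,
  since no bundle clock can be constructed for it.
* Problem sizes in the test suite (1,000-encounter invariant cohorts,
  50-encounter × 20-seed oracle sweeps) are chosen so the whole suite runs
  in seconds while keeping three-standard-error bounds meaningful.

## Known limitations

* Attending resolution is assignment/roster-based; a zone-based routing
  scheme (which deployed systems sometimes use) is not modelled.
* Deficiency state is evaluated at the poll tick; an element completed
  between alert generation and page transmission is not re-checked at send
  time.
* Septic-shock bundle elements (fluid volume, volume reassessment,
  vasopressors) are out of scope by design, as is any statistical inference
  (confidence intervals, hypothesis tests) on the reported rates.
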