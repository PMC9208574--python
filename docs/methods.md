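# Methods

This note documents the statistical model behind `wardflow`, the defaults
and why they were chosen, what the synthetic ward does and does not
emulate, and the numerical conventions that matter when comparing output
against published tables.

## Sessionization model

An RTLS event is an interval during which a badge was continuously in line
of sight of one room sensor. Two rules turn events into direct
nurse-patient encounters:

* **Floor** (`min_event_s`, default 5 s, strict): events of 5 s or less are
  noise — a nurse walking past a doorway. "Longer than 5 seconds" is read
  as a strict inequality.
* **Collapse** (`merge_gap_s`, default 30 s, strict): within one
  (nurse, room) stream sorted by start time, an event merges into the
  running encounter iff `next.t_start − (latest t_end seen so far)` is
  strictly below the gap. The gap is measured end-to-start because that is
  what a line-of-sight interruption produces; a tie at exactly 30.000 s
  does **not** merge. Measuring against the running maximum end rather than
  the immediately preceding event's end makes merging robust to nested or
  overlapping fragments; once a break of ≥ 30 s occurs, the next event
  necessarily starts after every earlier end, so the two conventions agree
  on every stream that can actually break. The tests verify the rule
  against an oracle that enumerates all contiguous partitions of the
  stream.

Encounter duration is last `t_end` minus first `t_start`, *including*
intra-encounter gaps: the interruption is part of the bedside visit.
Events are never split at shift or day boundaries; an encounter belongs
wholly to the shift containing its start. A badge sighted in two rooms at
once is an RTLS artifact: both streams keep the event and a warning is
logged rather than silently resolving it.

## Shifts and the governing census

AM covers 07:00:00–18:59:59 of its date; PM covers 19:00:00–06:59:59 of
the next morning. The AM shift of date D is governed by the midnight
census entering D; the PM shift starting on D is governed by the midnight
*inside* it (D+1), the snapshot contemporaneous with most of the shift.
The alternative (`pm_census="same"`) is supported because either reading
is defensible. Encounters in unoccupied rooms, or with no census record,
are flagged and excluded from per-patient denominators — never dropped, so
row counts are conserved and the exclusions are auditable. Mid-day
occupancy changes are invisible to a midnight census; the pipeline mirrors
that limitation rather than interpolating.

## Outcomes

Per unit-day-shift cell, with the occupied-bed count `n` from the
governing census:

1. encounters per patient = (unflagged encounters) / n;
2. median encounter duration (minutes) over the cell's encounters;
3. median over occupied rooms of total encounter minutes in that room
   (rooms without encounters contribute 0 — denominators follow the
   census, duration medians follow encounters).

Cells with n = 0 have all per-patient values undefined (NaN). Stage
summaries are means (SD) of the daily values — for outcomes 2–3 a mean of
daily medians — and the comparison arm pools its units' unit-day records
rather than averaging unit means. Encounter counts are reported per
patient (not per unit), which fixes the denominator used when converting
DiD estimates into the resource model's per-patient deltas.

## Difference-in-differences

For each outcome o, stage s and shift h, the estimand is

    DiD = (mean_covid,s − mean_covid,pre) − (mean_comp,s − mean_comp,pre)

computed on daily unit values. Significance comes from OLS (a Gaussian
GLM with identity link) on `value ~ arm + period + arm×period`; on this
saturated 2×2 design the interaction coefficient equals the four-cell-mean
DiD exactly, balanced or not, so the estimate and the table arithmetic can
never disagree (asserted at 1e-9 in the tests). The observational unit is
the unit-day; the comparison arm contributes one value per unit per day
and no clustering or autocorrelation correction is applied — a deliberate
simplification, so p-values should be read as approximate in the presence
of strong day-to-day correlation. Cells with fewer than 2 days are flagged
undefined rather than fitted.

The family for multiplicity adjustment is all stage × shift comparisons
within one outcome (one published-style table per outcome); pooling across
outcomes is available via `fdr_family="pooled"`.

### Adaptive two-stage FDR

The two-stage linear step-up procedure at level q: run the BH step-up at
q′ = q/(1+q); let r₁ be the rejection count and m̂₀ = m − r₁ the estimated
number of true nulls. If r₁ = 0, reject nothing; if m̂₀ = 0, reject
everything; otherwise rerun the step-up at q′·m/m̂₀. Decisions come from
this explicit rule; the reported adjusted values are BH q-values scaled by
m̂₀/m and are informative rather than decision-making (thresholding them
at q does not reproduce the rule's edge cases). For m ≤ 1 + 1/q the
stage-2 level is ≥ q whenever r₁ ≥ 1, so the procedure then rejects a
superset of plain BH at q; the implementation is cross-checked against an
independent two-stage implementation and a textbook step-up written from
the definition.

## Resource model

With per-patient per-shift avoided-encounter deltas Δ_AM, Δ_PM (the
day-count-weighted mean of −DiD across pandemic stages), a fully occupied
unit of `beds` beds over `days` days, PPE worn for `ppe_fraction` of
avoided encounters, and `don_min` + `doff_min` minutes of PPE handling per
entry:

    PPE saved   = beds × (Δ_AM + Δ_PM) × days × ppe_fraction
    min / shift = Δ_shift × (don_min + doff_min)

Defaults: 22 beds, 7 days, 0.25, 4 min, 3 min. All results are returned at
full precision; rounding is half-away-from-zero and happens only at the
rendering layer (62.91 → 64-style discrepancies in published prose are a
presentation-layer issue, which is why the model never rounds internally).

## Synthetic ward

The generator's defaults describe four identical 22-bed single-room units
(one COVID arm, three comparison), nurse-to-patient ratios of 1:4
(baseline) tightening to 1:3, badge pings every 1–3 s, and a six-stage
2020 calendar (prepandemic through a second surge). Per occupied bed and
shift, true visit counts are negative binomial — observed daily SDs are
too large for Poisson — with arm × stage × shift means set to the
magnitudes of published stage tables (e.g. 22.4 visits/patient/AM-shift on
the COVID arm prepandemic); dispersions are chosen so that daily-mean
variation is of the observed order. Visit durations are lognormal
(positive, right-skewed) with arm × stage medians near the published
per-encounter means (≈ 2.2 min baseline, up to ≈ 7.5 min in surges).
Telehealth call durations are lognormal with median 2.9 min and σ = 1.29,
reproducing the observed heavy right skew (mean ≈ 6.6 min, SD ≈ 13.6).

Design choices that keep ground truth recoverable:

* dropout fragments a visit into two events with a gap uniform on
  [3 s, 25 s] — strictly under the 30 s collapse rule — and every fragment
  is kept longer than the 5 s floor;
* distinct true visits to one room are spaced ≥ 120 s apart and one
  nurse's visits are serialized across her rooms (a badge is in one place
  at a time), so no two *different* visits can merge;
* spurious noise events are drawn uniformly from 1–5 s, entirely below the
  floor.

Under these defaults the sessionizer recovers the generator's visit ledger
*exactly* (event-count conservation is asserted in the tests), and the
full pipeline recovers configured encounter rates within Monte-Carlo error
over 100 simulated days. A separate fixture uses gaps > 30 s to exercise
genuine fragmentation.

What the simulator does **not** emulate, and hence what passing tests do
not show about real extracts: badge non-compliance, sensor sensitivity
drift, hallway/station events (inputs are pre-restricted to patient
rooms), day-to-day occupancy persistence (each midnight is drawn
independently), intra-day transfers, physicians and other roles, seasonal
or weekday structure, and any correlation between telehealth use and
visit behavior — the generator injects workflow change only through the
configured stage rates. Inter-visit timing within a shift is uniform by
default (`visit_timing="clustered"` is available) because the real
within-shift structure is unknown.

## Numerical conventions and degenerate inputs

* Timestamps are timezone-naive local time at seconds precision; the
  simulated calendar contains no DST transitions.
* Medians over zero encounters, rates over zero patients and rates over
  zero patient-days are NaN and flagged, never zero-filled.
* Stage windows must be non-overlapping, uniquely named, with
  "prepandemic" present and earliest; a stage covering zero data days is
  an error naming the stage.
* CSV readers validate schemas; `strict` mode aborts naming offending
  rows, `skip` mode drops them with a log line. Write-then-read is an
  identity on every format.
* Determinism: one `numpy` Generator seeded from the config drives the
  simulator; identical config + seed give byte-identical outputs, and the
  pipeline manifest records a config hash plus row counts.

## Known limitations

Unit-day inference ignores within-day correlation between the two shifts
and serial correlation across days; the DiD design identifies association,
not causation (no parallel-trends diagnostics are provided); the PPE model
is linear and assumes full occupancy; simulated problem sizes in the test
suite (2–4 units, 14–100 days per stage) were chosen as the smallest wards
at which the Monte-Carlo checks are informative.
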