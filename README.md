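# wardflow

Analytics for nursing workflow measured with a real-time locating system
(RTLS), built around the question of how inpatient telehealth deployment on
a COVID-19 unit changed direct nurse-patient care at the bedside.

Hospitals with badge-and-sensor RTLS infrastructure record an event every
time a nurse's badge is in line of sight of a room sensor. Because a brief
interruption (turning away from the sensor) splits one bedside visit into
several short events, raw RTLS extracts must be *sessionized* before they
measure anything. `wardflow` implements the full chain from raw badge
events to inference, for analysts studying workflow change on inpatient
units:

1. **Sessionization** — events longer than 5 s from roles "nurse" / "float
   nurse" are kept; successive events of one nurse in one room separated by
   a gap < 30 s are collapsed into a single *direct nurse-patient
   encounter* whose duration runs from its first to its last timestamp.
2. **Census linkage** — each encounter is assigned to a 12-hour shift (AM
   07:00–18:59, PM 19:00–06:59 spanning midnight) by its start time, and to
   the occupancy / COVID-19 status of its room's governing midnight census.
3. **Workflow outcomes** per unit-day-shift: encounters per patient, median
   encounter duration (min), and median total time per patient (min).
4. **Difference-in-differences (DiD) inference** — for each outcome, stage
   of the pandemic and shift, with COVID arm *c* and comparison arm *k*:

   `DiD = (x̄_c,stage − x̄_c,pre) − (x̄_k,stage − x̄_k,pre)`

   tested as the interaction term of a Gaussian GLM
   `y ~ arm + period + arm×period` on daily unit values, with p-values
   adjusted by the adaptive two-stage linear step-up FDR procedure
   (stage 1: step-up at q′ = q/(1+q); m̂₀ = m − r₁; stage 2: step-up at
   q′·m/m̂₀).
5. **Telehealth metrics** — call logs filtered to 30 s–2 h durations with
   ≥ 2 participants, summarized as calls per patient-day at unit level.
6. **Resource model** — avoided encounters translated into PPE sets and
   donning/doffing minutes saved:
   `PPE = beds × (Δ_AM + Δ_PM) × days × ppe_fraction`,
   `minutes/shift = Δ_shift × (don + doff)`.

A synthetic ward simulator (`wardflow.simulate`) generates raw RTLS events
(negative-binomial visit counts, lognormal durations, line-of-sight
dropouts, sub-floor noise), midnight census and telehealth logs with a
ground-truth visit ledger, so every stage of the pipeline is testable
without access to hospital data.

The core steps are scikit-learn-style estimators (`EncounterSessionizer`,
`CensusLinker`, `ShiftOutcomeAggregator`, `DifferenceInDifferences`,
`TelehealthCallFilter`, `ResourceModel`) with thin functional wrappers, and
a `wardflow` CLI (`simulate | sessionize | link | outcomes | did |
telehealth | resources | run`) over comma-delimited text formats.

## Worked example

Simulate a two-unit ward (one COVID arm, one comparison arm) over a
two-week prepandemic baseline and a two-week surge, then run the full
pipeline:

```python
import datetime as dt
import wardflow as wf
from wardflow.io import RunConfig
from wardflow.pipeline import run_pipeline

stages = (
    wf.StageWindow("prepandemic", dt.date(2020, 1, 1), dt.date(2020, 1, 14)),
    wf.StageWindow("surge1", dt.date(2020, 1, 15), dt.date(2020, 1, 28)),
)
cfg = wf.default_config(stages=stages, seed=7,
                        units={"U1": "covid", "U2": "comparison"})
sim = wf.simulate_ward(cfg)
report = run_pipeline(RunConfig(stages=stages, arm_of=dict(cfg.units)),
                      sim.events, sim.census, sim.calls)
print(report.did.round(3).to_string(index=False))
```

```
                     outcome  stage shift  covid_change  comparison_change     did  p_raw  p_fdr  significant
      encounters_per_patient surge1    AM       -16.520             -1.372 -15.148  0.000  0.000         True
      encounters_per_patient surge1    PM       -13.793             -1.961 -11.832  0.000  0.000         True
        median_encounter_min surge1    AM         5.291             -0.036   5.327  0.000  0.000         True
        median_encounter_min surge1    PM         5.527             -0.017   5.543  0.000  0.000         True
median_total_min_per_patient surge1    AM       -10.089             -4.346  -5.743  0.054  0.107        False
median_total_min_per_patient surge1    PM        -8.087             -5.520  -2.567  0.259  0.259        False
```

49,483 raw events collapse into 36,386 encounters (exactly the simulator's
visit ledger). The table shows the surge signature this kind of analysis is
meant to detect: on the COVID arm, encounters per patient drop sharply
(DiD ≈ −15 and −12 per shift) while each encounter lengthens (≈ +5 min),
so the change in *total* bedside time per patient is not significant after
FDR adjustment — fewer, longer visits ("batched" care) rather than less
care. The resource model then converts the per-shift encounter decreases
into supply terms, e.g. `report.resources["ppe_saved"]` → `1039` PPE sets
per week for this simulated ward.

With the published weighted decreases of 11.25 (AM) and 9.13 (PM)
encounters per patient per shift on a fully occupied 22-bed unit:

```python
>>> wf.ppe_saved(wf.EncounterDelta(11.25, 9.13))
785
>>> wf.nurse_time_saved(9.13)
63.91
```

i.e. ≈ 785 PPE units saved per week and ≈ 64 minutes of donning/doffing
saved per night shift.

## Layout

- `src/wardflow/sessionize.py` — event floor, role filter, 30 s collapse
- `src/wardflow/census.py` — shift assignment, governing midnight, linkage
- `src/wardflow/outcomes.py` — the three outcomes, stage means (SD)
- `src/wardflow/inference.py` — DiD, GLM interaction test, two-stage FDR
- `src/wardflow/telehealth.py` — call filtering and utilization summaries
- `src/wardflow/resources.py` — PPE / nurse-time savings model
- `src/wardflow/simulate.py` — synthetic ward generator and fixtures
- `src/wardflow/io.py`, `pipeline.py`, `cli.py` — formats, composition, CLI
- `docs/methods.md` — model assumptions, defaults, numerical conventions
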