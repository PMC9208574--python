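"""The three per-shift workflow outcomes and their stage aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import wardflow as wf
from wardflow.outcomes import OUTCOMES


def _linked(rows, flag=""):
    """rows: (room, start, duration_min) in unit U1, all linked/occupied."""
    return pd.DataFrame(
        {
            "nurse_id": ["N1"] * len(rows),
            "unit_id": ["U1"] * len(rows),
            "room_id": [r[0] for r in rows],
            "t_start": pd.to_datetime([r[1] for r in rows]),
            "t_end": pd.to_datetime([r[1] for r in rows])
            + pd.to_timedelta([r[2] for r in rows], unit="m"),
            "duration_s": [r[2] * 60.0 for r in rows],
            "n_fragments": [1] * len(rows),
            "shift_date": [pd.Timestamp(r[1]).date() for r in rows],
            "shift": ["AM"] * len(rows),
            "occupied": [True] * len(rows),
            "covid_status": ["negative"] * len(rows),
            "flag": [flag] * len(rows),
        }
    )


def _census(rooms, dates, occupied=True):
    return pd.DataFrame(
        [
            {
                "unit_id": "U1",
                "room_id": r,
                "census_date": d,
                "occupied": occupied,
                "covid_status": "negative" if occupied else "unknown",
            }
            for r in rooms
            for d in dates
        ]
    )


ARM = {"U1": "covid"}


class TestDailyOutcomes:
    def test_hand_arithmetic_single_patient(self):
        # encounters of 2, 3, 10 min with one patient
        linked = _linked(
            [
                ("R1", "2020-01-02 08:00:00", 2),
                ("R1", "2020-01-02 10:00:00", 3),
                ("R1", "2020-01-02 12:00:00", 10),
            ]
        )
        census = _census(["R1"], [dt.date(2020, 1, 2), dt.date(2020, 1, 3)])
        daily = wf.daily_outcomes(linked, census, ARM)
        row = daily[(daily["shift"] == "AM") & (daily["shift_date"] == dt.date(2020, 1, 2))].iloc[0]
        assert row["n_patients"] == 1
        assert row["encounters_per_patient"] == 3.0
        assert row["median_encounter_min"] == 3.0
        assert row["median_total_min_per_patient"] == 15.0

    def test_zero_occupied_beds_undefined(self):
        linked = _linked([], flag="")
        census = _census(["R1"], [dt.date(2020, 1, 2)], occupied=False)
        daily = wf.daily_outcomes(linked, census, ARM)
        assert (daily["n_patients"] == 0).all()
        assert daily[list(OUTCOMES)].isna().all().all()

    def test_zero_encounter_patient_contributes_zero_to_total_median(self):
        # R1 gets 10 min, R2 nothing: total-time median over patients is 5
        linked = _linked([("R1", "2020-01-02 08:00:00", 10)])
        census = _census(["R1", "R2"], [dt.date(2020, 1, 2)])
        daily = wf.daily_outcomes(linked, census, ARM)
        row = daily[daily["shift"] == "AM"].iloc[0]
        assert row["encounters_per_patient"] == 0.5
        assert row["median_total_min_per_patient"] == 5.0
        assert row["median_encounter_min"] == 10.0  # duration median over encounters only

    def test_flagged_encounters_excluded(self):
        linked = pd.concat(
            [
                _linked([("R1", "2020-01-02 08:00:00", 4)]),
                _linked([("R2", "2020-01-02 09:00:00", 60)], flag="unoccupied"),
            ],
            ignore_index=True,
        )
        census = _census(["R1"], [dt.date(2020, 1, 2)])
        census = pd.concat(
            [census, _census(["R2"], [dt.date(2020, 1, 2)], occupied=False)],
            ignore_index=True,
        )
        daily = wf.daily_outcomes(linked, census, ARM)
        row = daily[daily["shift"] == "AM"].iloc[0]
        assert row["n_encounters"] == 1
        assert row["median_encounter_min"] == 4.0

    def test_decomposition_total_time_equals_sum_of_durations(self, two_stage_sim):
        cfg, sim = two_stage_sim
        enc = wf.EncounterSessionizer().fit_transform(sim.events)
        linked = wf.CensusLinker().fit(sim.census).transform(enc)
        kept = linked[linked["flag"] == ""]
        # per cell: sum over patients of total time == sum over encounters
        per_room = kept.groupby(["unit_id", "shift_date", "shift", "room_id"])["duration_s"].sum()
        per_cell = kept.groupby(["unit_id", "shift_date", "shift"])["duration_s"].sum()
        assert np.allclose(
            per_room.groupby(["unit_id", "shift_date", "shift"]).sum().sort_index(),
            per_cell.sort_index(),
        )

    def test_scale_equivariance_of_duration_outcomes(self):
        linked = _linked(
            [("R1", "2020-01-02 08:00:00", 2), ("R1", "2020-01-02 10:00:00", 8)]
        )
        census = _census(["R1"], [dt.date(2020, 1, 2)])
        base = wf.daily_outcomes(linked, census, ARM)
        scaled_linked = linked.assign(duration_s=linked["duration_s"] * 3)
        scaled = wf.daily_outcomes(scaled_linked, census, ARM)
        b = base[base["shift"] == "AM"].iloc[0]
        s = scaled[scaled["shift"] == "AM"].iloc[0]
        assert s["encounters_per_patient"] == b["encounters_per_patient"]
        assert s["median_encounter_min"] == 3 * b["median_encounter_min"]
        assert s["median_total_min_per_patient"] == 3 * b["median_total_min_per_patient"]


class TestStageSummary:
    STAGES = (
        wf.StageWindow("prepandemic", dt.date(2020, 1, 1), dt.date(2020, 1, 2)),
    )

    def test_constant_value_zero_sd(self):
        linked = _linked(
            [("R1", "2020-01-01 08:00:00", 5), ("R1", "2020-01-02 08:00:00", 5)]
        )
        census = _census(["R1"], [dt.date(2020, 1, 1), dt.date(2020, 1, 2), dt.date(2020, 1, 3)])
        daily = wf.daily_outcomes(linked, census, ARM)
        summ = wf.stage_summary(daily, self.STAGES)
        row = summ[(summ["outcome"] == "median_encounter_min") & (summ["shift"] == "AM")].iloc[0]
        assert row["mean"] == 5.0 and row["sd"] == 0.0 and row["n_days"] == 2

    def test_two_day_mean_and_sd_closed_form(self):
        linked = _linked(
            [("R1", "2020-01-01 08:00:00", 10), ("R1", "2020-01-02 08:00:00", 20)]
        )
        census = _census(["R1"], [dt.date(2020, 1, 1), dt.date(2020, 1, 2), dt.date(2020, 1, 3)])
        daily = wf.daily_outcomes(linked, census, ARM)
        summ = wf.stage_summary(daily, self.STAGES)
        row = summ[(summ["outcome"] == "median_encounter_min") & (summ["shift"] == "AM")].iloc[0]
        assert row["mean"] == 15.0
        assert row["sd"] == pytest.approx(np.sqrt(50.0))

    def test_stage_with_no_days_errors(self):
        linked = _linked([("R1", "2020-01-01 08:00:00", 5)])
        census = _census(["R1"], [dt.date(2020, 1, 1)])
        daily = wf.daily_outcomes(linked, census, ARM)
        stages = self.STAGES + (
            wf.StageWindow("surge1", dt.date(2021, 6, 1), dt.date(2021, 6, 30)),
        )
        with pytest.raises(wf.SchemaError, match="surge1"):
            wf.stage_summary(daily, stages)

    def test_comparison_arm_pools_unit_days(self, two_stage_sim):
        cfg, sim = two_stage_sim
        enc = wf.EncounterSessionizer().fit_transform(sim.events)
        linked = wf.CensusLinker().fit(sim.census).transform(enc)
        daily = wf.daily_outcomes(linked, sim.census, dict(cfg.units))
        summ = wf.stage_summary(daily, cfg.stages)
        staged = wf.daily_with_stage(daily, cfg.stages)
        comp = staged[
            (staged["arm"] == "comparison")
            & (staged["stage"] == "prepandemic")
            & (staged["shift"] == "AM")
        ]["encounters_per_patient"].dropna()
        row = summ[
            (summ["outcome"] == "encounters_per_patient")
            & (summ["arm"] == "comparison")
            & (summ["stage"] == "prepandemic")
            & (summ["shift"] == "AM")
        ].iloc[0]
        # pooled over unit-days, not a mean of unit means
        assert row["mean"] == pytest.approx(comp.mean())
        assert row["n_days"] == len(comp)

    def test_fixture_two_arm_effect_daily_counts(self):
        events, census, _, manifest = wf.make_fixture("two_arm_effect")
        enc = wf.EncounterSessionizer().fit_transform(events)
        linked = wf.CensusLinker().fit(census).transform(enc)
        daily = wf.daily_outcomes(linked, census, manifest["arm_of"])
        am = daily[daily["shift"] == "AM"]
        for unit, by_date in manifest["daily_am_counts"].items():
            for date_iso, n in by_date.items():
                row = am[
                    (am["unit_id"] == unit)
                    & (am["shift_date"] == dt.date.fromisoformat(date_iso))
                ].iloc[0]
                assert row["n_encounters"] == n
                assert row["encounters_per_patient"] == n  # one patient per unit
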