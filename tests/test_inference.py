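"""Difference-in-differences estimation and FDR adjustment."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from _oracles import bh_step_up
import wardflow as wf
from wardflow.inference import DifferenceInDifferences, did, round_half_away


class TestChangeArithmetic:
    def test_change_from_baseline(self):
        assert wf.change_from_baseline(10.5, 22.4) == pytest.approx(-11.9)
        assert wf.change_from_baseline(5.0, 5.0) == 0.0
        assert wf.change_from_baseline(6.8, 2.0) == pytest.approx(4.8)

    def test_did_cells(self):
        assert did(-11.9, 0.0) == pytest.approx(-11.9)
        assert did(-13.1, -1.1) == pytest.approx(-12.0)
        assert did(3.3, 3.3) == 0.0

    def test_round_half_away(self):
        assert round_half_away(784.6) == 785.0
        assert round_half_away(-0.25, 1) == -0.3
        assert round_half_away(0.25, 1) == 0.3


def _daily(values):
    """values: dict (arm, stage, shift) -> list of daily values."""
    rows = []
    for (arm, stage, shift), vals in values.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "unit_id": f"{arm}-u",
                    "arm": arm,
                    "shift_date": dt.date(2020, 1, 1) + dt.timedelta(days=i),
                    "shift": shift,
                    "stage": stage,
                    "encounters_per_patient": v,
                    "median_encounter_min": np.nan,
                    "median_total_min_per_patient": np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestDidTest:
    def test_interaction_equals_cell_mean_did(self):
        daily = _daily(
            {
                ("covid", "prepandemic", "AM"): [5, 7, 6],
                ("covid", "surge1", "AM"): [2, 2],
                ("comparison", "prepandemic", "AM"): [4, 4, 5, 3],
                ("comparison", "surge1", "AM"): [3, 5],
            }
        )
        res = wf.did_test(daily, "encounters_per_patient", "surge1", "AM")
        cell = lambda a, s: daily[(daily.arm == a) & (daily.stage == s)][
            "encounters_per_patient"
        ].mean()
        expected = (cell("covid", "surge1") - cell("covid", "prepandemic")) - (
            cell("comparison", "surge1") - cell("comparison", "prepandemic")
        )
        assert res.estimate == pytest.approx(expected, abs=1e-9)

    def test_fixture_manifest_oracle(self):
        events, census, _, manifest = wf.make_fixture("two_arm_effect")
        enc = wf.EncounterSessionizer().fit_transform(events)
        linked = wf.CensusLinker().fit(census).transform(enc)
        daily = wf.daily_outcomes(linked, census, manifest["arm_of"])
        stages = [
            wf.StageWindow(s["name"], s["start_date"], s["end_date"])
            for s in manifest["stages"]
        ]
        staged = wf.daily_with_stage(daily, stages)
        m = manifest["did"]
        res = wf.did_test(staged, m["outcome"], m["stage"], m["shift"])
        assert res.estimate == pytest.approx(m["did"], abs=1e-9)
        assert res.p_value == pytest.approx(m["p_raw"], rel=1e-6)

    def test_identical_values_give_zero_interaction(self):
        daily = _daily(
            {
                ("covid", "prepandemic", "AM"): [3, 3],
                ("covid", "surge1", "AM"): [3, 3],
                ("comparison", "prepandemic", "AM"): [3, 3],
                ("comparison", "surge1", "AM"): [3, 3],
            }
        )
        res = wf.did_test(daily, "encounters_per_patient", "surge1", "AM")
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_sparse_cell_flagged(self):
        daily = _daily(
            {
                ("covid", "prepandemic", "AM"): [5],
                ("covid", "surge1", "AM"): [2, 2],
                ("comparison", "prepandemic", "AM"): [4, 4],
                ("comparison", "surge1", "AM"): [3, 5],
            }
        )
        res = wf.did_test(daily, "encounters_per_patient", "surge1", "AM")
        assert not res.ok and np.isnan(res.p_value)

    def test_power_increases_with_days(self):
        # a fixed DiD of 2 against noise sd 3: rejection rate grows with n
        rng = np.random.default_rng(11)
        rates = []
        for n_days in (10, 30, 100):
            hits = 0
            for _ in range(60):
                vals = {
                    ("covid", "prepandemic", "AM"): rng.normal(20, 3, n_days),
                    ("covid", "surge1", "AM"): rng.normal(22, 3, n_days),
                    ("comparison", "prepandemic", "AM"): rng.normal(25, 3, n_days),
                    ("comparison", "surge1", "AM"): rng.normal(25, 3, n_days),
                }
                res = wf.did_test(_daily(vals), "encounters_per_patient", "surge1", "AM")
                hits += res.p_value < 0.05
            rates.append(hits / 60)
        assert rates[0] < rates[1] < rates[2] or (rates[1] > 0.9 and rates[2] > 0.9)


class TestFdr:
    def test_two_stage_hand_example(self):
        reject, _ = wf.fdr_adjust([0.01, 0.04], q=0.05)
        assert reject.tolist() == [True, True]

    def test_all_ones_reject_nothing(self):
        reject, _ = wf.fdr_adjust([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_bh_matches_textbook_step_up(self):
        # the classic 15-p-value benchmark vector
        p = [0.0001, 0.0004, 0.0019, 0.0095, 0.0201, 0.0278, 0.0298, 0.0344,
             0.0459, 0.3240, 0.4262, 0.5719, 0.6528, 0.7590, 1.000]
        reject, _ = wf.fdr_adjust(p, q=0.05, method="bh")
        assert reject.tolist() == bh_step_up(p, 0.05)
        assert int(reject.sum()) == 4

    def test_matches_statsmodels_two_stage(self, rng):
        for _ in range(100):
            p = np.concatenate([rng.uniform(size=6), rng.beta(0.2, 5, size=6)])
            mine, _ = wf.fdr_adjust(p, q=0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert (mine == theirs).all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_dominates_bh_when_nulls_estimated_below_m(self, p):
        q = 0.05
        two_stage, _ = wf.fdr_adjust(p, q=q)
        bh, _ = wf.fdr_adjust(p, q=q, method="bh")
        q1 = q / (1 + q)
        r1 = int(multipletests(np.asarray(p), alpha=q1, method="fdr_bh")[0].sum())
        if r1 == 0:
            assert not two_stage.any()
        else:
            # step-up at a level >= q rejects a superset of BH at q
            assert (two_stage | ~bh).all()

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            wf.fdr_adjust([0.5, 1.5])


class TestEstimator:
    def test_results_table_shape_and_identity(self, two_stage_sim):
        cfg, sim = two_stage_sim
        enc = wf.EncounterSessionizer().fit_transform(sim.events)
        linked = wf.CensusLinker().fit(sim.census).transform(enc)
        daily = wf.daily_outcomes(linked, sim.census, dict(cfg.units))
        staged = wf.daily_with_stage(daily, cfg.stages)
        est = DifferenceInDifferences().fit(staged)
        res = est.results_
        assert set(res["outcome"]) == set(wf.OUTCOMES)
        assert set(res["stage"]) == {"surge1"}
        # did column is exactly covid_change - comparison_change, and equals
        # the OLS interaction estimate
        assert np.allclose(res["did"], res["covid_change"] - res["comparison_change"])
        for _, row in res.iterrows():
            t = wf.did_test(staged, row["outcome"], row["stage"], row["shift"])
            assert t.estimate == pytest.approx(row["did"], abs=1e-9)
        assert res["p_raw"].between(0, 1).all()

    def test_estimator_params_roundtrip(self):
        est = DifferenceInDifferences(q=0.1, fdr_method="bh")
        assert est.get_params()["q"] == 0.1
        est.set_params(fdr_family="pooled")
        assert est.fdr_family == "pooled"
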