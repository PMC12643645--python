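"""Eligibility filters, referent selection and stratum construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from heatpm.cohort import (EligibilityRules, build_strata, identify_qualifying,
                           make_referents, select_outcome)

ADRD = {"ADRD01", "ADRD02"}


def adm_row(eid, admit, discharge=None, dx="DX100", src="7", snf=False,
            zip_="Z0"):
    admit = pd.Timestamp(admit)
    discharge = pd.Timestamp(discharge) if discharge else admit + pd.Timedelta(days=3)
    return {"enrollee_id": eid, "admit_date": admit, "discharge_date": discharge,
            "dx_codes": dx, "source_code": src, "snf_flag": snf, "zip": zip_}


class TestIdentifyQualifying:
    def test_code_in_first_position_qualifies(self):
        adm = pd.DataFrame([adm_row("E1", "2010-02-01", dx="ADRD01;DX1")])
        out = identify_qualifying(adm, ADRD)
        assert len(out) == 1

    def test_code_at_position_eleven_does_not_qualify(self):
        dx = ";".join([f"DX{i}" for i in range(10)] + ["ADRD01"])
        adm = pd.DataFrame([adm_row("E1", "2010-02-01", dx=dx)])
        assert identify_qualifying(adm, ADRD).empty

    def test_code_at_position_ten_qualifies(self):
        dx = ";".join([f"DX{i}" for i in range(9)] + ["ADRD01"])
        adm = pd.DataFrame([adm_row("E1", "2010-02-01", dx=dx)])
        assert len(identify_qualifying(adm, ADRD)) == 1

    def test_earliest_qualifying_returned(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-06-01", dx="ADRD01"),
            adm_row("E1", "2010-02-01", dx="ADRD02"),
        ])
        out = identify_qualifying(adm, ADRD)
        assert out["admit_date"].iloc[0] == pd.Timestamp("2010-02-01")

    def test_malformed_codes_skipped_with_warning(self, caplog):
        adm = pd.DataFrame([adm_row("E1", "2010-02-01", dx="ADRD01")])
        adm.loc[0, "dx_codes"] = 123  # not a string
        with caplog.at_level("WARNING"):
            out = identify_qualifying(adm, ADRD)
        assert out.empty
        assert "malformed" in caplog.text


class TestSelectOutcome:
    def test_washout_skips_early_admission(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-03-20"),          # day 19: inside washout
            adm_row("E1", "2010-06-15"),
        ])
        out = select_outcome(adm, "2010-03-01")
        assert out["case_date"] == pd.Timestamp("2010-06-15")

    def test_exactly_thirty_days_qualifies(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-05-01", dx="ADRD01"),
            adm_row("E1", "2010-05-31"),
        ])
        out = select_outcome(adm, "2010-05-01")
        assert out["case_date"] == pd.Timestamp("2010-05-31")

    def test_off_season_only_returns_none(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-12-10"),
        ])
        assert select_outcome(adm, "2010-03-01") is None

    def test_readmission_within_gap_rejects_candidate_and_continues(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-06-25", discharge="2010-07-01"),
            adm_row("E1", "2010-07-20"),  # within 30 d of 07-01 discharge
        ])
        out = select_outcome(adm, "2010-03-01")
        # first candidate rejected; 07-20 itself qualifies (nothing follows)
        assert out["case_date"] == pd.Timestamp("2010-07-20")

    def test_snf_origin_excluded(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-06-15", snf=True),
        ])
        assert select_outcome(adm, "2010-03-01") is None

    def test_disallowed_source_excluded(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-06-15", src="4"),
        ])
        assert select_outcome(adm, "2010-03-01") is None

    def test_filters_commute(self):
        # SNF and source exclusions are independent: a record failing both is
        # excluded whichever rule is nominally applied first
        adm = pd.DataFrame([
            adm_row("E1", "2010-03-01", dx="ADRD01"),
            adm_row("E1", "2010-06-15", src="4", snf=True),
            adm_row("E1", "2010-08-15"),
        ])
        out = select_outcome(adm, "2010-03-01")
        assert out["case_date"] == pd.Timestamp("2010-08-15")

    def test_discharge_anchor_configurable(self):
        adm = pd.DataFrame([
            adm_row("E1", "2010-05-01", discharge="2010-05-10", dx="ADRD01"),
            adm_row("E1", "2010-06-05"),  # 35 d after admit, 26 d after discharge
        ])
        assert select_outcome(adm, "2010-05-01")["case_date"] == \
            pd.Timestamp("2010-06-05")
        rules = EligibilityRules(washout_anchor="discharge")
        assert select_outcome(adm, "2010-05-01", rules) is None


class TestMakeReferents:
    def test_worked_example_monday_july_2014(self):
        refs = make_referents("2014-07-14")
        assert refs == [pd.Timestamp(d) for d in
                        ("2014-07-07", "2014-07-21", "2014-07-28")]

    def test_bidirectional_for_first_occurrence(self):
        refs = make_referents("2014-07-07")
        assert refs == [pd.Timestamp(d) for d in
                        ("2014-07-14", "2014-07-21", "2014-07-28")]

    @given(st.dates(min_value=pd.Timestamp("2000-01-01").date(),
                    max_value=pd.Timestamp("2016-12-31").date()))
    def test_referents_share_weekday_month_year(self, d):
        case = pd.Timestamp(d)
        refs = make_referents(case)
        assert len(refs) in (3, 4)
        for r in refs:
            assert (r.dayofweek, r.month, r.year) == \
                (case.dayofweek, case.month, case.year)
            assert r != case


class TestBuildStrata:
    def _events(self):
        return pd.DataFrame([{"enrollee_id": "E1",
                              "case_date": pd.Timestamp("2010-07-14"),
                              "zip": "Z0"}])

    def _exposures(self, dates, **drop):
        rows = []
        for d in dates:
            rows.append({"zip": "Z0", "date": pd.Timestamp(d),
                         "heat_pctl": 50.0, "pm25": 10.0})
        df = pd.DataFrame(rows)
        for col, dts in drop.items():
            df.loc[df["date"].isin(pd.to_datetime(dts)), col] = np.nan
        return df

    def test_complete_exposures_full_stratum(self):
        dates = ["2010-07-07", "2010-07-14", "2010-07-21", "2010-07-28"]
        strata = build_strata(self._events(), self._exposures(dates))
        assert len(strata) == 4
        assert strata["case_flag"].sum() == 1

    def test_missing_control_day_shrinks_stratum(self):
        dates = ["2010-07-07", "2010-07-14", "2010-07-21", "2010-07-28"]
        strata = build_strata(self._events(),
                              self._exposures(dates, pm25=["2010-07-21"]))
        assert len(strata) == 3

    def test_all_controls_missing_drops_stratum(self):
        strata = build_strata(self._events(), self._exposures(["2010-07-14"]))
        assert strata.empty
        assert strata.attrs["n_strata_excluded"] == 1

    def test_event_zip_absent_excluded(self):
        exp = self._exposures(["2010-07-14"])
        exp["zip"] = "OTHER"
        strata = build_strata(self._events(), exp)
        assert strata.empty

    def test_known_violation_count_survives(self):
        # 3 events; one loses a control to missing pm, one loses everything
        events = pd.DataFrame([
            {"enrollee_id": "E1", "case_date": pd.Timestamp("2010-07-14"), "zip": "Z0"},
            {"enrollee_id": "E2", "case_date": pd.Timestamp("2010-07-15"), "zip": "Z0"},
            {"enrollee_id": "E3", "case_date": pd.Timestamp("2010-08-04"), "zip": "Z1"},
        ])
        days = pd.date_range("2010-07-01", "2010-07-31", freq="D")
        exp = pd.DataFrame({"zip": "Z0", "date": days,
                            "heat_pctl": 50.0, "pm25": 10.0})
        exp.loc[exp["date"] == "2010-07-22", "pm25"] = np.nan  # E2 control
        strata = build_strata(events, exp)
        # E3's ZIP has no exposures at all -> excluded
        assert strata["stratum_id"].nunique() == 2
        assert strata.attrs["n_strata_excluded"] == 1
        sizes = strata.groupby("stratum_id").size()
        # E1 (Wed 07-14): 3 referents -> 4 days; E2 (Thu 07-15): 4 referents
        # minus the missing-PM 07-22 -> 4 days
        assert sorted(sizes) == [4, 4]


class TestEngineEquivalence:
    def test_vectorized_matches_reference_loop(self):
        from heatpm.synthetic import (SYNTHETIC_ADRD_CODES, SimulationConfig,
                                      gen_admissions, gen_climate_map)
        from heatpm.cohort import build_cohort

        cfg = SimulationConfig(n_zips=20, n_enrollees=1500,
                               date_start="2004-01-01",
                               date_end="2010-12-31", rng_seed=13)
        climate = gen_climate_map(cfg.n_zips, seed=13)
        adm = gen_admissions(cfg, climate, adrd_fraction=0.8,
                             snf_fraction=0.1,
                             nonqualifying_source_fraction=0.1)
        vec = build_cohort(adm, SYNTHETIC_ADRD_CODES).sort_values(
            "enrollee_id").reset_index(drop=True)
        loop = build_cohort(adm, SYNTHETIC_ADRD_CODES, engine="loop") \
            .sort_values("enrollee_id").reset_index(drop=True)
        vec["case_date"] = pd.to_datetime(vec["case_date"])
        loop["case_date"] = pd.to_datetime(loop["case_date"])
        pd.testing.assert_frame_equal(vec, loop)
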