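"""Cohort derivations: filters, daily series, thresholds, person-days."""

import numpy as np
import pandas as pd
import pytest

from occmsm import cohort

from conftest import make_episodes
from oracles import census_by_day_loop, persondays_per_patient_loop


class TestInclusionFilters:
    def test_boundaries(self):
        recs = make_episodes([
            ("prior", "H", 1, 0, 5, False, None),     # admitted before the year
            ("edge_keep", "H", 1, 351, 360, False, None),
            ("edge_drop", "H", 1, 352, 360, False, None),
            ("normal", "H", 1, 100, 104, False, None),
        ])
        kept = cohort.apply_inclusion_filters(recs, year_length=365)
        assert sorted(kept["patient_id"]) == ["edge_keep", "normal"]

    def test_empty_input_passes_through(self):
        empty = make_episodes([])
        for col in cohort.EPISODE_COLUMNS:
            if col not in empty.columns:
                empty[col] = pd.Series(dtype=float)
        out = cohort.apply_inclusion_filters(empty, 365)
        assert len(out) == 0

    def test_invalid_dates_raise_with_row_id(self):
        recs = make_episodes([("bad", "H", 1, 10, 5, False, None)])
        with pytest.raises(cohort.CohortError, match="bad"):
            cohort.apply_inclusion_filters(recs, 365)


class TestDailySeries:
    def test_hand_enumerated_toy_hospital(self):
        # P1 in house days 1-2, P2 a same-day stay on day 2, P3 days 2-4
        recs = make_episodes([
            ("P1", "H", 1, 1, 3, False, None),
            ("P2", "H", 1, 2, 2, False, None),
            ("P3", "H", 1, 2, 5, False, None),
        ])
        hd = cohort.build_daily_series(recs, year_length=5)
        assert hd["census"].tolist() == [1, 3, 1, 1, 0]
        assert hd["peak_census"].iloc[0] == 3
        np.testing.assert_allclose(
            hd["capacity_utilization"], [100 / 3, 100, 100 / 3, 100 / 3, 0]
        )
        # day 2: two admissions plus the same-day discharge, over peak 3
        assert hd.loc[hd["day"] == 2, "turnover"].iloc[0] == pytest.approx(100.0)

    def test_single_patient_all_year(self):
        recs = make_episodes([("P1", "H", 1, 1, 366, False, None)])
        hd = cohort.build_daily_series(recs, year_length=365)
        assert (hd["capacity_utilization"] == 100.0).all()

    def test_census_conservation_and_loop_oracle(self, random_episode_fixtures):
        for recs in random_episode_fixtures:
            hd = cohort.build_daily_series(recs, year_length=120)
            for hid, sub in recs.groupby("hospital_id"):
                mine = hd.loc[hd["hospital_id"] == hid, "census"].to_numpy()
                np.testing.assert_array_equal(mine, census_by_day_loop(sub, 120))
            # total person-days present equal the census mass
            present = (recs["discharge_day"] - recs["admission_day"]).clip(lower=1)
            assert hd["census"].sum() == present.sum()

    def test_mean_pccl_only_when_occupied(self):
        recs = make_episodes([("P1", "H", 1, 2, 4, False, None)])
        hd = cohort.build_daily_series(recs, year_length=5)
        assert np.isnan(hd["mean_pccl"].iloc[0])
        assert hd["mean_pccl"].iloc[1] == 1.0  # fixture pccl


class TestThresholds:
    def test_linear_interpolation_quantile(self):
        hd = pd.DataFrame({"hospital_id": "H", "day": range(20),
                           "capacity_utilization": np.arange(1.0, 21.0)})
        thr = cohort.derive_threshold(hd, 85)
        assert thr["threshold"].iloc[0] == pytest.approx(17.15)
        flagged = cohort.flag_exposure(hd, thr)
        assert flagged["exposed"].sum() == 3  # days 18, 19, 20

    def test_constant_series_all_exposed(self):
        hd = pd.DataFrame({"hospital_id": "H", "day": range(10),
                           "capacity_utilization": 55.0})
        thr = cohort.derive_threshold(hd, 85)
        flagged = cohort.flag_exposure(hd, thr)
        assert (flagged["exposed"] == 1).all()

    def test_two_point_series(self):
        hd = pd.DataFrame({"hospital_id": "H", "day": [1, 2],
                           "capacity_utilization": [10.0, 90.0]})
        thr = cohort.derive_threshold(hd, 85)
        assert thr["threshold"].iloc[0] == pytest.approx(78.0)
        assert cohort.flag_exposure(hd, thr)["exposed"].tolist() == [0, 1]

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        hd = pd.DataFrame({"hospital_id": "H", "day": range(200),
                           "capacity_utilization": rng.uniform(0, 100, 200)})
        taus = [cohort.derive_threshold(hd, p)["threshold"].iloc[0]
                for p in (50, 75, 85, 90, 95)]
        assert taus == sorted(taus)

    def test_empty_series_raises(self):
        with pytest.raises(cohort.CohortError):
            cohort.derive_threshold(pd.DataFrame(columns=["hospital_id", "capacity_utilization"]), 85)


def _toy_days(flags):
    return (
        pd.DataFrame({
            "hospital_id": "H", "day": np.arange(1, len(flags) + 1),
            "capacity_utilization": [90.0 if f else 10.0 for f in flags],
            "turnover": 5.0, "mean_pccl": 1.0,
        }),
        pd.DataFrame({"hospital_id": ["H"], "percentile": [85], "threshold": [50.0]}),
    )


class TestPersonDays:
    def test_survivor_single_day(self):
        hd, thr = _toy_days([0, 0])
        recs = make_episodes([("P", "H", 1, 1, 2, False, None)])
        out = cohort.expand_person_days(recs, hd, thr)
        assert len(out) == 1
        assert out.loc[0, "t"] == 1 and out.loc[0, "death"] == 0

    def test_death_on_day_three_with_exposure_path(self):
        hd, thr = _toy_days([1, 0, 1, 0, 0])
        recs = make_episodes([("P", "H", 1, 1, 3, True, 3)])
        out = cohort.expand_person_days(recs, hd, thr)
        assert out["t"].tolist() == [1, 2, 3]
        assert out["exposed"].tolist() == [1, 0, 1]
        assert out["cum_exposed"].tolist() == [1, 1, 2]
        assert out["death"].tolist() == [0, 0, 1]

    def test_long_stay_capped_at_fourteen(self):
        hd, thr = _toy_days([0] * 25)
        recs = make_episodes([("P", "H", 1, 1, 21, False, None)])
        assert len(cohort.expand_person_days(recs, hd, thr)) == 14

    def test_exposure_lag_switch_excludes_current_day(self):
        hd, thr = _toy_days([1, 1, 0])
        recs = make_episodes([("P", "H", 1, 1, 4, False, None)])
        out = cohort.expand_person_days(
            recs, hd, thr, exposure_lag=cohort.ExposureLag(include_current=False)
        )
        assert out["cum_exposed"].tolist() == [0, 1, 2]

    def test_row_count_matches_per_patient_loop(self, random_episode_fixtures):
        for recs in random_episode_fixtures:
            hd = cohort.build_daily_series(recs, year_length=120)
            thr = cohort.derive_threshold(hd, 85)
            out = cohort.expand_person_days(recs, hd, thr)
            assert len(out) == persondays_per_patient_loop(recs)
            # structural invariants of the expansion
            assert out["exposed"].isin([0, 1]).all()
            grp = out.groupby("patient_id")
            assert (grp["cum_exposed"].diff().dropna() >= 0).all()
            deaths = out.groupby("patient_id")["death"].sum()
            assert deaths.isin([0, 1]).all()
            # a death occurs only on the patient's final row
            last = grp.tail(1).set_index("patient_id")["death"]
            assert deaths.sum() == last.sum()

    def test_out_of_year_person_day_raises(self):
        hd, thr = _toy_days([0, 0])
        recs = make_episodes([("P", "H", 1, 2, 6, False, None)])
        with pytest.raises(cohort.CohortError):
            cohort.expand_person_days(recs, hd, thr)


class TestCsvInterface:
    def test_iso_date_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["a"], "hospital_id": ["H"], "hospital_type": [1],
            "admission_date": ["2017-01-05"], "discharge_date": ["2017-01-09"],
            "died": [False], "death_date": [None],
            "sex": ["m"], "age_group": [4], "pccl": [0], "elixhauser_weight": [0.0],
        })
        p = tmp_path / "eps.csv"
        df.to_csv(p, index=False)
        out = cohort.read_episodes(p, year_start="2017-01-01")
        assert out.loc[0, "admission_day"] == 5
        assert out.loc[0, "discharge_day"] == 9

    def test_unparseable_date_raises(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["a"], "hospital_id": ["H"], "hospital_type": [1],
            "admission_date": ["05.01.2017"], "discharge_date": ["2017-01-09"],
            "died": [False], "death_date": [None],
            "sex": ["m"], "age_group": [4], "pccl": [0], "elixhauser_weight": [0.0],
        })
        p = tmp_path / "eps.csv"
        df.to_csv(p, index=False)
        with pytest.raises(cohort.CohortError):
            cohort.read_episodes(p, year_start="2017-01-01")
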