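from datetime import date

import numpy as np
import pandas as pd
import pytest

from cardiowell.index_engine import fit_index_curve
from cardiowell.synth import district_fixture, generate_user_sources
from cardiowell.warehouse import (
    EtlSources,
    Warehouse,
    age_in_full_years,
    band_salary,
    derive_fact_fields,
    exercise_from_calories,
)


@pytest.fixture
def wh(tmp_path):
    return Warehouse.init(tmp_path / "wh")


@pytest.fixture(scope="module")
def curve():
    return fit_index_curve()


def _snapshot(uid=4, district="LSB", education="Secondary", salary=1500,
              analysis="2019-01-01"):
    return {
        "id_user": uid, "district": district, "education_level": education,
        "salary": salary, "gender": "Female", "weight": 70, "height": 165,
        "family_history": "No", "diabetes": "No", "hypertension": "No",
        "pain_after_effort": "No", "hypothyroidism": "No",
        "total_cholesterol": 180, "fast_glucose": 100,
        "clinical_analysis_date": analysis, "date_of_birth": "1980-05-05",
        "cigarettes_per_day": 0, "smoke_years": 0,
    }


class TestInit:
    def test_fresh_directory_five_empty_tables(self, tmp_path):
        wh = Warehouse.init(tmp_path / "dw")
        status = wh.status()
        for table in ("fact", "dim_user", "dim_user_hst", "dim_calendar",
                      "dim_district"):
            assert status[table] == 0

    def test_reinit_without_overwrite_errors(self, tmp_path):
        Warehouse.init(tmp_path / "dw")
        with pytest.raises(FileExistsError):
            Warehouse.init(tmp_path / "dw")

    def test_reinit_with_overwrite_empties(self, tmp_path):
        wh = Warehouse.init(tmp_path / "dw")
        wh.apply_user_snapshot(_snapshot(), "2019-01-01")
        wh = Warehouse.init(tmp_path / "dw", overwrite=True)
        assert wh.status()["dim_user"] == 0

    def test_open_uninitialized_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            Warehouse(tmp_path / "nope")


class TestStaticDimensions:
    def test_full_year_calendar(self, wh):
        counts = wh.load_static_dimensions(
            (date(2019, 1, 1), date(2019, 12, 31)), district_fixture())
        assert counts["dim_calendar"] == 365
        assert counts["dim_district"] == 18

    def test_weekday_consistent(self, wh):
        wh.load_static_dimensions((date(2019, 10, 20), date(2019, 10, 20)),
                                  district_fixture())
        cal = wh.read("dim_calendar")
        assert cal.iloc[0]["weekday"] == "Sunday"

    def test_repeat_call_is_noop(self, wh):
        rng = (date(2019, 1, 1), date(2019, 1, 31))
        wh.load_static_dimensions(rng, district_fixture())
        again = wh.load_static_dimensions(rng, district_fixture())
        assert again == {"dim_calendar": 0, "dim_district": 0}

    def test_bad_range_rejected(self, wh):
        with pytest.raises(ValueError):
            wh.load_static_dimensions((date(2019, 2, 1), date(2019, 1, 1)),
                                      district_fixture())

    def test_duplicate_district_codes_rejected(self, wh):
        bad = pd.concat([district_fixture(), district_fixture().head(1)])
        with pytest.raises(ValueError):
            wh.load_static_dimensions((date(2019, 1, 1), date(2019, 1, 2)), bad)


class TestDerivedFields:
    def test_bmi_formula(self):
        derived = derive_fact_fields(_snapshot() | {"weight": 80, "height": 180},
                                     {"calories": 200})
        assert derived["bmi"] == pytest.approx(24.69, abs=0.01)

    def test_smoke_amount_formula(self):
        snap = _snapshot() | {"cigarettes_per_day": 10, "smoke_years": 10}
        derived = derive_fact_fields(snap, {"calories": 200})
        assert derived["smoke_amount"] == pytest.approx(36.5)

    def test_zero_cigarettes_zero_amount(self):
        derived = derive_fact_fields(_snapshot(), {"calories": 200})
        assert derived["smoke_amount"] == 0.0

    @pytest.mark.parametrize("analysis,expected", [
        ("2019-05-31", 43),  # day before 44th birthday
        ("2019-06-01", 44),
    ])
    def test_age_full_year_convention(self, analysis, expected):
        snap = _snapshot() | {"date_of_birth": "1975-06-01",
                              "clinical_analysis_date": analysis}
        assert derive_fact_fields(snap, {"calories": 10})["age"] == expected

    def test_age_in_full_years_matches_date_arithmetic(self):
        born = date(1975, 6, 1)
        for offset_years, probe in [(30, date(2005, 6, 1)), (30, date(2005, 12, 1))]:
            assert age_in_full_years(born, probe) == offset_years

    def test_height_must_be_positive(self):
        with pytest.raises(ValueError):
            derive_fact_fields(_snapshot() | {"height": 0}, {"calories": 10})

    def test_birth_after_analysis_rejected(self):
        snap = _snapshot() | {"date_of_birth": "2020-01-01"}
        with pytest.raises(ValueError):
            derive_fact_fields(snap, {"calories": 10})

    @pytest.mark.parametrize("calories,level", [
        (50, "None"), (99, "None"), (100, "Low"), (299, "Low"),
        (300, "Moderate"), (599, "Moderate"), (600, "High"), (2500, "High"),
    ])
    def test_exercise_thresholds(self, calories, level):
        assert exercise_from_calories(calories) == level

    @pytest.mark.parametrize("salary,band", [
        (500, "<1000"), (1500, "1000-1999"), (2500, "2000-2999"),
        (4000, "3000-4999"), (9000, ">=5000"),
    ])
    def test_salary_banding(self, salary, band):
        assert band_salary(salary) == band


class TestScd4:
    def test_residence_change_worked_example(self, wh):
        wh.apply_user_snapshot(_snapshot(district="LSB"), "2019-01-01")
        report = wh.apply_user_snapshot(_snapshot(district="VCT"), "2019-10-20")
        assert report.action == "update"
        assert report.changed == {"district": ("LSB", "VCT")}
        hst = wh.read("dim_user_hst")
        closed = hst[hst["valid_to"].notna()]
        opened = hst[hst["valid_to"].isna()]
        assert len(closed) == 1 and len(opened) == 1
        assert closed.iloc[0]["district"] == "LSB"
        assert closed.iloc[0]["valid_to"] == "2019-10-20"
        assert opened.iloc[0]["district"] == "VCT"
        assert opened.iloc[0]["valid_from"] == "2019-10-20"
        assert wh.read("dim_user").iloc[0]["district"] == "VCT"

    def test_identical_snapshot_is_noop(self, wh):
        wh.apply_user_snapshot(_snapshot(), "2019-01-01")
        before = wh.read("dim_user_hst")
        report = wh.apply_user_snapshot(_snapshot(), "2019-02-01")
        assert report.action == "noop"
        pd.testing.assert_frame_equal(before, wh.read("dim_user_hst"))

    def test_three_salary_changes_contiguous_intervals(self, wh):
        wh.apply_user_snapshot(_snapshot(salary=500), "2019-01-01")
        for i, salary in enumerate([1500, 2500, 4000], start=1):
            wh.apply_user_snapshot(_snapshot(salary=salary), f"2019-0{i + 1}-01")
        hst = wh.read("dim_user_hst").sort_values("valid_from")
        assert hst["valid_to"].notna().sum() == 3
        assert hst["valid_to"].isna().sum() == 1
        closed = hst[hst["valid_to"].notna()]
        opens = hst["valid_from"].tolist()
        assert closed["valid_to"].tolist() == opens[1:]

    def test_snapshot_before_open_interval_rejected(self, wh):
        wh.apply_user_snapshot(_snapshot(district="LSB"), "2019-06-01")
        with pytest.raises(ValueError):
            wh.apply_user_snapshot(_snapshot(district="VCT"), "2019-05-01")

    def test_remove_user_tombstone(self, wh):
        wh.apply_user_snapshot(_snapshot(), "2019-01-01")
        wh.remove_user(4, "2019-03-01")
        assert wh.read("dim_user").iloc[0]["active"] == "0"
        assert wh.read("dim_user_hst")["valid_to"].notna().all()
        with pytest.raises(KeyError):
            wh.remove_user(999, "2019-03-01")

    def test_partition_property_random_sequences(self, tmp_path):
        rng = np.random.default_rng(17)
        wh = Warehouse.init(tmp_path / "dw")
        day = 1
        for _ in range(25):
            uid = int(rng.integers(1, 4))
            snap = _snapshot(uid=uid,
                             district=str(rng.choice(["LSB", "VCT", "PRT"])),
                             salary=int(rng.choice([500, 1500, 2500])))
            wh.apply_user_snapshot(snap, date(2019, 1, 1) + pd.Timedelta(days=day))
            day += int(rng.integers(1, 5))
        hst = wh.read("dim_user_hst")
        dim = wh.read("dim_user")
        for uid, group in hst.groupby("id_user"):
            group = group.sort_values("valid_from")
            assert group["valid_to"].isna().sum() == 1
            assert group["valid_to"].isna().iloc[-1]
            closed = group[group["valid_to"].notna()]
            # contiguity: each close date equals the next open date
            assert closed["valid_to"].tolist() == group["valid_from"].tolist()[1:]
            # open interval equals the current dimension row
            open_row = group[group["valid_to"].isna()].iloc[0]
            current = dim[dim["id_user"] == uid].iloc[0]
            for attr in ("district", "education", "salary"):
                assert open_row[attr] == current[attr]


class TestEtl:
    @pytest.fixture
    def sources(self):
        users, meas = generate_user_sources(10, 30, seed=7, change_rate=0.3)
        return EtlSources(users, meas, district_fixture())

    def test_fresh_warehouse_loads_all_facts(self, wh, sources, tiny_model, curve):
        report = wh.run_etl(sources, tiny_model, curve)
        assert report.facts_loaded == 300
        assert report.users_inserted == 10
        assert report.watermark_after == "2019-01-30"

    def test_immediate_rerun_loads_nothing(self, wh, sources, tiny_model, curve):
        wh.run_etl(sources, tiny_model, curve)
        fact_before = wh.read("fact")
        report = wh.run_etl(sources, tiny_model, curve)
        assert report.facts_loaded == 0
        pd.testing.assert_frame_equal(fact_before, wh.read("fact"))

    def test_incremental_slice_exact(self, wh, sources, tiny_model, curve):
        wh.run_etl(sources, tiny_model, curve)
        extra = sources.measurements.head(5).copy()
        extra["index_date"] = ["2019-02-0%d" % d for d in range(1, 6)]
        grown = EtlSources(sources.users,
                           pd.concat([sources.measurements, extra]),
                           sources.districts)
        report = wh.run_etl(grown, tiny_model, curve)
        assert report.facts_loaded == 5

    def test_watermark_monotone(self, wh, sources, tiny_model, curve):
        r1 = wh.run_etl(sources, tiny_model, curve)
        old = EtlSources(sources.users, sources.measurements.head(3),
                         sources.districts)
        r2 = wh.run_etl(old, tiny_model, curve)
        assert r2.watermark_after == r1.watermark_after
        assert r2.facts_loaded == 0

    def test_unknown_user_quarantined(self, wh, sources, tiny_model, curve):
        bad = sources.measurements.copy()
        bad.loc[bad.index[-1], "id_user"] = 999
        report = wh.run_etl(EtlSources(sources.users, bad, sources.districts),
                            tiny_model, curve)
        assert len(report.quarantined) == 1
        assert report.quarantined[0]["id_user"] == 999
        assert report.facts_loaded == 299

    def test_referential_integrity(self, wh, sources, tiny_model, curve):
        wh.run_etl(sources, tiny_model, curve)
        fact = wh.read("fact")
        users = set(wh.read("dim_user")["id_user"])
        dates = set(wh.read("dim_calendar")["date"])
        assert set(fact["id_user"]) <= users
        assert set(fact["index_date"]) <= dates

    def test_index_values_in_range_with_colourable_values(self, wh, sources,
                                                          tiny_model, curve):
        wh.run_etl(sources, tiny_model, curve)
        values = wh.read("fact")["index_value"].astype(float)
        assert values.between(-5, 5).all()

    def test_fact_grain_unique(self, wh, sources, tiny_model, curve):
        wh.run_etl(sources, tiny_model, curve)
        fact = wh.read("fact")
        assert not fact.duplicated(["id_user", "index_date"]).any()
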