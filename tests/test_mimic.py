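"""Cohort extraction rules on synthetic MIMIC-schema fixtures."""

import numpy as np
import pandas as pd
import pytest

from icurisk.data import DXPROC, MEDVIT
from icurisk.mimic import (apply_exclusions, build_static_vector,
                           decode_static_vector, dedupe_consecutive,
                           elapsed_time, extract_cohort, label_readmission,
                           oasis_bin_vital, relabel_rare, split_patients)
from icurisk.synthetic import STATIC_NAMES
from oracles import brute_dedupe

T = pd.Timestamp


class TestExclusions:
    def _stays(self):
        return pd.DataFrame([
            # patient 1: clean stay
            {"patient_id": 1, "stay_id": 10, "intime": T("2100-01-01"),
             "outtime": T("2100-01-05")},
            # patient 2: dies during the stay
            {"patient_id": 2, "stay_id": 20, "intime": T("2100-01-01"),
             "outtime": T("2100-01-06")},
            # patient 3: 17 years old at discharge
            {"patient_id": 3, "stay_id": 30, "intime": T("2100-01-01"),
             "outtime": T("2100-01-04")},
            # patient 4: dies day 20 after discharge, no readmission
            {"patient_id": 4, "stay_id": 40, "intime": T("2100-01-01"),
             "outtime": T("2100-01-03")},
            # patient 5: clean stay
            {"patient_id": 5, "stay_id": 50, "intime": T("2100-02-01"),
             "outtime": T("2100-02-10")},
        ])

    def _people(self):
        deaths = pd.Series({2: T("2100-01-03"), 4: T("2100-01-23")})
        births = pd.Series({1: T("2050-01-01"), 2: T("2050-01-01"),
                            3: T("2083-02-01"), 4: T("2050-01-01"),
                            5: T("2050-01-01")})
        return deaths, births

    def test_rules_applied_one_each(self):
        deaths, births = self._people()
        kept, counts = apply_exclusions(self._stays(), deaths, births)
        assert sorted(kept.stay_id) == [10, 50]
        assert counts["died_in_stay"] == 1
        assert counts["under_18"] == 1
        assert counts["died_within_30d_no_readmit"] == 1

    def test_death_after_readmission_keeps_and_labels_positive(self):
        stays = pd.DataFrame([
            {"patient_id": 9, "stay_id": 90, "intime": T("2100-01-01"),
             "outtime": T("2100-01-03")},
            {"patient_id": 9, "stay_id": 91, "intime": T("2100-01-13"),
             "outtime": T("2100-01-15")},
        ])
        deaths = pd.Series({9: T("2100-01-23")})  # day 20 after first discharge
        births = pd.Series({9: T("2050-01-01")})
        # labelling uses all stays, then exclusions remove unusable samples
        stays["label"] = label_readmission(stays).values
        kept, counts = apply_exclusions(stays, deaths, births)
        assert 90 in set(kept.stay_id)  # retained: readmitted before death
        assert kept.loc[kept.stay_id == 90, "label"].iloc[0] == 1
        # the second stay ends <30d before death without readmission
        assert 91 not in set(kept.stay_id)

    def test_missing_outtime_rejected(self):
        stays = self._stays()
        stays.loc[0, "outtime"] = pd.NaT
        deaths, births = self._people()
        kept, counts = apply_exclusions(stays, deaths, births)
        assert counts["missing_outtime"] == 1
        assert 10 not in set(kept.stay_id)


class TestLabelReadmission:
    def _two_stays(self, gap_days):
        out = T("2100-01-10")
        return pd.DataFrame([
            {"patient_id": 1, "stay_id": 1, "intime": T("2100-01-01"), "outtime": out},
            {"patient_id": 1, "stay_id": 2,
             "intime": out + pd.Timedelta(days=gap_days),
             "outtime": out + pd.Timedelta(days=gap_days + 2)},
        ])

    @pytest.mark.parametrize("gap,expected", [(29.5, 1), (31, 0), (30.0, 1)])
    def test_thirty_day_boundary_inclusive(self, gap, expected):
        labels = label_readmission(self._two_stays(gap))
        assert labels.iloc[0] == expected
        assert labels.iloc[1] == 0  # last stay has no later admission

    def test_overlapping_stays_raise_with_ids(self):
        df = self._two_stays(-5)
        with pytest.raises(ValueError, match="1 and 2"):
            label_readmission(df)


class TestOasisBins:
    @pytest.mark.parametrize("vital,value,expected", [
        ("temperature", 35.0, "temperature:33.22_35.93"),
        ("mean_arterial_pressure", 55, "mean_arterial_pressure:51_61.32"),
        ("respiratory_rate", 35, "respiratory_rate:31_44"),
        ("gcs", 15, "gcs:15"),
        ("gcs", 7, "gcs:lt8"),
        ("heart_rate", 88, "heart_rate:33_88"),
        ("heart_rate", 89, "heart_rate:89_106"),
        ("urine_output", 7000, "urine_output:gt6896"),
    ])
    def test_published_cutpoints(self, vital, value, expected):
        assert oasis_bin_vital(vital, value) == expected

    def test_out_of_range_dropped(self):
        assert oasis_bin_vital("temperature", 80.0) is None
        assert oasis_bin_vital("heart_rate", -5) is None

    def test_unknown_vital_rejected(self):
        with pytest.raises(KeyError):
            oasis_bin_vital("blood_sugar", 5.0)


class TestDedupe:
    def test_keeps_latest_of_run(self):
        events = [("A", 1.0), ("A", 2.0), ("B", 3.0)]
        assert dedupe_consecutive(events, {"A", "B"}) == [("A", 2.0), ("B", 3.0)]

    def test_run_broken_by_other_code(self):
        events = [("A", 1.0), ("B", 2.0), ("A", 3.0)]
        assert dedupe_consecutive(events, {"A", "B"}) == events

    def test_non_vital_codes_untouched(self):
        events = [("x", 1.0), ("x", 2.0)]
        assert dedupe_consecutive(events, set()) == events

    def test_matches_brute_force_on_random_sequences(self, rng):
        codes = list("ABCD")
        vitals = {"A", "B"}
        for _ in range(100):
            n = int(rng.integers(1, 15))
            ev = [(codes[rng.integers(0, 4)], float(t)) for t in range(n)]
            assert dedupe_consecutive(ev, vitals) == brute_dedupe(ev, vitals)


class TestRelabelRare:
    def test_strict_threshold(self):
        stay_values = {i: ["common"] for i in range(100)}
        for i in range(99):
            stay_values[i].append("rare")
        mapping, counts = relabel_rare(stay_values, threshold=100)
        assert mapping["common"] == "common"
        assert mapping["rare"] == "other"
        assert counts == {"common": 100, "rare": 99}

    def test_matches_brute_force_filter(self, rng):
        stay_values = {i: [f"v{rng.integers(0, 8)}" for _ in range(3)]
                       for i in range(60)}
        mapping, counts = relabel_rare(stay_values, threshold=20)
        for v, n in counts.items():
            brute = sum(1 for vals in stay_values.values() if v in vals)
            assert n == brute
            assert mapping[v] == (v if brute >= 20 else "other")


class TestElapsedTime:
    def test_event_at_reference_is_zero(self):
        assert elapsed_time(T("2100-01-01"), T("2100-01-01")) == 0.0

    def test_one_year_old_code_in_days(self):
        assert elapsed_time(T("2099-01-01"), T("2100-01-01"), "days") == 365.0

    def test_hours_unit(self):
        assert elapsed_time(T("2100-01-01 06:30"), T("2100-01-01 12:00"),
                            "hours") == pytest.approx(5.5)

    def test_event_after_reference_clamped(self):
        assert elapsed_time(T("2100-01-02"), T("2100-01-01"), "days") == 0.0


class TestSplitPatients:
    def test_deterministic_and_patient_level(self):
        ids = [1, 1, 1, 2, 3]
        a = split_patients(ids, seed=4)
        b = split_patients(ids, seed=4)
        assert a == b
        assert len({a[1]}) == 1  # one assignment per patient

    def test_fraction_approximates_ten_percent(self):
        split = split_patients(list(range(10_000)), test_fraction=0.10, seed=0)
        n_test = sum(1 for v in split.values() if v == "test")
        assert abs(n_test - 1000) <= 100  # within +-1% of the patient count


class TestStaticVector:
    def test_reference_group_all_zero_categoricals(self):
        x = build_static_vector({
            "age": 70, "icu_los_days": 2.0, "preicu_los_days": 1.0,
            "n_recent_admissions": 0, "gender": "F", "elective": False,
            "ethnicity": "WHITE", "insurance": "Medicare",
            "marital_status": "MARRIED", "admission_location": "EMERGENCY ROOM ADMIT"})
        cat_cols = [n for n in STATIC_NAMES
                    if n.split("_")[0] in ("gender", "elective", "ethnicity",
                                           "insurance", "marital", "admloc")]
        assert all(x[STATIC_NAMES.index(c)] == 0 for c in cat_cols)
        assert x[STATIC_NAMES.index("age")] == 70

    def test_male_medicare_one_hot(self):
        x = build_static_vector({"gender": "M", "insurance": "Medicare"})
        assert x[STATIC_NAMES.index("gender_male")] == 1
        assert sum(x[STATIC_NAMES.index(c)] for c in STATIC_NAMES
                   if c.startswith("insurance_")) == 0

    def test_round_trip_decode(self):
        raw = {"age": 55.0, "icu_los_days": 3.5, "preicu_los_days": 0.5,
               "n_recent_admissions": 2.0, "gender": "M", "elective": True,
               "ethnicity": "BLACK/AFRICAN AMERICAN", "insurance": "Private",
               "marital_status": "SINGLE",
               "admission_location": "PHYS REFERRAL/NORMAL DELI"}
        d = decode_static_vector(build_static_vector(raw))
        assert d["gender"] == "M" and d["elective"] is True
        assert d["ethnicity"] == "black" and d["insurance"] == "private"
        assert d["marital"] == "single" and d["admloc"] == "physician_referral"
        assert d["age"] == 55.0


@pytest.fixture(scope="module")
def mimic_fixture(tmp_path_factory):
    """Tiny synthetic directory in the MIMIC-III v1.4 table schema."""
    d = tmp_path_factory.mktemp("mimic")
    pd.DataFrame([
        {"SUBJECT_ID": 1, "GENDER": "M", "DOB": "2040-05-01", "DOD": ""},
        {"SUBJECT_ID": 2, "GENDER": "F", "DOB": "2035-01-01", "DOD": ""},
    ]).to_csv(d / "PATIENTS.csv", index=False)
    pd.DataFrame([
        {"HADM_ID": 100, "SUBJECT_ID": 1, "ADMITTIME": "2100-01-01 00:00",
         "DISCHTIME": "2100-01-12 00:00", "ADMISSION_TYPE": "EMERGENCY",
         "ADMISSION_LOCATION": "EMERGENCY ROOM ADMIT", "INSURANCE": "Medicare",
         "MARITAL_STATUS": "MARRIED", "ETHNICITY": "WHITE"},
        {"HADM_ID": 101, "SUBJECT_ID": 1, "ADMITTIME": "2100-02-01 00:00",
         "DISCHTIME": "2100-02-08 00:00", "ADMISSION_TYPE": "EMERGENCY",
         "ADMISSION_LOCATION": "EMERGENCY ROOM ADMIT", "INSURANCE": "Medicare",
         "MARITAL_STATUS": "MARRIED", "ETHNICITY": "WHITE"},
        {"HADM_ID": 200, "SUBJECT_ID": 2, "ADMITTIME": "2100-03-01 00:00",
         "DISCHTIME": "2100-03-10 00:00", "ADMISSION_TYPE": "ELECTIVE",
         "ADMISSION_LOCATION": "PHYS REFERRAL/NORMAL DELI", "INSURANCE": "Private",
         "MARITAL_STATUS": "SINGLE", "ETHNICITY": "BLACK/AFRICAN AMERICAN"},
    ]).to_csv(d / "ADMISSIONS.csv", index=False)
    pd.DataFrame([
        {"ICUSTAY_ID": 1000, "HADM_ID": 100, "SUBJECT_ID": 1,
         "INTIME": "2100-01-02 00:00", "OUTTIME": "2100-01-05 00:00"},
        {"ICUSTAY_ID": 1001, "HADM_ID": 101, "SUBJECT_ID": 1,
         "INTIME": "2100-02-02 00:00", "OUTTIME": "2100-02-04 00:00"},
        {"ICUSTAY_ID": 2000, "HADM_ID": 200, "SUBJECT_ID": 2,
         "INTIME": "2100-03-02 00:00", "OUTTIME": "2100-03-06 00:00"},
    ]).to_csv(d / "ICUSTAYS.csv", index=False)
    pd.DataFrame([
        {"HADM_ID": 100, "ICD9_CODE": "4280"},
        {"HADM_ID": 100, "ICD9_CODE": "5849"},
        {"HADM_ID": 101, "ICD9_CODE": "4280"},
        {"HADM_ID": 200, "ICD9_CODE": "25000"},
    ]).to_csv(d / "DIAGNOSES_ICD.csv", index=False)
    pd.DataFrame([
        {"HADM_ID": 100, "ICD9_CODE": "9604"},
    ]).to_csv(d / "PROCEDURES_ICD.csv", index=False)
    pd.DataFrame([
        {"HADM_ID": 100, "DRUG": "Furosemide", "STARTDATE": "2100-01-03 08:00"},
        {"HADM_ID": 200, "DRUG": "Heparin", "STARTDATE": "2100-03-03 10:00"},
    ]).to_csv(d / "PRESCRIPTIONS.csv", index=False)
    pd.DataFrame([
        {"ICUSTAY_ID": 1000, "ITEMID": 211, "CHARTTIME": "2100-01-03 00:00",
         "VALUENUM": 95},
        {"ICUSTAY_ID": 1000, "ITEMID": 211, "CHARTTIME": "2100-01-03 06:00",
         "VALUENUM": 97},   # consecutive same bin -> deduped
        {"ICUSTAY_ID": 1000, "ITEMID": 618, "CHARTTIME": "2100-01-03 12:00",
         "VALUENUM": 35},
        {"ICUSTAY_ID": 2000, "ITEMID": 676, "CHARTTIME": "2100-03-03 00:00",
         "VALUENUM": 35.0},
    ]).to_csv(d / "CHARTEVENTS.csv", index=False)
    pd.DataFrame([
        {"ICUSTAY_ID": 2000, "ITEMID": 226559, "CHARTTIME": "2100-03-03 08:00",
         "VALUE": 800},
    ]).to_csv(d / "OUTPUTEVENTS.csv", index=False)
    return d


class TestExtractCohort:
    def test_schema_and_labels(self, mimic_fixture):
        cohort = extract_cohort(mimic_fixture, rare_threshold=1)
        assert len(cohort) == 3
        by_id = {s.stay_id: s for s in cohort.stays}
        # patient 1 readmitted 28 days after first ICU discharge
        assert by_id[1000].label == 1
        assert by_id[1001].label == 0 and by_id[2000].label == 0
        # history: second stay carries the first admission's codes with
        # day-scale elapsed times
        names = cohort.vocabulary.code_names[DXPROC]
        codes_1001 = {names[c] for c in by_id[1001].codes_dxproc}
        assert "d_4280" in codes_1001 and "d_5849" in codes_1001
        assert np.all(by_id[1001].elapsed_dxproc >= 0)

    def test_consecutive_duplicate_vitals_deduped(self, mimic_fixture):
        cohort = extract_cohort(mimic_fixture, rare_threshold=1)
        by_id = {s.stay_id: s for s in cohort.stays}
        names = cohort.vocabulary.code_names[MEDVIT]
        hr_codes = [c for c in by_id[1000].codes_medvit
                    if names[c].startswith("v_heart_rate")]
        assert len(hr_codes) == 1  # two same-bin measurements collapsed

    def test_rare_threshold_relabels_to_other(self, mimic_fixture):
        cohort = extract_cohort(mimic_fixture, rare_threshold=2)
        names = cohort.vocabulary.code_names[DXPROC]
        assert "d_other" in names
        assert "d_4280" in names  # appears in 2 stays of patient 1

    def test_extraction_deterministic(self, mimic_fixture):
        a = extract_cohort(mimic_fixture, rare_threshold=1, seed=3)
        b = extract_cohort(mimic_fixture, rare_threshold=1, seed=3)
        assert [s.split for s in a.stays] == [s.split for s in b.stays]
        for sa, sb in zip(a.stays, b.stays):
            np.testing.assert_array_equal(sa.codes_medvit, sb.codes_medvit)
            np.testing.assert_allclose(sa.static, sb.static)

    def test_every_code_within_vocabulary(self, mimic_fixture):
        cohort = extract_cohort(mimic_fixture, rare_threshold=1)
        for s in cohort.stays:
            assert np.all(s.codes_dxproc < cohort.vocabulary.size(DXPROC))
            assert np.all(s.codes_medvit < cohort.vocabulary.size(MEDVIT))
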