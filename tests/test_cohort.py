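"""Inclusion criteria, stratification, and transaction building."""

from datetime import date

import pytest

from conftest import make_demographics, make_diagnoses
from morbidmine.cohort import (
    DEFAULT_WINDOW,
    EXCLUDED,
    DiagnosisRecord,
    PatientProfile,
    StratumKey,
    UnknownRaceLabelError,
    apply_inclusion,
    assign_stratum,
    build_cohort,
    build_transactions,
    cohort_summary,
    exclusion_counts,
    map_race,
)
from morbidmine.icd import default_filter

WINDOW = DEFAULT_WINDOW
IN_WIN = date(2016, 6, 1)


def record(pid="p1", code="E11.0", system="ICD10", when=IN_WIN, enc="e1"):
    return DiagnosisRecord(pid, enc, when, code, system)


def profile(pid="p1", race="Caucasian", age=50, bmis=(25.0,)):
    return PatientProfile(
        patient_id=pid, race_raw=race, race=race, age_years=age, bmi_values=tuple(bmis)
    )


class TestRaceMapping:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("Pacific Islander", "Asian/Pacific Islander"),
            ("Asian", "Asian/Pacific Islander"),
            ("Asian/Pacific Islander", "Asian/Pacific Islander"),
            ("Caucasian", "Caucasian"),
            ("Native American", "Native American"),
            ("", EXCLUDED),
            ("Other", EXCLUDED),
            ("Mid-Eastern Indian", EXCLUDED),
        ],
    )
    def test_default_mapping(self, label, expected):
        assert map_race(label) == expected

    def test_unknown_label_strict_raises(self):
        with pytest.raises(UnknownRaceLabelError):
            map_race("Martian")

    def test_unknown_label_lenient_excludes(self):
        assert map_race("Martian", strict=False) == EXCLUDED

    def test_nan_treated_as_missing(self):
        assert map_race(float("nan")) == EXCLUDED


class TestInclusion:
    def test_fully_valid_patient_included(self):
        prof = apply_inclusion(profile(), [record()])
        assert prof.included
        assert prof.exclusion_reasons == ()
        assert prof.age_band == "middle_aged"

    @pytest.mark.parametrize(
        "kwargs, records, reason",
        [
            (dict(age=44), [record()], "age"),  # one year under the floor
            (dict(bmis=(210.0,)), [record()], "bmi"),  # above 206 ceiling
            (dict(bmis=(18.0,)), [record()], "bmi"),  # below 18.5 floor
            (dict(race=EXCLUDED), [record()], "race"),
            (dict(), [], "no_icd10"),
            (dict(), [record(when=date(2015, 6, 1))], "no_icd10"),  # out of window
            (dict(), [record(), record(code="250.00", system="ICD9")], "icd9"),
        ],
    )
    def test_each_criterion_excludes(self, kwargs, records, reason):
        prof = apply_inclusion(profile(**kwargs), records)
        assert not prof.included
        assert reason in prof.exclusion_reasons

    def test_all_reasons_recorded_not_short_circuited(self):
        prof = apply_inclusion(profile(age=30, bmis=(300.0,), race=EXCLUDED), [])
        assert set(prof.exclusion_reasons) == {"age", "bmi", "race", "no_icd10"}

    def test_bmi_boundaries_inclusive(self):
        for bmi in (18.5, 206.0):
            assert apply_inclusion(profile(bmis=(bmi,)), [record()]).included

    def test_invalid_bmi_dropped_not_clamped(self):
        prof = apply_inclusion(profile(bmis=(25.0, 500.0)), [record()])
        assert prof.mean_bmi == 25.0

    def test_icd9_outside_window_ignored(self):
        recs = [record(), record(code="250.00", system="ICD9", when=date(2015, 1, 1))]
        assert apply_inclusion(profile(), recs).included


class TestStratum:
    @pytest.mark.parametrize(
        "age, bmi, band, obesity",
        [
            (64, 30.0, "middle_aged", "with_obesity"),  # both boundaries
            (65, 29.9, "elderly", "without_obesity"),
            (45, 25.0, "middle_aged", "without_obesity"),
            (90, 40.0, "elderly", "with_obesity"),
        ],
    )
    def test_boundaries(self, age, bmi, band, obesity):
        prof = apply_inclusion(profile(age=age, bmis=(bmi,)), [record()])
        key = assign_stratum(prof)
        assert key == StratumKey("Caucasian", band, obesity)

    def test_mean_of_multiple_bmi_values(self):
        # [25, 35] averages to exactly 30 -> with_obesity (inclusive cutoff)
        prof = apply_inclusion(profile(bmis=(25.0, 35.0)), [record()])
        assert prof.mean_bmi == 30.0
        assert assign_stratum(prof).obesity_class == "with_obesity"

    def test_requires_included_profile(self):
        with pytest.raises(ValueError):
            assign_stratum(profile())


class TestBulkCohort:
    def _tables(self):
        demo = make_demographics(
            [
                ("a", "Caucasian", 50, 25.0),
                ("a", "Caucasian", 50, 27.0),  # second BMI row, same patient
                ("b", "African American", 70, 33.0),
                ("c", "Caucasian", 44, 25.0),  # under age
                ("d", "", 50, 25.0),  # missing race
                ("e", "Caucasian", 50, 300.0),  # no valid BMI
                ("f", "Caucasian", 50, 25.0),  # will carry an ICD-9 row
                ("g", "Caucasian", 50, 25.0),  # no diagnoses at all
            ]
        )
        dx = make_diagnoses(
            [
                ("a", "a-e1", "2016-03-01", "E11.0", "ICD10"),
                ("a", "a-e1", "2016-03-01", "E11.9", "ICD10"),
                ("a", "a-e2", "2017-03-01", "I10", "ICD10"),
                ("b", "b-e1", "2016-05-01", "I10.1", "ICD10"),
                ("c", "c-e1", "2016-05-01", "I10", "ICD10"),
                ("d", "d-e1", "2016-05-01", "I10", "ICD10"),
                ("e", "e-e1", "2016-05-01", "I10", "ICD10"),
                ("f", "f-e1", "2016-05-01", "I10", "ICD10"),
                ("f", "f-e1", "2016-05-01", "250.00", "ICD9"),
            ]
        )
        return demo, dx

    def test_included_and_reasons(self):
        demo, dx = self._tables()
        cohort = build_cohort(demo, dx)
        assert set(cohort.index[cohort["included"]]) == {"a", "b"}
        reasons = dict(cohort["exclusion_reasons"])
        assert reasons["c"] == ("age",)
        assert reasons["d"] == ("race",)
        assert reasons["e"] == ("bmi",)
        assert reasons["f"] == ("icd9",)
        assert reasons["g"] == ("no_icd10",)
        counts = exclusion_counts(cohort)
        assert counts == {"age": 1, "bmi": 1, "race": 1, "no_icd10": 1, "icd9": 1}

    def test_mean_bmi_over_multiple_rows(self):
        demo, dx = self._tables()
        cohort = build_cohort(demo, dx)
        assert cohort.loc["a", "mean_bmi"] == pytest.approx(26.0)

    def test_transactions_dedupe_and_filter(self):
        demo, dx = self._tables()
        cohort = build_cohort(demo, dx)
        txns = build_transactions(cohort, dx, default_filter())
        key_a = StratumKey("Caucasian", "middle_aged", "without_obesity")
        # E11.0 and E11.9 collapse to one E11; I10 kept.
        assert txns[key_a].transactions["a"] == frozenset({"E11", "I10"})

    def test_empty_transaction_still_in_denominator(self):
        demo = make_demographics([("a", "Caucasian", 50, 25.0), ("b", "Caucasian", 50, 25.0)])
        dx = make_diagnoses(
            [
                ("a", "a-e1", "2016-03-01", "E11", "ICD10"),
                ("b", "b-e1", "2016-03-01", "Z51.1", "ICD10"),  # ineligible chapter
            ]
        )
        cohort = build_cohort(demo, dx)
        txns = build_transactions(cohort, dx)
        ts = txns[StratumKey("Caucasian", "middle_aged", "without_obesity")]
        assert ts.n_patients == 2
        assert ts.transactions["b"] == frozenset()
        dropped = build_transactions(cohort, dx, drop_empty=True)
        assert dropped[StratumKey("Caucasian", "middle_aged", "without_obesity")].n_patients == 1

    def test_strata_partition_included_cohort(self, small_dataset, small_result):
        cohort = small_result.cohort
        total = sum(ts.n_patients for ts in small_result.transaction_sets.values())
        assert total == int(cohort["included"].sum())
        # disjoint patient sets across strata
        seen = set()
        for ts in small_result.transaction_sets.values():
            pids = set(ts.transactions)
            assert not (pids & seen)
            seen |= pids

    def test_transactions_sorted_and_duplicate_free(self, small_result):
        for ts in small_result.transaction_sets.values():
            for items in ts.transactions.values():
                as_list = sorted(items)
                assert len(as_list) == len(set(as_list))

    def test_cohort_summary_percentages(self):
        demo, dx = self._tables()
        summary = cohort_summary(build_cohort(demo, dx))
        assert summary["n_patients"].sum() == 2
        for band in summary["age_band"].unique():
            sub = summary[summary["age_band"] == band]
            assert sub["pct_of_age_cohort"].sum() == pytest.approx(100.0)
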