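"""Quarter calendar, ICD truncation, contact counting and the inclusion filter."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morbiq.core import (
    ExclusionTally,
    Quarter,
    StudyConfig,
    StudyWindow,
    age_in_year,
    classify_patients,
    count_contacts,
    filter_patients,
    read_cohort,
    read_events,
    to_quarter,
    truncate_icd,
)

from conftest import events_frame, roster_frame


class TestTruncateIcd:
    @pytest.mark.parametrize("raw, expected", [
        ("I10.90", "I10"),
        ("E11", "E11"),
        ("j45.1 ", "J45"),
        ("  m54.5", "M54"),
    ])
    def test_truncates_to_group_level(self, raw, expected):
        assert truncate_icd(raw) == expected

    @pytest.mark.parametrize("bad", ["", "  ", "I1", "a", None])
    def test_rejects_short_codes_naming_the_value(self, bad):
        with pytest.raises(ValueError):
            truncate_icd(bad)
        if bad not in ("", "  ", None):
            with pytest.raises(ValueError, match=repr(bad)):
                truncate_icd(bad)

    @given(st.text("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghij0123456789.",
                   min_size=3, max_size=10),
           st.sampled_from(["", " ", "  ", "\t"]),
           st.sampled_from(["", " ", " \n"]))
    def test_idempotent(self, token, lead, trail):
        once = truncate_icd(lead + token + trail)
        assert truncate_icd(once) == once


class TestQuarterCalendar:
    def test_window_endpoints_span_55_quarters(self):
        win = StudyWindow()
        assert win.n_quarters == 55
        assert win.study_ordinal(to_quarter(date(1994, 1, 1))) == 0
        assert win.study_ordinal(to_quarter(date(2007, 9, 30))) == 54

    @pytest.mark.parametrize("d, yq", [
        (date(2000, 3, 31), (2000, 1)),
        (date(2000, 4, 1), (2000, 2)),
        (date(1999, 12, 31), (1999, 4)),
    ])
    def test_month_to_quarter_boundaries(self, d, yq):
        assert to_quarter(d) == Quarter(*yq)

    @given(st.dates(min_value=date(1990, 1, 1), max_value=date(2010, 12, 31)))
    def test_any_date_shares_ordinal_with_quarter_first_day(self, d):
        q = to_quarter(d)
        assert to_quarter(q.first_day()).ordinal == q.ordinal

    def test_ordinal_roundtrip_and_ordering(self):
        q = Quarter(1997, 3)
        assert Quarter.from_ordinal(q.ordinal) == q
        assert Quarter(1997, 3) < Quarter(1998, 1)

    def test_invalid_quarter_rejected(self):
        with pytest.raises(ValueError):
            Quarter(1997, 5)


class TestCountContacts:
    def test_multiple_entries_on_one_date_count_once(self):
        ev = events_frame([
            ("a", "2001-05-02", "I10"),
            ("a", "2001-05-02", None),
            ("a", "2001-05-02", "E11"),
            ("a", "2001-06-01", None),
        ])
        assert count_contacts(ev, "a", 2001) == 2

    def test_year_without_entries_is_zero_but_unknown_patient_raises(self):
        ev = events_frame([("a", "2001-05-02", None)])
        assert count_contacts(ev, "a", 2002) == 0
        with pytest.raises(KeyError):
            count_contacts(ev, "zzz", 2001)

    def test_distinct_dates_identity(self):
        ev = events_frame([("a", f"2001-0{m}-01", None) for m in range(1, 6)])
        assert count_contacts(ev, "a", 2001) == 5

    def test_yearly_sum_equals_distinct_patient_date_pairs(self):
        rng = np.random.default_rng(5)
        rows = [("p%d" % rng.integers(3),
                 str(date(2000 + int(rng.integers(3)), int(rng.integers(1, 13)),
                          int(rng.integers(1, 28)))), None)
                for _ in range(200)]
        ev = events_frame(rows)
        total = sum(count_contacts(ev, p, y)
                    for p in ev["patient_id"].unique()
                    for y in range(2000, 2003))
        assert total == len(ev.drop_duplicates(["patient_id", "date"]))


class TestFilterPatients:
    def test_reasons_and_tally(self, tiny_cohort):
        roster, events = tiny_cohort
        reason = classify_patients(roster, events)
        assert reason["a"] == "valid"
        assert reason["b"] == "missing_diagnosis"
        assert reason["c"] == "single_quarter"
        assert reason["d"] == "missing_diagnosis"
        valid, tally = filter_patients(roster, events)
        assert list(valid) == ["a"]
        assert tally.as_dict() == {"n_raw": 4, "n_missing_diagnosis": 2,
                                   "n_single_quarter": 1, "n_valid": 1}

    def test_same_quarter_diagnoses_do_not_qualify(self):
        roster = roster_frame([("c", "f", "1970-01-01")])
        events = events_frame([("c", "1999-04-10", "J45"),
                               ("c", "1999-05-20", "E11")])
        _, tally = filter_patients(roster, events)
        assert tally.n_single_quarter == 1

    def test_any_diagnosis_suffices_not_same_code(self):
        # two quarters with *different* codes still qualify for inclusion
        roster = roster_frame([("a", "f", "1950-01-01")])
        events = events_frame([("a", "1995-02-01", "I10"),
                               ("a", "1996-08-15", "K52")])
        valid, _ = filter_patients(roster, events)
        assert list(valid) == ["a"]

    def test_looser_rule_accepts_active_quarters_without_diagnosis(self):
        roster = roster_frame([("a", "f", "1950-01-01")])
        events = events_frame([("a", "1995-02-01", "I10"),
                               ("a", "1996-08-15", None)])
        strict_valid, _ = filter_patients(roster, events)
        loose_valid, _ = filter_patients(roster, events,
                                         rule="any_two_active_quarters")
        assert list(strict_valid) == []
        assert list(loose_valid) == ["a"]

    def test_orphan_events_raise_listing_ids(self, tiny_cohort):
        roster, events = tiny_cohort
        bad = pd.concat([events, events_frame([("ghost", "1999-01-01", None)])])
        with pytest.raises(ValueError, match="ghost"):
            filter_patients(roster, bad)

    def test_order_independence_and_partition_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_pat = int(rng.integers(2, 15))
            roster = roster_frame([(f"p{i}", "f", "1950-01-01")
                                   for i in range(n_pat)])
            rows = []
            for _ in range(int(rng.integers(1, 60))):
                pid = f"p{rng.integers(n_pat)}"
                d = date(1994 + int(rng.integers(3)),
                         int(rng.integers(1, 13)), int(rng.integers(1, 28)))
                icd = None if rng.random() < 0.4 else f"I{rng.integers(10, 99)}"
                rows.append((pid, str(d), icd))
            events = events_frame(rows)
            valid1, tally1 = filter_patients(roster, events)
            shuffled = events.sample(frac=1, random_state=3).reset_index(drop=True)
            valid2, tally2 = filter_patients(roster, shuffled)
            assert sorted(valid1) == sorted(valid2)
            assert tally1 == tally2
            assert (tally1.n_missing_diagnosis + tally1.n_single_quarter
                    + tally1.n_valid == tally1.n_raw)

    def test_tally_rejects_broken_partition(self):
        with pytest.raises(ValueError):
            ExclusionTally(10, 3, 3, 3)
        with pytest.raises(ValueError):
            ExclusionTally(2, -1, 0, 3)


class TestReadCohort:
    def _write(self, tmp_path, events_text, patients_text):
        ep = tmp_path / "events.csv"
        pp = tmp_path / "patients.csv"
        ep.write_text(events_text)
        pp.write_text(patients_text)
        return ep, pp

    def test_wellformed_fixture_parses_and_truncates(self, tmp_path):
        ep, pp = self._write(
            tmp_path,
            "patient_id,date,icd_code\n"
            "a,1995-02-01,i10.90\n"
            "a,1996-08-15,\n"
            "b,1999-04-10,E11\n",
            "patient_id,gender,birth_date\na,f,1950-06-01\nb,m,1960-01-15\n")
        patients, events = read_cohort(ep, pp)
        assert len(events) == 3
        assert events["icd3"].tolist()[0] == "I10"
        assert pd.isna(events["icd3"].iloc[1])
        assert len(patients) == 2

    def test_two_character_icd_rejected_at_row(self, tmp_path):
        ep, pp = self._write(
            tmp_path,
            "patient_id,date,icd_code\na,1995-02-01,I10\na,1995-03-01,I1\n",
            "patient_id,gender,birth_date\na,f,1950-06-01\n")
        with pytest.raises(ValueError, match="line 3"):
            read_cohort(ep, pp)

    def test_out_of_window_row_dropped_and_counted(self, tmp_path):
        ep, _ = self._write(
            tmp_path,
            "patient_id,date,icd_code\na,1995-02-01,I10\na,2009-01-05,I10\n",
            "patient_id,gender,birth_date\na,f,1950-06-01\n")
        events = read_events(ep, StudyWindow())
        assert len(events) == 1
        assert events.attrs["n_dropped_window"] == 1

    def test_schema_and_date_errors(self, tmp_path):
        ep, pp = self._write(
            tmp_path,
            "patient_id,when\na,1995-02-01\n",
            "patient_id,gender,birth_date\na,f,1950-06-01\n")
        with pytest.raises(ValueError, match="date"):
            read_cohort(ep, pp)
        ep2 = tmp_path / "e2.csv"
        ep2.write_text("patient_id,date,icd_code\na,02/01/1995,I10\n")
        with pytest.raises(ValueError, match="unparseable"):
            read_cohort(ep2, pp)

    def test_event_before_birth_rejected(self, tmp_path):
        ep, pp = self._write(
            tmp_path,
            "patient_id,date,icd_code\na,1995-02-01,I10\n",
            "patient_id,gender,birth_date\na,f,1996-06-01\n")
        with pytest.raises(ValueError, match="before birth"):
            read_cohort(ep, pp)

    def test_unknown_gender_and_duplicate_id_rejected(self, tmp_path):
        ep, pp = self._write(
            tmp_path,
            "patient_id,date,icd_code\na,1995-02-01,I10\n",
            "patient_id,gender,birth_date\na,x,1950-06-01\n")
        with pytest.raises(ValueError, match="gender"):
            read_cohort(ep, pp)
        pp.write_text("patient_id,gender,birth_date\n"
                      "a,f,1950-06-01\na,f,1950-06-01\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(ep, pp)


class TestAge:
    def test_age_conventions(self):
        birth = pd.Series(pd.to_datetime(["1950-06-15"]))
        assert age_in_year(birth, 2000, at="year_end").iloc[0] == 50
        assert age_in_year(birth, 2000, at="year_start").iloc[0] == 49
        # birthday (June 15) precedes the mid-year reference date
        assert age_in_year(birth, 2000, at="midyear").iloc[0] == 50

    def test_config_validates_choices(self):
        with pytest.raises(ValueError):
            StudyConfig(age_at="birthday")
        with pytest.raises(ValueError):
            StudyConfig(inclusion_rule="whatever")
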