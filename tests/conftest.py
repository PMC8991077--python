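from datetime import date

import pandas as pd
import pytest


def events_frame(rows):
    """Build an internal-schema event frame from (patient_id, iso_date, icd3)
    triples; icd3 may be None for a contact-only entry."""
    df = pd.DataFrame(rows, columns=["patient_id", "date", "icd3"])
    df["date"] = pd.to_datetime(df["date"])
    df["icd3"] = df["icd3"].astype(object).where(df["icd3"].notna(), pd.NA)
    df["year"] = df["date"].dt.year
    df["ordinal"] = 4 * df["year"] + (df["date"].dt.month + 2) // 3 - 1
    return df


def roster_frame(rows):
    """Build a roster from (patient_id, gender, iso_birth_date) triples."""
    df = pd.DataFrame(rows, columns=["patient_id", "gender", "birth_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def presence_frame(cells):
    """Presence grid from (patient_id, icd3, quarter ordinal) triples."""
    return pd.DataFrame(cells, columns=["patient_id", "icd3", "ordinal"])


@pytest.fixture
def tiny_cohort():
    """Hand-written 4-patient cohort covering the filter's three outcomes."""
    roster = roster_frame([
        ("a", "f", "1950-06-01"),   # valid: diagnoses in two quarters
        ("b", "m", "1960-01-15"),   # contacts only -> missing_diagnosis
        ("c", "f", "1970-12-31"),   # all activity in 1999Q2 -> single_quarter
        ("d", "u", "1980-03-03"),   # no events at all -> missing_diagnosis
    ])
    events = events_frame([
        ("a", "1995-02-01", "I10"),
        ("a", "1995-02-01", None),
        ("a", "1996-08-15", "I10"),
        ("b", "1995-03-01", None),
        ("b", "1997-05-01", None),
        ("c", "1999-04-10", "J45"),
        ("c", "1999-05-20", "E11"),
    ])
    return roster, events
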