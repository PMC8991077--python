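"""Quarter-indexed EMR data model, cohort ingestion and the inclusion filter.

Ambulatory billing data from the German statutory health insurance (SHI)
system arrive as an event stream: one row per EMR entry, carrying a patient
identifier, a calendar date, and optionally an ICD-10 diagnosis. The SHI
accounting period is the annual quarter (3 months), which makes the quarter
the atomic time unit of everything downstream — chronicity detection,
multimorbidity classification and case construction all operate on a
quarter grid.

This module provides

* :class:`Quarter` / :func:`to_quarter` — the quarter calendar with a total
  ordering (``ordinal = 4*year + quarter - 1``);
* :func:`truncate_icd` — ICD-10 codes cut to their three-character group;
* :func:`read_cohort` — validated ingestion of the two delimited input
  files (``events.csv``, ``patients.csv``);
* :func:`count_contacts` — a contact is any *distinct* calendar date with
  at least one EMR entry (direct or indirect, e.g. phone or paperwork);
* :func:`filter_patients` — the patient inclusion rule (activity plus a
  diagnosis in at least two of the study quarters) with a full exclusion
  tally, the machine-readable flow chart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: gender codes accepted in patients.csv
GENDER_CODES = ("f", "m", "u")

MISSING_DIAGNOSIS = "missing_diagnosis"
SINGLE_QUARTER = "single_quarter"
VALID = "valid"

#: inclusion-rule identifiers (see :func:`filter_patients`)
RULE_DIAGNOSIS_QUARTERS = "diagnosis_in_two_quarters"
RULE_ANY_ACTIVE = "any_two_active_quarters"


@dataclass(frozen=True, order=True)
class Quarter:
    """One SHI accounting quarter, totally ordered by (year, quarter)."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not 1 <= self.quarter <= 4:
            raise ValueError(f"quarter must be 1..4, got {self.quarter}")

    @property
    def ordinal(self) -> int:
        """Absolute quarter index; differences equal elapsed quarters."""
        return 4 * self.year + self.quarter - 1

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "Quarter":
        return cls(ordinal // 4, ordinal % 4 + 1)

    def first_day(self) -> date:
        return date(self.year, 3 * (self.quarter - 1) + 1, 1)

    def __str__(self) -> str:  # e.g. "1994Q1"
        return f"{self.year}Q{self.quarter}"


def to_quarter(d: date) -> Quarter:
    """Map a calendar date to its annual quarter (month 1-3 -> Q1, ...)."""
    return Quarter(d.year, (d.month + 2) // 3)


def truncate_icd(raw_code: str) -> str:
    """Truncate an ICD-10 code to its three-character group level.

    Whitespace is stripped and the code upper-cased first. Codes shorter
    than three characters after cleaning are rejected — they cannot name an
    ICD group.
    """
    if raw_code is None:
        raise ValueError("ICD code is missing")
    code = str(raw_code).strip().upper()
    if len(code) < 3:
        raise ValueError(f"ICD code too short after cleaning: {raw_code!r}")
    return code[:3]


@dataclass(frozen=True)
class StudyWindow:
    """The observation window, spanning whole quarters.

    The default spans the 55 quarters from 1994Q1 through 2007Q3.
    """

    start: date = date(1994, 1, 1)
    end: date = date(2007, 9, 30)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must not be after window end")

    @property
    def first_quarter(self) -> Quarter:
        return to_quarter(self.start)

    @property
    def last_quarter(self) -> Quarter:
        return to_quarter(self.end)

    @property
    def n_quarters(self) -> int:
        return self.last_quarter.ordinal - self.first_quarter.ordinal + 1

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    def study_ordinal(self, q: Quarter) -> int:
        """Quarter index relative to the window start (first quarter = 0)."""
        o = q.ordinal - self.first_quarter.ordinal
        if not 0 <= o < self.n_quarters:
            raise ValueError(f"{q} lies outside the study window")
        return o


@dataclass
class ExclusionTally:
    """Flow-chart accounting of the patient inclusion filter.

    The three exclusion/retention counts partition the raw roster exactly:
    ``n_raw = n_missing_diagnosis + n_single_quarter + n_valid``.
    """

    n_raw: int
    n_missing_diagnosis: int
    n_single_quarter: int
    n_valid: int

    def __post_init__(self) -> None:
        counts = (self.n_raw, self.n_missing_diagnosis,
                  self.n_single_quarter, self.n_valid)
        if any(c < 0 for c in counts):
            raise ValueError("tally counts must be non-negative")
        if self.n_raw != (self.n_missing_diagnosis + self.n_single_quarter
                          + self.n_valid):
            raise ValueError("tally does not partition the roster")

    @property
    def n_excluded(self) -> int:
        return self.n_missing_diagnosis + self.n_single_quarter

    @property
    def pct_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_raw

    @property
    def pct_valid(self) -> float:
        return 100.0 * self.n_valid / self.n_raw

    @property
    def pct_missing_diagnosis(self) -> float:
        return 100.0 * self.n_missing_diagnosis / self.n_raw

    @property
    def pct_single_quarter(self) -> float:
        return 100.0 * self.n_single_quarter / self.n_raw

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_missing_diagnosis": self.n_missing_diagnosis,
            "n_single_quarter": self.n_single_quarter,
            "n_valid": self.n_valid,
        }


@dataclass(frozen=True)
class StudyConfig:
    """Analysis configuration.

    Parameters
    ----------
    window
        Study window; events outside it are dropped on ingest.
    inclusion_rule
        ``diagnosis_in_two_quarters`` (default): a patient is valid iff at
        least two distinct quarters each contain a diagnosis-bearing entry
        (such an entry is itself a contact on that date, so the
        contact-plus-diagnosis conjunction is implied).
        ``any_two_active_quarters``: looser reading — at least one diagnosis
        anywhere plus activity in at least two distinct quarters.
    age_at
        Reference date for the per-year age: ``year_end`` (default,
        equivalent to ``year − birth year``), ``year_start`` or ``midyear``.
    chronic_persist
        If true, a code that has once met the chronicity criterion counts
        as chronic at every later occurrence for that patient.
    chronic_code_allowlist
        Optional set of ICD-3 codes eligible for chronicity; ``None`` means
        every code is eligible.
    """

    window: StudyWindow = field(default_factory=StudyWindow)
    inclusion_rule: str = RULE_DIAGNOSIS_QUARTERS
    age_at: str = "year_end"
    chronic_persist: bool = False
    chronic_code_allowlist: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.inclusion_rule not in (RULE_DIAGNOSIS_QUARTERS, RULE_ANY_ACTIVE):
            raise ValueError(f"unknown inclusion_rule: {self.inclusion_rule!r}")
        if self.age_at not in ("year_start", "midyear", "year_end"):
            raise ValueError(f"unknown age_at: {self.age_at!r}")

    @classmethod
    def from_mapping(cls, m: dict) -> "StudyConfig":
        window = StudyWindow(
            start=_as_date(m.get("window_start", StudyWindow.start)),
            end=_as_date(m.get("window_end", StudyWindow.end)),
        )
        allow = m.get("chronic_code_allowlist")
        return cls(
            window=window,
            inclusion_rule=m.get("inclusion_rule", RULE_DIAGNOSIS_QUARTERS),
            age_at=m.get("age_at", "year_end"),
            chronic_persist=bool(m.get("chronic_persist", False)),
            chronic_code_allowlist=frozenset(allow) if allow else None,
        )


def _as_date(v) -> date:
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def load_config(path) -> dict:
    """Read a YAML config file with optional ``study``, ``models`` and
    ``cohort`` sections; returns the raw mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


# ---------------------------------------------------------------------------
# ingestion

EVENT_COLUMNS = ("patient_id", "date", "icd_code")
PATIENT_COLUMNS = ("patient_id", "gender", "birth_date")


def _parse_dates(s: pd.Series, what: str) -> pd.Series:
    try:
        return pd.to_datetime(s, format="%Y-%m-%d", errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable {what} date: {exc}") from exc


def read_events(path, window: StudyWindow) -> pd.DataFrame:
    """Read and validate ``events.csv``.

    Returns a frame with columns ``patient_id``, ``date`` (datetime),
    ``icd3`` (nullable string, already truncated/upper-cased), plus derived
    ``ordinal`` (absolute quarter index) and ``year``. Rows dated outside
    the study window are dropped; the drop count is logged and stored in
    ``df.attrs["n_dropped_window"]``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "icd_code"]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "icd_code" not in df.columns:
        df["icd_code"] = ""
    df["date"] = _parse_dates(df["date"], "event")

    icd = df["icd_code"].str.strip()
    short = icd.str.len().between(1, 2)
    if short.any():
        row = int(np.flatnonzero(short.to_numpy())[0]) + 2  # 1 header + 1-based
        raise ValueError(
            f"{path}: ICD code too short after cleaning at line {row}: "
            f"{df['icd_code'].iloc[row - 2]!r}"
        )
    df["icd3"] = icd.str.upper().str[:3].replace("", pd.NA)

    in_window = df["date"].between(pd.Timestamp(window.start),
                                   pd.Timestamp(window.end))
    n_dropped = int((~in_window).sum())
    if n_dropped:
        log.info("dropped %d event row(s) outside the study window", n_dropped)
    df = df.loc[in_window, ["patient_id", "date", "icd3"]].reset_index(drop=True)
    df["year"] = df["date"].dt.year
    df["ordinal"] = 4 * df["year"] + (df["date"].dt.month + 2) // 3 - 1
    df.attrs["n_dropped_window"] = n_dropped
    return df


def read_patients(path) -> pd.DataFrame:
    """Read and validate ``patients.csv`` (id, gender f|m|u, birth date)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path}: duplicate patient_id {dup!r}")
    bad = ~df["gender"].isin(GENDER_CODES)
    if bad.any():
        raise ValueError(
            f"{path}: invalid gender value(s) {sorted(df.loc[bad, 'gender'].unique())}; "
            f"expected one of {GENDER_CODES}"
        )
    df["birth_date"] = _parse_dates(df["birth_date"], "birth")
    return df[["patient_id", "gender", "birth_date"]]


def read_cohort(events_path, roster_path, config: StudyConfig | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the roster and event stream and cross-validate them.

    Raises on schema violations, events referencing unknown patients, and
    events dated before the patient's birth.
    """
    config = config or StudyConfig()
    patients = read_patients(roster_path)
    events = read_events(events_path, config.window)

    known = set(patients["patient_id"])
    orphans = sorted(set(events["patient_id"]) - known)
    if orphans:
        raise ValueError(f"events reference unknown patient id(s): {orphans[:10]}")

    first = events.groupby("patient_id")["date"].min()
    birth = patients.set_index("patient_id")["birth_date"]
    pre_birth = first < birth.reindex(first.index)
    if pre_birth.any():
        bad_ids = sorted(first.index[pre_birth])
        raise ValueError(f"event(s) dated before birth for patient(s): {bad_ids[:10]}")
    return patients, events


# ---------------------------------------------------------------------------
# contacts and the inclusion filter

def count_contacts(events: pd.DataFrame, patient_id: str, year: int) -> int:
    """Number of distinct contact dates for one patient in one year.

    Multiple EMR entries on one calendar date count once. A patient absent
    from the event stream altogether is unknown and raises ``KeyError``;
    a known patient with no entries in the requested year yields 0.
    """
    mask = events["patient_id"] == patient_id
    if not mask.any():
        raise KeyError(f"unknown patient: {patient_id!r}")
    sub = events.loc[mask & (events["year"] == year)]
    return int(sub["date"].nunique())


def contact_table(events: pd.DataFrame) -> pd.DataFrame:
    """Distinct (patient, date) pairs — one row per contact day."""
    ct = events.drop_duplicates(["patient_id", "date"])[
        ["patient_id", "date", "year", "ordinal"]]
    return ct.reset_index(drop=True)


def classify_patients(roster: pd.DataFrame, events: pd.DataFrame,
                      rule: str = RULE_DIAGNOSIS_QUARTERS) -> pd.Series:
    """Assign each roster patient ``valid`` or an exclusion reason.

    Precedence: a patient without any diagnosis-bearing entry is
    ``missing_diagnosis`` (such a patient can never satisfy the two-quarter
    diagnosis condition); otherwise a patient failing the two-quarter rule
    is ``single_quarter``.
    """
    if rule not in (RULE_DIAGNOSIS_QUARTERS, RULE_ANY_ACTIVE):
        raise ValueError(f"unknown inclusion rule: {rule!r}")
    known = set(roster["patient_id"])
    orphans = sorted(set(events["patient_id"]) - known)
    if orphans:
        raise ValueError(f"events reference unknown patient id(s): {orphans[:10]}")

    dx = events.dropna(subset=["icd3"])
    dx_quarters = dx.groupby("patient_id")["ordinal"].nunique()
    active_quarters = events.groupby("patient_id")["ordinal"].nunique()

    reason = pd.Series(VALID, index=pd.Index(roster["patient_id"], name="patient_id"))
    has_dx = dx_quarters.reindex(reason.index).fillna(0).astype(int)
    n_active = active_quarters.reindex(reason.index).fillna(0).astype(int)

    reason[has_dx == 0] = MISSING_DIAGNOSIS
    if rule == RULE_DIAGNOSIS_QUARTERS:
        fail = (has_dx > 0) & (has_dx < 2)
    else:
        fail = (has_dx > 0) & (n_active < 2)
    reason[fail] = SINGLE_QUARTER
    return reason


def filter_patients(roster: pd.DataFrame, events: pd.DataFrame,
                    rule: str = RULE_DIAGNOSIS_QUARTERS
                    ) -> tuple[pd.Index, ExclusionTally]:
    """Apply the inclusion filter; return valid patient ids and the tally."""
    reason = classify_patients(roster, events, rule)
    tally = ExclusionTally(
        n_raw=len(reason),
        n_missing_diagnosis=int((reason == MISSING_DIAGNOSIS).sum()),
        n_single_quarter=int((reason == SINGLE_QUARTER).sum()),
        n_valid=int((reason == VALID).sum()),
    )
    log.info("inclusion filter: %s", tally.as_dict())
    return reason.index[reason == VALID], tally


def age_in_year(birth_date: pd.Series, year, at: str = "year_end") -> pd.Series:
    """Completed age (integer years) of each patient in calendar year
    ``year``, at the configured reference date.

    ``year_end`` equals the simple ``year − birth year`` convention.
    """
    year = pd.Series(year, index=birth_date.index) if np.isscalar(year) else year
    by = birth_date.dt.year
    if at == "year_end":
        return (year - by).astype(int)
    if at == "year_start":
        ref_month, ref_day = 1, 1
    elif at == "midyear":
        ref_month, ref_day = 7, 1
    else:
        raise ValueError(f"unknown age_at: {at!r}")
    before = (birth_date.dt.month > ref_month) | (
        (birth_date.dt.month == ref_month) & (birth_date.dt.day > ref_day))
    return (year - by - before.astype(int)).astype(int)
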