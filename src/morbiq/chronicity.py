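"""The M2Q chronic-condition criterion at (patient, ICD-3, quarter) resolution.

Under SHI billing rules a diagnosis recorded in some quarter counts as a
*chronic condition* if the same three-character code was also recorded for
that patient in at least one of the three directly preceding quarters —
i.e. the code is billed in at least two quarters of a rolling 12-month
span ("M2Q"). Chronicity is therefore a per-quarter property of a
(patient, code) pair, derived purely from recurrence; no external disease
list is consulted (an optional allow-list can restrict eligibility).

Quarters before the study window are treated as unobserved-and-absent: no
left-censoring compensation, so a code can never be chronic in the very
first study quarter. This biases chronicity conservatively during a
patient's first three observed quarters.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .core import Quarter, StudyWindow

#: number of preceding quarters searched for a recurrence
LOOKBACK = 3


def quarter_code_presence(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse the event stream to the presence grid the M2Q rule reads.

    One row per distinct (patient_id, icd3, quarter ordinal) with at least
    one diagnosis-bearing entry; repeat recordings within a quarter carry
    no extra information.
    """
    dx = events.dropna(subset=["icd3"])
    grid = (dx[["patient_id", "icd3", "ordinal"]]
            .drop_duplicates()
            .sort_values(["patient_id", "icd3", "ordinal"])
            .reset_index(drop=True))
    return grid


def detect_chronic(presence: pd.DataFrame, patient_id: str, icd3: str,
                   quarter: Quarter, window: StudyWindow | None = None) -> bool:
    """Is ``icd3`` a chronic condition for this patient in this quarter?

    True iff the code is present in ``quarter`` and in at least one of the
    three directly preceding quarters. Raises if the quarter lies outside
    the study window.
    """
    window = window or StudyWindow()
    window.study_ordinal(quarter)  # raises outside the window
    cell = presence[(presence["patient_id"] == patient_id)
                    & (presence["icd3"] == icd3)]
    ords = set(cell["ordinal"])
    q = quarter.ordinal
    return q in ords and any(q - k in ords for k in range(1, LOOKBACK + 1))


def chronic_flags(presence: pd.DataFrame,
                  allowlist: Optional[Iterable[str]] = None,
                  persist: bool = False) -> pd.DataFrame:
    """Evaluate the M2Q rule at every cell of the presence grid.

    Returns the grid with an ``is_chronic`` column. Because a code present
    anywhere in the lookback window implies its *latest* previous presence
    is in the window, the rule reduces to a gap test on consecutive
    presences of the same (patient, code), which vectorises.

    Parameters
    ----------
    allowlist
        If given, only these ICD-3 codes are eligible for chronicity.
    persist
        If true, a code stays chronic at every later presence once the
        criterion has been met (chronicity, once earned, is carried along
        the record instead of being re-earned after long gaps).
    """
    grid = presence.sort_values(["patient_id", "icd3", "ordinal"]).copy()
    gap = grid.groupby(["patient_id", "icd3"], sort=False)["ordinal"].diff()
    grid["is_chronic"] = gap.le(LOOKBACK).fillna(False)
    if persist:
        grid["is_chronic"] = grid.groupby(
            ["patient_id", "icd3"], sort=False)["is_chronic"].cummax()
    if allowlist is not None:
        grid.loc[~grid["icd3"].isin(set(allowlist)), "is_chronic"] = False
    return grid.reset_index(drop=True)


def chronic_flags_for_patient(presence: pd.DataFrame, patient_id: str,
                              **kwargs) -> pd.DataFrame:
    """M2Q flags for every (code, quarter) presence of one patient."""
    if patient_id not in set(presence["patient_id"]):
        raise KeyError(f"unknown patient: {patient_id!r}")
    sub = presence[presence["patient_id"] == patient_id]
    return chronic_flags(sub, **kwargs)


def export_flags(flags: pd.DataFrame, path) -> None:
    """Debug export: patient_id, icd3, quarter label (yearQn), is_chronic."""
    out = flags.copy()
    out["quarter"] = [str(Quarter.from_ordinal(o)) for o in out["ordinal"]]
    out[["patient_id", "icd3", "quarter", "is_chronic"]].to_csv(path, index=False)
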