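"""Threshold multimorbidity models and the temporal-delimiter state logic.

A *case* is one patient in one calendar year with at least one practice
contact — the unit of analysis. Four models classify each case as
multimorbid or not, differing in the minimum number of distinct ICD-3
codes required and in whether any diagnosis counts or only chronic
conditions (codes meeting the M2Q criterion):

=======  =========  =================  ==========================
model    min count  condition scope    window
=======  =========  =================  ==========================
model1   2          any diagnosis      quarter
model2   3          any diagnosis      quarter
model3   2          chronic condition  quarter
model4   3          chronic condition  quarter
=======  =========  =================  ==========================

Each model is evaluated under two temporal readings:

* ``annual`` (with a time delimiter): a case is multimorbid iff the
  criterion is met at least once within that calendar year;
* ``propagated`` (without a delimiter, "no way back"): once a patient has
  met the criterion in any observed year, every later observed year is
  multimorbid too — a cumulative OR over the patient's case years. Years
  without contacts generate no case and neither carry nor reset state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .core import StudyConfig, age_in_year, contact_table

SCOPE_ANY = "any_diagnosis"
SCOPE_CHRONIC = "chronic_condition"
MODE_ANNUAL = "annual"
MODE_PROPAGATED = "propagated"
MODES = (MODE_ANNUAL, MODE_PROPAGATED)


@dataclass(frozen=True)
class ModelSpec:
    """One multimorbidity definition: at least ``min_count`` distinct
    qualifying codes within the evaluation window."""

    name: str
    min_count: int
    scope: str = SCOPE_ANY
    window: str = "quarter"

    def __post_init__(self) -> None:
        if self.min_count < 2:
            raise ValueError(
                f"{self.name}: multimorbidity needs min_count >= 2, "
                f"got {self.min_count}")
        if self.scope not in (SCOPE_ANY, SCOPE_CHRONIC):
            raise ValueError(f"{self.name}: unknown scope {self.scope!r}")
        if self.window not in ("quarter", "year"):
            raise ValueError(f"{self.name}: unknown window {self.window!r}")


DEFAULT_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("model1", 2, SCOPE_ANY),
    ModelSpec("model2", 3, SCOPE_ANY),
    ModelSpec("model3", 2, SCOPE_CHRONIC),
    ModelSpec("model4", 3, SCOPE_CHRONIC),
)


def models_from_config(items: Sequence[Mapping]) -> tuple[ModelSpec, ...]:
    """Build the model family from a config ``models`` section."""
    specs = tuple(
        ModelSpec(d["name"], int(d["min_count"]),
                  d.get("scope", SCOPE_ANY), d.get("window", "quarter"))
        for d in items)
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("model names must be unique")
    return specs


def meets_model(codes_by_quarter: Mapping[int, Set[str]],
                chronic_by_quarter: Mapping[int, Set[str]],
                spec: ModelSpec) -> bool:
    """Does one patient-year meet a model's criterion?

    ``codes_by_quarter`` / ``chronic_by_quarter`` map quarter ordinals of
    the year to the distinct codes present / chronic there. With
    ``window='quarter'`` some single quarter must hold ``min_count``
    qualifying codes; with ``window='year'`` the quarters are pooled (a
    code qualifies as chronic if chronic in at least one quarter).
    """
    if spec.window == "quarter":
        for q, codes in codes_by_quarter.items():
            qual = codes if spec.scope == SCOPE_ANY else (
                set(codes) & set(chronic_by_quarter.get(q, ())))
            if len(qual) >= spec.min_count:
                return True
        return False
    pooled: set = set()
    if spec.scope == SCOPE_ANY:
        for codes in codes_by_quarter.values():
            pooled |= set(codes)
    else:
        for codes in chronic_by_quarter.values():
            pooled |= set(codes)
    return len(pooled) >= spec.min_count


def _year_counts(flags: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, year): the four counting statistics the models read.

    ``qmax_any``/``qmax_chronic`` — the best single quarter's distinct
    (chronic) code count; ``ytot_any``/``ytot_chronic`` — distinct codes
    pooled over the year (chronic: chronic in >=1 quarter of the year).
    """
    f = flags.copy()
    f["year"] = f["ordinal"] // 4
    per_q = f.groupby(["patient_id", "year", "ordinal"]).agg(
        n_any=("icd3", "size"), n_chronic=("is_chronic", "sum"))
    qmax = per_q.groupby(["patient_id", "year"]).max()
    ytot_any = f.groupby(["patient_id", "year"])["icd3"].nunique()
    ytot_chr = (f[f["is_chronic"]]
                .groupby(["patient_id", "year"])["icd3"].nunique())
    out = pd.DataFrame({
        "qmax_any": qmax["n_any"],
        "qmax_chronic": qmax["n_chronic"],
        "ytot_any": ytot_any,
        "ytot_chronic": ytot_chr,
    }).fillna(0).astype(int)
    return out


_STAT_COLUMN = {
    (SCOPE_ANY, "quarter"): "qmax_any",
    (SCOPE_CHRONIC, "quarter"): "qmax_chronic",
    (SCOPE_ANY, "year"): "ytot_any",
    (SCOPE_CHRONIC, "year"): "ytot_chronic",
}


def annual_flags(flags: pd.DataFrame, case_index: pd.MultiIndex,
                 specs: Sequence[ModelSpec]) -> pd.DataFrame:
    """Time-delimiter (annual) multimorbidity flags for every case.

    ``flags`` is the chronicity-annotated presence grid; ``case_index`` the
    (patient_id, year) index of cases. Case years without any diagnosis
    count zero everywhere and are never multimorbid.
    """
    counts = _year_counts(flags).reindex(case_index, fill_value=0)
    out = pd.DataFrame(index=case_index)
    for spec in specs:
        col = _STAT_COLUMN[(spec.scope, spec.window)]
        out[spec.name] = counts[col] >= spec.min_count
    return out


def propagate_flags(annual: pd.DataFrame) -> pd.DataFrame:
    """Apply the "no way back" rule: cumulative OR over each patient's
    observed case years, in year order."""
    ordered = annual.sort_index()
    return ordered.groupby(level="patient_id", sort=False).cummax()


def build_cases(patients: pd.DataFrame, events: pd.DataFrame,
                flags: pd.DataFrame, specs: Sequence[ModelSpec] = DEFAULT_MODELS,
                config: StudyConfig | None = None,
                valid_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Assemble the analysis-ready case table.

    One row per (patient, calendar year with >=1 contact), with age,
    gender, contact count, distinct-diagnosis count, and one boolean
    column per model x delimiter mode (``<model>_annual``,
    ``<model>_propagated``).
    """
    config = config or StudyConfig()
    if valid_ids is not None:
        valid = set(valid_ids)
        patients = patients[patients["patient_id"].isin(valid)]
        events = events[events["patient_id"].isin(valid)]
        flags = flags[flags["patient_id"].isin(valid)]

    contacts = contact_table(events)
    n_contacts = contacts.groupby(["patient_id", "year"]).size()
    n_contacts.name = "n_contacts"
    case_index = n_contacts.index

    ann = annual_flags(flags, case_index, specs)
    prop = propagate_flags(ann)

    dx = events.dropna(subset=["icd3"])
    n_codes = (dx.groupby(["patient_id", "year"])["icd3"].nunique()
               .reindex(case_index, fill_value=0))

    cases = pd.DataFrame({"n_contacts": n_contacts, "n_codes": n_codes})
    cases = cases.join(ann.add_suffix("_annual"))
    cases = cases.join(prop.add_suffix("_propagated"))
    cases = cases.reset_index()

    meta = patients.set_index("patient_id")
    cases["gender"] = cases["patient_id"].map(meta["gender"])
    birth = cases["patient_id"].map(meta["birth_date"])
    cases["age"] = age_in_year(birth, cases["year"], at=config.age_at)

    front = ["patient_id", "year", "age", "gender", "n_contacts", "n_codes"]
    flag_cols = [f"{s.name}_{m}" for s in specs for m in MODES]
    cases = cases[front + flag_cols]
    return cases
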