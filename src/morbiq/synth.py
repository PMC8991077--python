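"""Seeded generator of SHI-style EMR cohorts with known ground truth.

The generator emulates the statistical structure a quarter-billed
primary-care record carries, while keeping the *truth* separate from its
*recording*:

* each patient owns a latent set of chronic conditions, acquired at some
  quarter and active for life — only their recording per quarter is
  stochastic (probability ``chronic_recurrence``, forced at acquisition);
* acute one-off diagnoses arrive as a per-quarter Poisson stream;
* contact days (distinct calendar dates with an EMR entry) are drawn per
  quarter with intensity ``contact_base + contact_per_dx × recorded
  diagnoses``, coupling workload to morbidity burden;
* designated fractions of patients are emitted with no diagnoses at all or
  with all activity inside a single quarter, to exercise the inclusion
  filter's two exclusion arms.

The separation of truth from recording is exactly the gap the M2Q
recurrence rule has to bridge, and :func:`truth_prevalence` provides the
recovery target the pipeline is judged against: with recurrence 1.0 every
acquired code is visible every quarter and the detector can only lag truth
by the single quarter a first occurrence needs; with lower recurrence the
detector undershoots (recording gaps plus left-censoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import Quarter, StudyWindow
from .models import ModelSpec, SCOPE_ANY

_AGE_CAP = (0.0, 105.0)


class CohortConfig(BaseModel):
    """Generator parameters. Defaults describe a mixed primary-care panel:
    mean age 49 (SD 23.6) at window end, 54% female, an acute-heavy
    diagnosis mix with a minority of accumulating chronic conditions, and
    exclusion strata sized like a raw practice roster (28.7% without any
    diagnosis, 26.7% active in a single quarter)."""

    n_patients: int = Field(gt=0)
    seed: int = 0
    window_start: date = date(1994, 1, 1)
    window_end: date = date(2007, 9, 30)

    age_mean: float = 49.0
    age_sd: float = Field(default=23.6, gt=0)
    female_fraction: float = Field(default=0.54, ge=0, le=1)

    n_chronic_codes: int = Field(default=40, gt=0)
    chronic_acquisition_rate: float = Field(default=0.18, ge=0, le=1)
    chronic_age_coeff: float = Field(default=0.5, ge=0)
    chronic_recurrence: float = Field(default=0.6, ge=0, le=1)

    acute_rate: float = Field(default=0.6, ge=0)
    n_acute_codes: int = Field(default=80, gt=0)

    contact_base: float = Field(default=0.55, ge=0)
    contact_per_dx: float = Field(default=1.0, ge=0)

    missing_diagnosis_fraction: float = Field(default=0.287, ge=0, le=1)
    single_quarter_fraction: float = Field(default=0.267, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if self.missing_diagnosis_fraction + self.single_quarter_fraction > 1:
            raise ValueError("exclusion-stratum fractions must sum to <= 1")
        if self.window_start > self.window_end:
            raise ValueError("window_start must not be after window_end")
        return self

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.window_start, self.window_end)


@dataclass
class GroundTruth:
    """Latent state behind a generated cohort.

    ``acquisitions`` — one row per truly chronic (patient, code) with its
    acquisition quarter (absolute ordinal); active for life thereafter.
    ``acute`` — every one-off diagnosis with its quarter.
    ``spans`` — per patient: observation span (absolute quarter ordinals)
    and stratum (``normal`` / ``missing_diagnosis`` / ``single_quarter``;
    the designated exclusion strata carry no chronic truth).
    """

    acquisitions: pd.DataFrame
    acute: pd.DataFrame
    spans: pd.DataFrame
    window: StudyWindow


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame  # internal schema: patient_id, gender, birth_date
    events: pd.DataFrame    # internal schema: patient_id, date, icd3, year, ordinal
    truth: GroundTruth
    config: CohortConfig

    def write(self, outdir) -> dict[str, Path]:
        """Serialize to ``patients.csv`` / ``events.csv`` (the ingestion
        schemas) plus ``ground_truth.csv``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": outdir / "patients.csv",
            "events": outdir / "events.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        pat = self.patients.copy()
        pat["birth_date"] = pat["birth_date"].dt.strftime("%Y-%m-%d")
        pat.to_csv(paths["patients"], index=False)

        ev = self.events[["patient_id", "date", "icd3"]].copy()
        ev["date"] = ev["date"].dt.strftime("%Y-%m-%d")
        ev = ev.rename(columns={"icd3": "icd_code"})
        ev["icd_code"] = ev["icd_code"].fillna("")
        ev.to_csv(paths["events"], index=False)

        gt = self.truth.acquisitions.copy()
        gt["acquired"] = [str(Quarter.from_ordinal(o)) for o in gt["ordinal"]]
        gt[["patient_id", "icd3", "acquired"]].to_csv(
            paths["ground_truth"], index=False)
        return paths


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection-sample a truncated normal (exact, rng-deterministic)."""
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _days_in_quarter(q: Quarter) -> int:
    nxt = Quarter.from_ordinal(q.ordinal + 1).first_day()
    return (np.datetime64(nxt) - np.datetime64(q.first_day())).astype(int)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; same config (including seed) → identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    win = config.window
    nq = win.n_quarters
    base_ord = win.first_quarter.ordinal

    ids = np.array([f"p{i:05d}" for i in range(n)])

    # --- demographics -----------------------------------------------------
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *_AGE_CAP, n)
    gender = np.where(rng.random(n) < config.female_fraction, "f", "m")
    offset_days = age * 365.25 + rng.uniform(0, 365.25, n)
    end64 = np.datetime64(config.window_end)
    birth = end64 - offset_days.astype("timedelta64[D]")

    # --- strata and observation spans (study-ordinal units) ---------------
    u = rng.random(n)
    md_frac = config.missing_diagnosis_fraction
    sq_frac = config.single_quarter_fraction
    category = np.where(u < md_frac, "missing_diagnosis",
                        np.where(u < md_frac + sq_frac,
                                 "single_quarter", "normal"))
    span_hi = max(nq - 8, 1)  # multi-year panels enter with >=2 years left
    entry = rng.integers(0, span_hi, n)
    entry_sq = rng.integers(0, nq, n)
    entry = np.where(category == "single_quarter", entry_sq, entry)
    # nobody is observed before the quarter after birth
    birth_q = (4 * birth.astype("datetime64[Y]").astype(int) + 1970 * 4
               + (birth.astype("datetime64[M]").astype(int) % 12) // 3)
    entry_min = np.maximum(birth_q + 1 - base_ord, 0)
    entry = np.maximum(entry, entry_min)
    exit_ = np.where(category == "single_quarter", entry, nq - 1)

    # --- chronic acquisitions (normal stratum only) -----------------------
    p_acq = np.clip(config.chronic_acquisition_rate
                    * (1 + config.chronic_age_coeff
                       * (age - config.age_mean) / config.age_sd),
                    0.0, 0.9)
    n_owned = np.zeros(n, dtype=int)
    first_code = rng.integers(0, config.n_chronic_codes, n)
    acq_pid, acq_code, acq_q = [], [], []
    for year in range(win.start.year, win.end.year + 1):
        y_lo = 4 * year - base_ord
        y_hi = min(y_lo + 3, nq - 1)
        lo = np.maximum(entry, max(y_lo, 0))
        hi = np.minimum(exit_, y_hi)
        eligible = ((category == "normal") & (lo <= hi)
                    & (n_owned < config.n_chronic_codes))
        drawn = eligible & (rng.random(n) < p_acq)
        idx = np.flatnonzero(drawn)
        if idx.size:
            code = (first_code[idx] + n_owned[idx]) % config.n_chronic_codes
            q = lo[idx] + (rng.random(idx.size)
                           * (hi[idx] - lo[idx] + 1)).astype(int)
            acq_pid.append(idx)
            acq_code.append(code)
            acq_q.append(q)
            n_owned[idx] += 1
    if acq_pid:
        acq_pid = np.concatenate(acq_pid)
        acq_code = np.concatenate(acq_code)
        acq_q = np.concatenate(acq_q)
    else:
        acq_pid = np.empty(0, int)
        acq_code = np.empty(0, int)
        acq_q = np.empty(0, int)

    # --- quarter-by-quarter event emission --------------------------------
    ev_pid, ev_date, ev_code = [], [], []
    ac_pid_all, ac_q_all, ac_code_all = [], [], []
    no_dx = category == "missing_diagnosis"
    for s in range(nq):
        active = (entry <= s) & (exit_ >= s)
        if not active.any():
            continue
        quarter = Quarter.from_ordinal(base_ord + s)
        d = _days_in_quarter(quarter)
        q_start = np.datetime64(quarter.first_day())

        # recorded chronic codes: forced at acquisition, Bernoulli after
        live = acq_q <= s
        rec = live & ((acq_q == s)
                      | (rng.random(acq_q.size) < config.chronic_recurrence))
        ch_pid = acq_pid[rec]
        ch_code = acq_code[rec]

        # acute one-off codes; the single-quarter stratum always records at
        # least one diagnosis so it exercises that exclusion arm (a patient
        # with no diagnosis at all falls under missing-diagnosis precedence)
        lam_ac = np.where(active & ~no_dx, config.acute_rate, 0.0)
        n_ac = rng.poisson(lam_ac)
        force_dx = active & (category == "single_quarter")
        n_ac = np.maximum(n_ac, force_dx.astype(int))
        ac_pid = np.repeat(np.arange(n), n_ac)
        ac_code = rng.integers(0, config.n_acute_codes, ac_pid.size)
        ac_pid_all.append(ac_pid)
        ac_q_all.append(np.full(ac_pid.size, base_ord + s))
        ac_code_all.append(ac_code)

        # contact days
        n_dx = (np.bincount(ch_pid, minlength=n)
                + np.bincount(ac_pid, minlength=n))
        lam_days = np.where(active,
                            config.contact_base
                            + config.contact_per_dx * n_dx, 0.0)
        n_days = rng.poisson(lam_days)
        n_days = np.maximum(n_days, (n_dx > 0).astype(int))
        n_days = np.minimum(n_days, d)
        sub = np.flatnonzero(n_days > 0)
        if sub.size == 0:
            continue
        k = n_days[sub]
        order = np.argsort(rng.random((sub.size, d)), axis=1)
        pick = np.arange(d)[None, :] < k[:, None]
        offs = order[pick]  # row-major: first k offsets of each row
        starts = np.concatenate([[0], np.cumsum(k)])
        inv = np.full(n, -1)
        inv[sub] = np.arange(sub.size)

        ev_pid.append(np.repeat(sub, k))
        ev_date.append(q_start + offs.astype("timedelta64[D]"))
        ev_code.append(np.full(offs.size, -1))

        # attach each diagnosis to one of its patient's contact days
        dx_pid = np.concatenate([ch_pid, ac_pid])
        dx_code = np.concatenate([ch_code, ac_code + config.n_chronic_codes])
        if dx_pid.size:
            rows = inv[dx_pid]
            kk = k[rows]
            j = (rng.random(dx_pid.size) * kk).astype(int)
            dx_off = offs[starts[rows] + j]
            ev_pid.append(dx_pid)
            ev_date.append(q_start + dx_off.astype("timedelta64[D]"))
            ev_code.append(dx_code)

    pid = np.concatenate(ev_pid) if ev_pid else np.empty(0, int)
    dates = np.concatenate(ev_date) if ev_date else np.empty(0, "datetime64[D]")
    codes = np.concatenate(ev_code) if ev_code else np.empty(0, int)

    chronic_labels = np.array(
        [f"C{i:02d}" for i in range(config.n_chronic_codes)])
    acute_labels = np.array([f"A{i:02d}" for i in range(config.n_acute_codes)])
    labels = np.concatenate([chronic_labels, acute_labels, [""]])
    icd3 = pd.Series(labels[codes]).replace("", pd.NA)

    events = pd.DataFrame({
        "patient_id": ids[pid],
        "date": pd.to_datetime(dates),
        "icd3": icd3.astype(object),
    })
    events = events.sort_values(["patient_id", "date", "icd3"],
                                kind="stable", na_position="first")
    events = events.reset_index(drop=True)
    events["year"] = events["date"].dt.year
    events["ordinal"] = (4 * events["year"]
                         + (events["date"].dt.month + 2) // 3 - 1)

    patients = pd.DataFrame({
        "patient_id": ids,
        "gender": gender,
        "birth_date": pd.to_datetime(birth),
    })

    acq_frame = pd.DataFrame({
        "patient_id": ids[acq_pid],
        "icd3": chronic_labels[acq_code],
        "ordinal": acq_q + base_ord,
    }).sort_values(["patient_id", "ordinal", "icd3"]).reset_index(drop=True)
    if ac_pid_all:
        ac_pid_cat = np.concatenate(ac_pid_all)
        acute_frame = pd.DataFrame({
            "patient_id": ids[ac_pid_cat],
            "ordinal": np.concatenate(ac_q_all),
            "icd3": acute_labels[np.concatenate(ac_code_all)],
        }).sort_values(["patient_id", "ordinal", "icd3"]).reset_index(drop=True)
    else:
        acute_frame = pd.DataFrame(columns=["patient_id", "ordinal", "icd3"])
    spans = pd.DataFrame({
        "patient_id": ids,
        "entry": entry + base_ord,
        "exit": exit_ + base_ord,
        "category": category,
    })
    truth = GroundTruth(acq_frame, acute_frame, spans, win)
    return SyntheticCohort(patients, events, truth, config)


# ---------------------------------------------------------------------------
# ground-truth summaries

def truth_year_counts(truth: GroundTruth) -> pd.DataFrame:
    """True per-(patient, year) condition counts over observed quarters.

    A chronic code is truly active in every quarter from acquisition
    onward; an acute code only in its quarter. Columns mirror the model
    counting statistics: best single quarter (``qmax_*``) and pooled over
    the year (``ytot_*``), for the any-diagnosis and chronic scopes.
    """
    spans = truth.spans
    lengths = np.clip((spans["exit"] - spans["entry"] + 1).to_numpy(), 0, None)
    pid = np.repeat(spans["patient_id"].to_numpy(), lengths)
    ordinal = np.concatenate([np.arange(a, b + 1) for a, b in
                              zip(spans["entry"], spans["exit"])]) \
        if len(spans) else np.empty(0, int)
    grid = pd.DataFrame({"patient_id": pid, "ordinal": ordinal})
    grid = grid.sort_values(["patient_id", "ordinal"], kind="stable")

    acq_at = (truth.acquisitions.groupby(["patient_id", "ordinal"])
              .size().rename("n_new"))
    grid = grid.join(acq_at, on=["patient_id", "ordinal"])
    grid["n_new"] = grid["n_new"].fillna(0)
    grid["n_chronic"] = grid.groupby("patient_id")["n_new"].cumsum().astype(int)

    ac = (truth.acute.drop_duplicates()
          .groupby(["patient_id", "ordinal"]).size().rename("n_acute"))
    grid = grid.join(ac, on=["patient_id", "ordinal"])
    grid["n_acute"] = grid["n_acute"].fillna(0).astype(int)
    grid["n_any"] = grid["n_chronic"] + grid["n_acute"]
    grid["year"] = grid["ordinal"] // 4

    per_year = grid.groupby(["patient_id", "year"]).agg(
        qmax_chronic=("n_chronic", "max"),
        qmax_any=("n_any", "max"))
    ac_year = (truth.acute.drop_duplicates()
               .assign(year=lambda f: f["ordinal"] // 4)
               .groupby(["patient_id", "year"])["icd3"].nunique())
    per_year["ytot_chronic"] = per_year["qmax_chronic"]
    per_year["ytot_any"] = (per_year["qmax_chronic"]
                            + ac_year.reindex(per_year.index, fill_value=0))
    return per_year.astype(int)


_TRUTH_COLUMN = {
    (SCOPE_ANY, "quarter"): "qmax_any",
    (SCOPE_ANY, "year"): "ytot_any",
    ("chronic_condition", "quarter"): "qmax_chronic",
    ("chronic_condition", "year"): "ytot_chronic",
}


def truth_prevalence(truth: GroundTruth, spec: ModelSpec,
                     by_year: bool = False, case_index=None):
    """Prevalence computed from latent condition counts, bypassing the M2Q
    detector — the recovery target for the pipeline.

    By default the denominator is every observed patient-year of the
    ``normal`` stratum; pass the pipeline's case index to evaluate both
    routes over exactly the same patient-years.
    """
    counts = truth_year_counts(truth)
    flags = counts[_TRUTH_COLUMN[(spec.scope, spec.window)]] >= spec.min_count
    if case_index is not None:
        flags = flags.reindex(case_index, fill_value=False)
    else:
        normal = set(truth.spans.loc[truth.spans["category"] == "normal",
                                     "patient_id"])
        flags = flags[flags.index.get_level_values(0).isin(normal)]
    if len(flags) == 0:
        raise ValueError("no patient-years to evaluate")
    if by_year:
        return flags.groupby(level="year").mean() * 100.0
    return 100.0 * float(flags.mean())
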