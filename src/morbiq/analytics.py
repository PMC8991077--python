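"""Descriptive statistics over the case table.

Prevalence is case-based: the denominator is patient-years, not patients.
Contact burden is summarised per group with mean, SD (sample, n−1),
median and IQR (linear interpolation between order statistics). The
association between the dichotomous multimorbidity flags and continuous
variables (age, annual contacts) is the point-biserial correlation

    r_pb = (M1 − M0) / s_n · sqrt(n1·n0 / n²)

with s_n the population (n-denominator) SD — algebraically identical to
the Pearson product-moment coefficient on a 0/1 coding of the flag.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import MODES, DEFAULT_MODELS, ModelSpec


def prevalence(cases: pd.DataFrame, model: str, mode: str = "annual",
               by_year: bool = False):
    """Percent of cases flagged multimorbid under ``model`` × ``mode``.

    Returns a float, or a per-year Series when ``by_year`` is true.
    An empty case set has no defined proportion and raises.
    """
    col = _flag_column(cases, model, mode)
    if len(cases) == 0:
        raise ValueError("prevalence undefined on an empty case set")
    if by_year:
        return cases.groupby("year")[col].mean() * 100.0
    return 100.0 * float(cases[col].mean())


def prevalence_cluster_se(cases: pd.DataFrame, model: str,
                          mode: str = "annual") -> float:
    """Patient-clustered standard error of the case-level prevalence, in
    percentage points.

    Case-years of one patient are strongly dependent (flags persist, and
    always persist under propagation), so the independent Monte-Carlo
    replicate is the patient. Taylor-linearisation estimator for a
    cluster-correlated mean.
    """
    col = _flag_column(cases, model, mode)
    per = cases.groupby("patient_id")[col].agg(["sum", "size"])
    m_total = per["size"].sum()
    p = per["sum"].sum() / m_total
    resid = per["sum"] - p * per["size"]
    g = len(per)
    if g < 2:
        raise ValueError("need at least two patients for a clustered SE")
    var = g / (g - 1) * float((resid ** 2).sum()) / m_total ** 2
    return 100.0 * float(np.sqrt(var))


def _flag_column(cases: pd.DataFrame, model: str, mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"unknown delimiter mode: {mode!r}")
    col = f"{model}_{mode}"
    if col not in cases.columns:
        raise KeyError(f"case table has no flag column {col!r}")
    return col


def summarize(values: pd.Series) -> dict:
    """n, mean, SD (n−1), median, IQR and range of one numeric vector."""
    v = pd.Series(values).astype(float)
    q25, q75 = v.quantile([0.25, 0.75], interpolation="linear")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(v.median()),
        "q25": float(q25),
        "q75": float(q75),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def contact_summary(cases: pd.DataFrame, group_by: str | None = None
                    ) -> pd.DataFrame:
    """Contact-count summary per stratum.

    ``group_by`` may be ``None`` (whole table), ``"gender"`` (only the
    female/male strata are reported), or the name of a flag column such as
    ``"model1_annual"``. Empty strata are simply absent from the result.
    """
    if group_by is None:
        return pd.DataFrame([summarize(cases["n_contacts"])], index=["all"])
    sub = cases
    if group_by == "gender":
        sub = cases[cases["gender"].isin(["f", "m"])]
    rows = {name: summarize(grp["n_contacts"])
            for name, grp in sub.groupby(group_by, observed=True)
            if len(grp) > 0}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = group_by
    return out


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; rejects degenerate input
    (length < 3 or zero variance) instead of returning NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def point_biserial(flag, y) -> float:
    """Point-biserial correlation between a boolean vector and a numeric
    vector, from the group-mean formula (see module docstring)."""
    flag = np.asarray(flag, dtype=bool)
    y = np.asarray(y, dtype=float)
    if flag.shape != y.shape or flag.ndim != 1:
        raise ValueError("flag and y must be equal-length 1-d vectors")
    n = y.size
    n1 = int(flag.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both flag groups must be non-empty")
    s = float(y.std(ddof=0))
    if s == 0:
        raise ValueError("correlation undefined for zero-variance y")
    m1 = float(y[flag].mean())
    m0 = float(y[~flag].mean())
    return (m1 - m0) / s * np.sqrt(n1 * n0 / n ** 2)


# ---------------------------------------------------------------------------
# the full report

def table2_report(cases: pd.DataFrame,
                  specs: Sequence[ModelSpec] = DEFAULT_MODELS
                  ) -> dict[str, pd.DataFrame]:
    """Assemble the study's summary outputs as data frames.

    Returns a mapping with keys

    * ``overall`` — case count and contact summaries, total and by gender;
    * ``prevalence`` — percent multimorbid per model × delimiter mode;
    * ``table2`` — per model × mode × (multimorbid / not): case count,
      percent female, age and contact summaries;
    * ``correlations`` — Pearson r between age and contacts, plus
      point-biserial r between each flag and age / contacts.
    """
    if len(cases) == 0:
        raise ValueError("empty case table")

    overall = contact_summary(cases).assign(group="all")
    by_gender = contact_summary(cases, "gender").reset_index().rename(
        columns={"gender": "group"})
    overall = pd.concat([overall.reset_index(drop=True), by_gender],
                        ignore_index=True)

    prev_rows, t2_rows, corr_rows = [], [], []
    corr_rows.append({"variables": "age~contacts", "model": "all",
                      "mode": "all",
                      "r": pearson_r(cases["age"], cases["n_contacts"])})
    for spec in specs:
        for mode in MODES:
            col = f"{spec.name}_{mode}"
            flagged = cases[col]
            prev_rows.append({
                "model": spec.name, "mode": mode,
                "n_cases": len(cases), "n_multimorbid": int(flagged.sum()),
                "percent": 100.0 * float(flagged.mean()),
            })
            for is_mm, grp in cases.groupby(col):
                gender = grp["gender"]
                n_fm = int(gender.isin(["f", "m"]).sum())
                t2_rows.append({
                    "model": spec.name, "mode": mode,
                    "group": "multimorbid" if is_mm else "non_multimorbid",
                    "n_cases": len(grp),
                    "pct_female": (100.0 * float((gender == "f").sum()) / n_fm
                                   if n_fm else np.nan),
                    "age_mean": float(grp["age"].mean()),
                    "age_sd": float(grp["age"].std(ddof=1)) if len(grp) > 1 else 0.0,
                    "contacts_mean": float(grp["n_contacts"].mean()),
                    "contacts_sd": (float(grp["n_contacts"].std(ddof=1))
                                    if len(grp) > 1 else 0.0),
                    "contacts_median": float(grp["n_contacts"].median()),
                    "contacts_q25": float(grp["n_contacts"].quantile(0.25)),
                    "contacts_q75": float(grp["n_contacts"].quantile(0.75)),
                })
            if 0 < int(flagged.sum()) < len(cases):
                corr_rows.append({"variables": "mm~age", "model": spec.name,
                                  "mode": mode,
                                  "r": point_biserial(flagged, cases["age"])})
                corr_rows.append({"variables": "mm~contacts",
                                  "model": spec.name, "mode": mode,
                                  "r": point_biserial(flagged,
                                                      cases["n_contacts"])})

    return {
        "overall": overall,
        "prevalence": pd.DataFrame(prev_rows),
        "table2": pd.DataFrame(t2_rows),
        "correlations": pd.DataFrame(corr_rows),
    }


def write_report(report: Mapping[str, pd.DataFrame], outdir) -> None:
    """Write the report frames as delimited text files with headers."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {"overall": "overall.csv",
             "prevalence": "prevalence_by_model.csv",
             "table2": "table2.csv",
             "correlations": "correlations.csv"}
    for key, frame in report.items():
        frame.to_csv(outdir / names.get(key, f"{key}.csv"), index=False)
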