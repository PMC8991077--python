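# morbiq

Multimorbidity classification from quarter-indexed primary-care EMR data.

## The problem

How many primary-care patients are multimorbid? The answer depends heavily
on the definition. `morbiq` implements a reusable pipeline for
quarter-billed electronic medical records of the kind produced by the
German statutory health insurance (SHI) system, where the 3-month
accounting quarter is the atomic time unit. The pipeline:

1. **ingests** an event stream (one row per EMR entry: patient, date,
   optional ICD-10 code truncated to its three-character group) and a
   patient roster;
2. **filters** patients — inclusion requires activity plus a diagnosis in
   at least two of the study quarters — with a full exclusion tally
   (missing-diagnosis vs. single-quarter, the machine-readable flow
   chart);
3. **detects chronic conditions** with the M2Q criterion: a code is
   chronic in quarter *q* iff it is recorded in *q* and in at least one of
   the three directly preceding quarters (two quarters within 12 months);
4. **classifies** every case — one patient in one calendar year with ≥1
   practice contact — under a configurable family of threshold models,

   | model  | criterion                                      |
   |--------|------------------------------------------------|
   | model1 | ≥2 diagnoses of any kind in one quarter        |
   | model2 | ≥3 diagnoses of any kind in one quarter        |
   | model3 | ≥2 chronic (M2Q) conditions in one quarter     |
   | model4 | ≥3 chronic (M2Q) conditions in one quarter     |

   each under two temporal readings: **annual** (re-assessed every
   calendar year — a time delimiter) and **propagated** ("no way back":
   once multimorbid, multimorbid in every later observed year);
5. **summarises** prevalence (case-based, in percent), contact burden
   (a contact is any distinct calendar date with an EMR entry, including
   indirect contacts), and the association of multimorbidity with age and
   contacts via the point-biserial correlation
   r_pb = (M₁ − M₀)/sₙ · √(n₁n₀/n²), alongside Pearson's r.

Because real SHI practice records are not freely available, the package
ships a seeded synthetic-cohort generator with latent ground truth
(true chronic conditions vs. their stochastic quarterly recording), which
is how the pipeline is validated.

## Worked example

```python
from morbiq import (CohortConfig, generate_cohort, filter_patients,
                    quarter_code_presence, chronic_flags, build_cases,
                    table2_report)

cohort = generate_cohort(CohortConfig(n_patients=1000, seed=7))
valid, tally = filter_patients(cohort.patients, cohort.events)
print(f"roster {tally.n_raw}: {tally.n_missing_diagnosis} missing-diagnosis, "
      f"{tally.n_single_quarter} single-quarter, {tally.n_valid} valid "
      f"({tally.pct_valid:.1f}%)")

presence = quarter_code_presence(
    cohort.events[cohort.events["patient_id"].isin(set(valid))])
cases = build_cases(cohort.patients, cohort.events, chronic_flags(presence),
                    valid_ids=valid)
report = table2_report(cases)
print(f"{len(cases)} cases (patient*years)")
print(report["prevalence"][["model", "mode", "percent"]]
      .pivot(index="model", columns="mode", values="percent").round(1))
```

prints

```
roster 1000: 298 missing-diagnosis, 269 single-quarter, 433 valid (43.3%)
3741 cases (patient*years)
mode    annual  propagated
model
model1    65.2        86.2
model2    31.2        55.3
model3    20.5        24.7
model4     7.0         9.5
```

Reading: of 1,000 simulated roster patients, 433 pass the inclusion
filter and contribute 3,741 patient-year cases. Under the loose
definition (model1) about two-thirds of cases are multimorbid each year,
rising to 86% once status propagates; under the advanced definition
(model4, ≥3 chronic conditions) only 7–10% are. The spread across
definitions dwarfs the effect of the time delimiter, and prevalence is
monotone from model1 to model4 in both modes.

The same analysis runs from a shell:

```sh
morbiq all --n 1000 --seed 7 --out out/
# out/: data/{patients,events,ground_truth}.csv, cases.csv, manifest.json,
#       prevalence_by_model.csv, table2.csv, correlations.csv, overall.csv
```

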