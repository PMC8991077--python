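# Methods

## Data model and calendar

The pipeline operates on an event stream — one row per EMR entry with a
patient id, a calendar date and an optional ICD-10 code — plus a roster
(id, gender f/m/u, birth date). Codes are truncated to their
three-character ICD group on ingest; tokens shorter than three characters
after cleaning are schema errors. Time is discretised into SHI accounting
quarters, ordered by `ordinal = 4·year + quarter − 1`; the default study
window spans the 55 quarters 1994Q1–2007Q3, and events outside it are
dropped (with a logged count), not rejected — records extend beyond the
analysable span for administrative reasons, and truncation is the normal
condition.

A **contact** is a distinct calendar date with ≥1 entry, a deliberately
wide proxy for practice workload that includes indirect contacts (phone,
report processing). A **case** is one patient in one calendar year with
≥1 contact. Age in year *Y* defaults to *Y − birth year* (configurable to
the year-start or mid-year reference date). Genders outside {f, m} are
retained in the case table but excluded from gender-stratified summaries.

## Inclusion filter

A patient is retained iff at least two distinct quarters each contain a
diagnosis-bearing entry (such an entry is itself a contact on its date,
so the contact-and-diagnosis conjunction is implied); only such patients
can, in principle, ever satisfy the chronicity criterion below. The
diagnosis need not be the same code in both quarters — same-code
recurrence belongs to chronicity, not inclusion. A looser reading (any
diagnosis anywhere plus two active quarters) is available as
`inclusion_rule: any_two_active_quarters`.

Exclusions are assigned with a fixed precedence: *missing diagnosis*
first (no diagnosis-bearing entry anywhere — such a patient can never
meet the two-quarter condition), then *single quarter*. This makes the
tally a well-defined partition: `n_raw = n_missing_diagnosis +
n_single_quarter + n_valid`, an invariant enforced by the
`ExclusionTally` type and checked on every run.

## M2Q chronicity

A code is a chronic condition in quarter *q* iff it is recorded in *q*
and in ≥1 of quarters *q−1 … q−3* (at least two billed quarters within a
rolling year). Chronicity is evaluated per quarter — a code chronic in
1997Q3 is not automatically chronic at an isolated recurrence years
later. Two deliberate conventions:

* **Left censoring is not compensated**: quarters before the study window
  count as absent, so nothing is chronic in the first study quarter and
  detection is conservatively biased during a patient's first three
  observed quarters.
* Because any presence in the lookback window implies the *latest*
  previous presence is in it, the rule reduces to a gap-≤3 test on
  consecutive presences of a (patient, code) pair; this vectorised form
  is verified against a brute-force all-quarter-pairs enumerator in the
  test suite.

Options: `chronic_persist` carries chronicity, once earned, to every
later presence of the code; `chronic_code_allowlist` restricts
eligibility to a code list when a regulatory catalogue is to be applied.
Both default off: the criterion is purely recurrence-based.

## Models and delimiter semantics

A model is `(min_count ≥ 2, scope ∈ {any_diagnosis, chronic_condition},
window ∈ {quarter, year})`. The default family is model1 = (2, any),
model2 = (3, any), model3 = (2, chronic), model4 = (3, chronic), all with
the quarter window: the criterion is judged within single accounting
quarters, the billing unit in which co-occurring diagnoses are actually
documented together, and a year counts as multimorbid if any of its
quarters qualifies. The year-pooled window (distinct codes over the whole
year; a code chronic if chronic in ≥1 quarter of it) is available per
model for sensitivity analyses. The family is config-driven; thresholds
below 2 are rejected.

Delimiter modes: the **annual** flag is re-earned each year; the
**propagated** flag is the cumulative OR of annual flags over the
patient's observed case years, in year order. Propagation operates on
observed years only: a gap year without contacts produces no case and
neither resets nor carries anything by itself. Two orderings are
structural consequences and are asserted as invariants: propagated ≥
annual everywhere, and flag sets are nested when one model's criterion
implies another's (higher threshold ⊆ lower; chronic scope ⊆ any scope,
at equal threshold). The ordering of model2 vs. model3 (≥3 any vs. ≥2
chronic) is *not* structural — it is an empirical property of
acute-heavy primary-care data, and holds on the default synthetic
conditions.

A patient-year with contacts but no diagnoses is a valid case with all
flags false.

## Statistics

* Group summaries report mean, sample SD (n−1), median, IQR and range;
  quantiles use linear interpolation between order statistics.
* `pearson_r` rejects degenerate input (n < 3 or zero variance) rather
  than returning NaN.
* `point_biserial` implements r_pb = (M₁ − M₀)/sₙ · √(n₁n₀/n²) with sₙ
  the population (n-denominator) SD; this is algebraically the Pearson
  coefficient on a 0/1 coding, an identity the tests verify to 1e−12
  against both the product-moment formula and an independent library
  implementation.
* Prevalence is case-based (denominator = patient-years). For
  Monte-Carlo error bars the package provides a patient-clustered
  (Taylor linearisation) standard error, `prevalence_cluster_se`: case
  years within a patient are strongly dependent — under propagation,
  perfectly so — hence the patient, not the case, is the independent
  replicate. No confidence intervals or tests are attached to the
  descriptive reports themselves.
* Correlations with the multimorbidity flags are emitted for both
  delimiter modes and labelled, since either reading is defensible.

## Synthetic cohort generator

The generator separates **truth** from **recording** — exactly the gap
the M2Q rule exists to bridge. Each patient carries latent chronic
conditions, acquired at some quarter and active for life; only their
quarterly recording is stochastic. Defaults define the study conditions
and are fixed:

| parameter | default | meaning |
|---|---|---|
| age at window end | N(49, 23.6²) truncated to [0, 105] | panel age structure |
| female fraction | 0.54 | roster composition |
| missing-diagnosis / single-quarter strata | 0.287 / 0.267 | designated fractions exercising the two exclusion arms |
| observation span | entry quarter uniform, ≥2 years before window end; single-quarter stratum: one quarter | staggered enrolment |
| chronic acquisition | 0.18 /patient·year, slope +0.5 per SD of age, pool of 40 codes | accumulating morbidity, age-graded |
| chronic recurrence | 0.6 /quarter (forced at acquisition) | billing visibility of a true condition |
| acute diagnoses | Poisson(0.6) /quarter, pool of 80 codes | one-off morbidity |
| contact days | Poisson(0.55 + 1.0 × recorded diagnoses) /quarter, distinct days drawn without replacement, capped at the quarter length | workload coupled to recorded burden |

The contact increment was calibrated once so that multimorbid cases
carry roughly twice the contacts of the remainder, the structural
pattern the analysis is meant to expose; with these defaults the
multimorbid:other contact ratio lies near 2 for all four models and the
per-case mean is ≈7 contacts/year. The single-quarter stratum always
records at least one diagnosis in its quarter — without one, exclusion
precedence would reclassify it as missing-diagnosis and that filter arm
would go unexercised. Patients in the two designated exclusion strata
carry no chronic truth. Code labels (`C00…`, `A00…`) are synthetic
tokens at ICD-3 shape, not a real catalogue. Same config + seed yields
byte-identical output.

Ground truth defines a chronic code as truly active in every quarter
from acquisition onward; `truth_prevalence` applies the same window
semantics as the models to these latent counts, bypassing detection.
With recurrence 1.0 the M2Q route lags truth by exactly one quarter per
code (a first occurrence cannot be chronic), so pipeline prevalence
falls marginally below truth — within twice the patient-clustered SE at
the problem sizes used; with sporadic recording (recurrence ≤ 0.6) the
shortfall is a genuine, directionally conservative bias, and the tests
assert it as such.

What the generator does **not** emulate: real ICD code frequencies,
practice-level clustering (142 practices are pooled unadjusted, as in
the analysis design), seasonality, mortality/dropout (patients remain
observable to window end), or care-seeking feedback beyond the linear
contact coupling. Passing tests therefore demonstrate the pipeline's
internal correctness and the direction of its biases, not the exact
prevalence levels of any real population.

## Problem sizes and runtime conventions

The validation suite runs the full pipeline on 5,000-patient cohorts
(≈240k events, ≈19k cases) for structural checks and 4,000-patient
cohorts for truth recovery — sizes at which Monte-Carlo error on the
reported percentages is a few tenths of a point and a full run takes a
couple of seconds. Oracle-equivalence suites sweep ≥1,000 random
presence grids and 500 random model fixtures against brute-force
enumerators.

## Known limitations

* Exact reproduction of any published prevalence level is out of scope;
  the reference data are not available, and all quantitative targets are
  structural (orderings, dominance, ratios, recovery gaps).
* The reconstruction of the two middle models (3-any, 2-chronic) is a
  documented choice; the model family is configuration, so an alternative
  family drops in without code changes.
* Left-censoring at window start and the one-quarter detection lag make
  every chronicity-based figure conservative near a patient's entry.
* Inclusion and chronicity assume diagnosis-bearing rows are reliable;
  no code-validity catalogue is consulted.
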