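# Methods

## Problem and model

A LOINC code identifies a laboratory test, not a finding. The same clinical
interpretation (say, nitrituria) can arise from several distinctly coded
tests, reported either as numbers against a reference range, as
positive/negative, or as coded nominal values. `lab2pheno` maps each test
*outcome* to an HPO term through a curated annotation map keyed by
(LOINC, outcome), and represents normal results as negated terms
(`NOT <abnormality>`), since HPO contains only abnormality terms. The
downstream analysis treats the resulting per-patient term profiles as the
phenotype side of a phenome-wide screen against binary exposures.

## Outcome resolution

Order of precedence for one Observation:

1. **Interpretation code**, when present. Variant codes collapse onto seven
   primary codes (`A` abnormal, `L` low, `N` normal, `H` high, `NEG` absent,
   `POS` present, `U` unknown); the normalization is total (any unlisted
   token → `U`) and idempotent. Matching is case-insensitive after trimming;
   `<` and `>` are matched literally. An explicit `U` fails the record with
   `UNKNOWN_INTERPRETATION` even when a numeric value is available: the
   reporting lab itself declined to interpret, and we do not override that.
2. **Coded value** (nominal and ordinal tests): the coding system + code are
   used directly as an external outcome key (typically SNOMED CT).
3. **Numeric value vs. reference range** (quantitative tests): below the low
   bound → `L`, above the high bound → `H`, otherwise `N`.

Numerical choices:

* Range bounds are **inclusive of normal** (value == bound → `N`), following
  the FHIR convention that the reference range is the normal interval.
* **No unit conversion** is attempted: a bound whose unit string differs from
  the value's (after trimming) is unusable, and a record with no usable bound
  fails with `INSUFFICIENT_DATA`. Silent unit coercion in a clinical pipeline
  is a safety hazard; callers must normalize units upstream if needed.
* When a record carries both an interpretation code and a value+range and the
  two disagree, the **interpretation code wins** and the disagreement is
  logged as a warning, not a failure.
* A resolved `L`/`H` with no scale-specific annotation falls back to the
  test's `A` (abnormal) annotation when one exists; `N` never falls back to
  `A` (a normal result is not evidence of the abnormal phenotype).
* Multiple reference ranges: the first range without an age/population
  qualifier is used, else the first. Observations without a LOINC coding, and
  panel observations whose codings live in components, are skipped with typed
  reasons rather than guessed at.

Every failure mode is a typed per-record value (`UNMAPPED_LOINC`,
`UNMAPPED_OUTCOME`, `UNKNOWN_INTERPRETATION`, `INSUFFICIENT_DATA`,
`RANGE_CONFLICT`), so collection-level conversion always partitions its input
and reports a conversion rate.

## Profiles and propagation

Per patient, calls are grouped by (term, negated) with observation counts,
contributing LOINC codes and first/last times. Non-negated counts are
propagated to all is\_a ancestors with **union semantics over source
observation ids**: one observation contributes at most once to each ancestor
regardless of how many paths reach it, which makes propagation idempotent and
immune to double counting through DAG diamonds. Negated calls are never
propagated — upward propagation of a negation is logically invalid, and
downward propagation has no support — but they are retained as asserted and
count toward per-patient unique-term summaries.

Propagation stops at (excludes) *Phenotypic abnormality* (HP:0000118) and the
root *All* (HP:0000001): these would otherwise be assigned to every patient
and carry no information. Everything strictly below HP:0000118 is eligible;
associations at fairly general terms (e.g. *Abnormal metabolism*) are
legitimate outputs of the aggregation, so no deeper cutoff is applied.
Obsolete ontology terms are kept out of closures (with `replaced_by`
resolution when given), and alt-ids resolve to primary ids.

Presence is three-valued, computed on **post-propagation** counts:

* `PRESENT` — at least `min_obs_for_present` (default 3) observations.
  An isolated abnormal value may be an artifact; requiring three observations
  over the tracking period trades sensitivity for robustness.
* `ABSENT` — the term was never assigned (count 0 including propagation).
* `INDETERMINATE` — assigned but under-supported.

Thresholding after propagation is what lets three observations spread across
sibling terms (e.g. specific vitamin abnormalities) make the shared parent
PRESENT — the aggregation behaviour the hierarchy exists to provide. A config
flag (`threshold_before_propagation`) switches to thresholding asserted
counts first, for sensitivity analysis; with it, only terms individually
meeting the threshold propagate support upward.

## Cohort rules and exposures

* Patients with medical encounters on fewer than `min_encounter_days`
  (default 10) **distinct calendar dates** are excluded: rarely seen patients
  receive few tests and their profiles are unreliably sparse.
* A patient with **strictly more than** `prednisone_rx_threshold` (default 3)
  prednisone prescriptions is a frequent user (exactly 3 is not).
* The acute-asthma flag matches diagnosis codes **prefix-wise after
  dot-stripping** (so `J45` covers `J45.901` and `J45901`); the code set is
  configuration, defaulting to the ICD-10 `J45` block and ICD-9 `493` family.

## Association screen

For each candidate term, patients PRESENT (outcome 1) or ABSENT (outcome 0)
for that term enter a logistic model with intercept and the two exposure
indicators; INDETERMINATE patients are dropped **per term**. Terms are
excluded when the majority share among determinate patients reaches
`uniformity_threshold` (default 0.95 — a 95 %-uniform outcome supports no
stable fit) or when fewer than `min_term_patients` (default 100) patients
carry the phenotype; the library default is deliberately conservative and
tests/examples lower it explicitly for small simulated cohorts.

Fitting is maximum likelihood (statsmodels `Logit`), standard errors from the
observed information, two-sided Wald p-values. Confidence intervals are
$e^{\beta \pm z\,\mathrm{SE}}$ with **z = 1.98** by default (configurable).
Significance markers: `**` p < 0.01, `*` p < 0.05, `-` otherwise. No
multiple-testing correction is applied to the markers; a Benjamini–Hochberg
q-value column is emitted alongside for transparency. Separation and
non-convergence (detected via the optimizer flag, non-finite estimates, or
absurd standard errors > 50) yield a typed `NON_CONVERGED` record; the screen
continues over the remaining terms. Reports are deterministic functions of
their inputs (stable patient and term ordering, mergesort for ties).

## Synthetic data

The generator emulates a de-identified respiratory-cohort EHR extract:

* **Exposures**: acute asthma ≈ 1/3 of patients; frequent prednisone use is
  drawn conditionally (14.2 % given asthma, 8.5 % otherwise), giving
  correlated exposures as observed in such cohorts.
* **Phenotypes**: per term, presence follows
  $\operatorname{logit}^{-1}(\operatorname{logit}(p_0) + \beta_p x_p + \beta_a x_a)$
  with configurable baseline prevalence and planted log-odds effects. The
  default effect set spans strong steroid-linked terms (eosinophilia,
  OR ≈ 3.7), moderate effects, vitamin-branch terms tied to asthma (to
  exercise parent-level aggregation), and deliberate nulls.
* **Observations**: an intended-present patient receives at least
  `min_obs_for_present` abnormal results of a test mapped to the term (cycling
  through the term's panel codes, so aggregation across distinctly coded
  tests is exercised); intended-absent patients receive only normal results.
  A configurable fraction of observations carries only an interpretation code
  (occasionally a variant code) and the rest carry value + reference range,
  exercising both resolution paths. Abnormal values are drawn uniformly from
  a band just outside the range, normals from within it — crude, but only the
  L/N/H partition matters downstream.
* **Unannotated tests**: a configurable share of observations (default
  11.4 %) uses LOINC-shaped codes absent from the annotation map, so default
  cohorts convert at ≈ 88.6 %.
* **Utilization**: encounter-day counts are Poisson (mean 24) with a small
  low-utilizer mixture (3 % at mean 5) so the encounter-day exclusion has
  work to do. All dates fall in a fixed 2004–2016 window.

All randomness flows from a single seed; equal seeds give byte-identical
output files. Ground truth (exposures, intended presence, true log-ORs) is
written alongside.

**What passing tests do and do not show.** The generator plants presence
deterministically enough that the design matrix reproduces the intended truth
almost exactly; recovery tests therefore validate the pipeline's bookkeeping
and the estimator, not robustness to measurement noise. Real extracts have
missing-not-at-random testing, unit heterogeneity, local codes, longitudinal
drift and confounding by indication — none of which the generator models, and
none of which these tests certify.

## Problem sizes used in checks

Calibration checks run at sizes chosen to make their Monte-Carlo error small
relative to the bounds checked: planted-effect bias is the mean estimation
error over 8 seeded cohorts of n = 5000 (a single cohort's sampling SE is
comparable to the 0.1 bound, so bias — an expectation — is estimated over
replicates); CI coverage uses 20 seeds at n = 2000; the null false-positive
rate uses 200 replicate null terms at n = 1000 via a profile-level simulator
that skips FHIR emission (the upstream stages add runtime but no information
at the association layer).

## Known limitations

* Free-text (string) values are never interpreted; they fail as
  `INSUFFICIENT_DATA` unless an interpretation code is present.
* No covariate adjustment (age, sex), no temporal modelling, no semantic
  similarity — the screen is a deliberately simple per-term cross-sectional
  logistic model.
* Unit strings are compared literally; commensurable-but-differently-written
  units (mg/dL vs mg/dl) are treated as mismatched by design.
* The bundled mini-ontology is a ~35-term synthetic fixture whose deep chains
  follow published HPO structure but whose intermediate placements are
  simplified; analyses of real data should load the full HPO release.
* The annotation-TSV loader accepts the upstream published layout
  best-effort via a column-alias table; exotic layouts require explicit
  aliases or fail in strict mode.
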