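# Methods

This note records the statistical model behind frailtykit, the choices
made where conventions differ, and what the synthetic cohorts do and do
not emulate.

## The cumulative-deficit frailty index

For person *i* with `a_i` assessed (non-missing) deficits of which
`p_i` are present, the frailty index is `FI_i = p_i / a_i`. Categories
are left-closed, right-open bands: fit `[0, 0.12)`, mild
`[0.12, 0.24)`, moderate `[0.24, 0.36)`, severe `[0.36, 1]`.

**Denominator with missing survey items.** We divide by the number of
assessed items for that person, the standard cumulative-deficit
convention; the completeness filter (at least 38 of 58 items assessed)
caps the distortion this can introduce. Published survey indices do not
always state their denominator, so `denominator="total"` (divide by the
fixed item count) is available as a configuration switch.

**Summaries.** Quartiles use linear-interpolation quantiles (the common
statistical default; the convention is recorded in the run manifest);
SD is the n−1 sample SD, matching conventional "mean ± SD" cohort
reporting.

## Ascertainment rules

* **Coded deficits**: present iff any event carries a code from the
  deficit's codelist dated *strictly before* the index date. "Before"
  is read literally as `<`; absence of any matching record is coded 0
  (never missing), reflecting how EHR phenotyping works.
* **Polypharmacy**: present iff prescriptions span ≥ 5 distinct BNF
  (chapter, paragraph) drug classes with issue dates in the half-open
  window `[index, index + 84 days)`, restricted to medication chapters
  1–15. Non-medication classes are modelled as a configurable
  excluded-paragraph set, since source data do not pin down whether
  exclusion happens at paragraph or product level. Prescriptions with a
  missing BNF paragraph are dropped by default (count logged); a
  `"count"` policy treats each such row as its own class, giving an
  upper bound — no principled imputation is recoverable for this case.
* **Eligibility**: age ≥ 65 at index, and for EHR persons registration
  of ≥ 9 full years before index; both thresholds are inclusive
  (registered exactly 9 years qualifies).
* **Survey items**: taken solely from current-wave responses; missing
  answers stay missing (no carry-forward, no imputation to absent).
  Respondents missing more than 20 of the 58 items are excluded, with
  the count reported.

## Harmonisation

The deficit mapping is a relation-typed table (one_to_one /
one_to_many / one_to_none) validated as a *partition* of each side's
deficit list: every deficit appears, and none appears under two
relations. Items genuinely listed under two broader headings can be
annotated `overlap` in the note column, which exempts them from the
duplicate check. Only one-to-one pairs enter the per-deficit
comparison models. The shipped mapping pairs 14 deficits directly,
maps 6 broad EHR deficits to 31 granular survey items, and leaves
16 EHR-only and 13 survey-only deficits; survey item names inside the
one-to-many groups are plausible placeholders chosen to produce those
cardinalities, not a transcription of any particular questionnaire.

## Comparison battery

* **Direct standardisation**: deficit prevalence is a weighted average
  of (5-year age band × sex) stratum prevalences. The default reference
  population is the pooled two-source person table, which treats both
  sources symmetrically; any weight scheme can be injected. Strata with
  scheme weight but no observations have their weight renormalised over
  observed strata (logged) so the estimate remains a weighted average
  rather than 0/0.
* **Per-deficit logistic models**:
  `logit p = β₀ + β_age(age−65) + β_sex·sex + β_source·source` with
  sex coded 0 = male / 1 = female and source 0 = survey / 1 = EHR.
  The data-source odds ratio is `exp(β_source)` with a Wald 95%
  interval (the conventional default; profile likelihood is not
  implemented). Constant outcomes and separation/non-convergence return
  flagged results rather than silent NaNs; adjustment covariates that
  are constant in a given table are dropped so that degenerate 2×2
  inputs still yield the closed-form cross-product odds ratio. No
  multiple-testing adjustment is applied across the per-deficit models
  (p-values are reported unadjusted, noted in the manifest).
* **Kolmogorov–Smirnov**: D is the exact supremum of the ECDF
  difference over pooled jump points (delegated to
  `scipy.stats.ks_2samp`); the p-value uses the asymptotic two-sided
  Kolmogorov distribution with the two-sample effective n, accurate at
  the cohort sizes used here.
* **Score regression**: OLS of the score on (age−65), sex, source and
  the three pairwise interactions, via statsmodels. Designs with a
  constant term (e.g. one source only) are rejected naming the term.

## Synthetic cohort generator

The generator exists so that every pipeline stage can be tested against
known ground truth. Deficit presence is drawn from
`logit p = β₀ + β_age(age−65) + β_sex·sex + β_source·source + λu`,
with one shared standard-normal latent factor `u` per person. The
latent factor is the simplest mechanism that induces positive
between-deficit correlation and reproduces the characteristic
gamma-like, right-skewed score distribution with an effective ceiling
well below 1; it is generator plumbing, not a claim about the true
dependence structure of real deficits.

Defaults live in `src/frailtykit/data/default_params.yaml` (versioned,
so tests can pin them):

* Age structure: integer ages drawn uniformly within 5-year bands
  (90+ drawn on 90–99), with band weights and female fractions (0.536
  EHR, 0.563 survey) matching published cohort tables for English
  adults 65+.
* Per-deficit coefficients: baseline prevalences span ~1–40% with a
  mean near 13%, age gradients of 0.01–0.09 log-odds/year and modest
  sex effects — chosen as clinically plausible for this age range. For
  the 14 directly comparable pairs, `β_source` is set to the log of the
  published adjusted odds ratios (e.g. 13.50 for visual impairment,
  0.16 for falls), so the synthetic study exhibits the same pattern of
  differential capture between routine and survey data. λ = 0.55 and a
  global 0.85 scaling of baseline prevalences calibrate the score
  distribution to mean ≈ 0.13 with maximum < 0.75 at n = 20,000.
* Missingness is MCAR in two layers: a 0.004 per-item probability
  (emulating near-complete questionnaires: ~98% of respondents miss at
  most one item) plus a 5.5% chance of being a heavy non-responder who
  misses each item with probability 0.5 (emulating the ~5% of
  respondents later removed by the completeness filter). Both layers
  are independent of deficit values.
* EHR event dates are uniform over the 9 years before index;
  prescription dates uniform within the polypharmacy window — only
  ordering relative to the index date matters for ascertainment.
  Distractor events (codes matching no codelist) and out-of-scope
  prescriptions are interleaved so ascertainment cannot succeed by
  accident.

What the generator does **not** emulate: informative healthcare
contact, coding-practice variation, care-home coverage differences,
survey design weights, or missingness that depends on health status.
Passing tests therefore demonstrate the *correctness of the pipeline's
logic and statistics under known conditions*, not that real EHR and
survey cohorts would yield any particular comparison result.

## Reproducibility and problem sizes

All randomness descends from a single root seed split per stage with
`numpy.random.SeedSequence`; identical configurations reproduce every
output byte for byte. The test suite uses n = 10,000 persons for
distribution-shape and calibration checks and n = 20,000 per source
for parameter-recovery checks — large enough that 3-standard-error
recovery bounds are informative. Parameter-recovery experiments set
λ = 0 so the fitted marginal logistic model coincides with the
generating model; with λ > 0 the marginal source effect is attenuated
relative to the conditional one (a known property of omitted random
effects in logistic models, worth remembering when interpreting the
default-parameter runs). The published-coefficient recovery experiment
uses an intercept of 0.09 and residual SD 0.08, values consistent with
the reported score means and variance explained; the intercept is not
itself published.

## Known limitations

* Codelists are flat toy lists with exact string matching; no clinical
  hierarchy (Read/SNOMED) expansion.
* The Wald/asymptotic choices are poor at very small n; exact K-S and
  profile-likelihood CIs are not implemented.
* The one-to-many group memberships in the shipped mapping are
  placeholders with correct cardinalities.
* EHR matrices cannot represent "not assessed": absence of a code is
  structurally absent, which is faithful to EHR phenotyping but means
  EHR/survey prevalence differences partly reflect ascertainment, not
  biology — which is precisely the phenomenon the comparison battery
  measures.
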