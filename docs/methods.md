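# Methods

## The register definition

Chronic pain (CP) has no incentivised register in UK primary care and no
consensus diagnostic code, so the package operationalises it over coded
records with two routes onto a register, evaluated at an extraction date:

* **Medication criterion.** Four or more prescription-only analgesic issues
  in the preceding 12 months. Analgesic classes include simple analgesics,
  opioids, NSAIDs, tricyclic antidepressants and antiepileptics; the last two
  have major non-pain indications, so their issues are discounted entirely
  for patients carrying the corresponding dual-indication diagnosis code
  (epilepsy for antiepileptics, depression for tricyclics) at any date up to
  extraction. One issue is one (patient, date, code) triple; exact duplicate
  rows collapse, which guards against duplicated extract rows.
* **Diagnostic criterion.** A two-tier hierarchy of 33 pain-associated
  conditions. Tier-1 conditions (12: e.g. fibromyalgia, chronic low back
  pain, pathological fracture) are strongly enough associated with chronic
  pain to qualify on code presence alone. Tier-2 conditions (21) qualify only
  with at least three qualifying analgesic issues in the same window.
  Cancer-pain codes never qualify. Diagnosis lookback is lifetime; only the
  prescription count is windowed — the 12-month clause attaches to
  medication, not coding.

A patient is on the register if either criterion fires. The 31 comparator
long-term-condition (LTC) registers are plain code-presence registers.

Conventions the data do not pin down, chosen and fixed here: "a whole
calendar year of data" is read as 365 days of continuous registration ending
at extraction; "four or more" counts total issues, not distinct drugs; ages
are completed years at extraction. Each is a single code path, not a flag,
except the 12-month window length which is a module constant.

## Cohort covariates

Eligibility: age ≥ 18 completed years, registration covering the full
12-month window, no informed-dissent flag; exclusions are counted by reason
and conservation (eligible + excluded = input) is asserted in tests.
Deprivation quintiles are *within-sample*: cut points at the 20/40/60/80th
percentiles of the observed IMD score, quintile 1 least deprived, tied
score-groups assigned to the lower quintile so assignment is deterministic.
Age bands are the closed decades 18–29 … 80–89 plus open-ended ≥ 90.
Ethnicity missing is recoded to an explicit `unknown` level because
recorded-as-unknown is itself a reported analysis level.

## Utilisation and costing

Utilisation counts **every** in-window consultation of register members —
overall contact rates, not pain-coded contacts — across the twelve
provider × mode cells (GP/nurse/other HCP × face-to-face/telephone/home
visit/digital). Registers overlap; a multimorbid patient contributes her
consultations to every register she is on.

Each consultation is priced as `rate_per_minute × mean_duration` for its
cell (or the recorded duration under the `use_recorded_duration` flag —
cell means are the default because published unit costs are duration-
standardised). Costs accumulate in integer thousandths of a penny
("millipence"). Whole-penny accumulation was rejected because per-event
rounding breaks exact rescaling whenever a cell cost lands on a half penny;
with millipence, provider components sum to totals bit-exactly and doubling
every rate exactly doubles every output for any schedule quoted to
fractions of a penny per minute and tenths of a minute. Reporting rounds
rates to 1 dp, per-patient costs to the nearest pound, and the headline
excess-cost comparison to an integer percent, computed from the rounded
per-patient figures since those are the reported quantities.

The shipped cost schedule is a **placeholder**: round numbers in the style
of national per-consultation benchmarks (GP £3.40/min over 5.5–13.5 min,
nurse £0.85/min, other £1.10/min). Substitute published figures via the
codebook YAML for real costing; every downstream number scales accordingly.

## The inequality model

Register membership is modelled by multivariable binary logistic regression
on six categorical factors with the reference levels 18–29, male, quintile 1,
White, English, UK-born. Missing policy: ethnicity → `unknown` level;
language, country and deprivation → complete case, with drops counted in a
missingness report rather than silently resolved (country of birth is the
big contributor; the tension between complete-case analysis and ~46%
missingness is surfaced, not hidden). Fitting is Newton maximum likelihood
(statsmodels `Logit`), declared converged only if the score norm is below
1e-8 within 100 iterations; coefficients above 15 in absolute value abort
with a separation diagnosis (penalised fitting is out of scope). Confidence
intervals are Wald, `exp(β ± 1.959964·SE)`, from observed-information
standard errors; no multiplicity adjustment, matching conventional register
reporting. A univariable 2×2 fit reproduces the cross-product odds ratio to
1e-6 relative error, and permuting row order leaves coefficients unchanged
to 1e-10 (both asserted in tests).

## The synthetic generator

The generator emulates the *statistical structure* the analyses assume, for
an inner-London-like adult practice population:

* **Demographics** are drawn independently per field from configurable
  marginals (defaults: 58.5% White among 92.3% known ethnicity, 48.1%
  female, 28.5% non-English preference among 75.9% known, 54.8% non-UK-born
  among 54.2% known, IMD score uniform on (0, 100), a young age mix with
  every band populated at n ≥ 10 000). Only marginals are emulated — no
  joint structure, which is the main divergence from real data (real age,
  ethnicity and deprivation are correlated). Missingness in language and
  country is missing-completely-at-random; ethnicity-unknown is a level,
  not missingness.
* **Latent CP** follows a logistic model with configurable odds ratios per
  demographic level (defaults 1.67–39.91 across age bands, 2.22 female,
  1.16–1.70 across quintiles, 0.87–1.51 across ethnic groups, 0.95
  non-English, 0.61 non-UK). The intercept is solved by exact enumeration of
  the 2 240-cell covariate product distribution so expected prevalence
  equals the 18.6% target.
* **Events are constructive.** Each CP-positive patient is assigned a
  realisation pathway (medication-only 35%, tier-1-only 25%, tier-2-plus-
  analgesics 20%, both 20%) and given events guaranteed to satisfy exactly
  that pathway; CP-negatives get at most three qualifying issues (at most
  two when carrying a tier-2 "near-miss" code, 15% of negatives), never a
  tier-1 code, plus adversarial decoys: nullified antiepileptic users (1%),
  cancer-pain codes (1%), OTC and non-analgesic scripts. Prescription dates
  are placed in per-patient 30-day slots so planted counts cannot be eroded
  by same-day de-duplication. Consequently the register must recover latent
  truth with sensitivity = specificity = 1 — the central oracle for the
  algorithm, checked exactly against an independent brute-force evaluator.
* **Consultations** are negative binomial (dispersion k = 1.5, a free choice;
  the source reports only means) with mean 15.3 for CP patients, a
  configured conditional mean for each planted comparator LTC (anxiety
  21.4% prevalence, depression 15.0%, hypertension 12.0%, asthma 11.7%),
  and a base mean for patients on no register solved in closed form so the
  population mean is 6.7/year. A patient's mean is the maximum over her
  registers, so the CP mean is exact and comparator means are conditional
  choices set to preserve the reported rankings (anxiety most prevalent; CP
  highest consultations and cost). The implied base mean (~1.1/year) is low
  — the price of hitting both 15.3 and 6.7 under this simple mixture.
* 2.6% of patients carry dissent flags and 8.7% lack the full 12-month
  record, both independent of CP, so eligibility filtering does not bias
  prevalence.

What passing tests therefore show: the algorithm implements the stated rules
exactly, the estimator recovers planted effects at nominal CI coverage, and
the accounting conserves. What they do not show: performance against real
coded data, where code-list quality, correlated demographics, informative
missingness and clustered practices all matter.

## Problem sizes and numerical checks

Frozen check sizes (chosen to keep the full suite around a minute on one
CPU while leaving Monte-Carlo error well inside the asserted bands):
register-vs-brute-force on 100 seeds × 500 patients; truth recovery at
5 000; preset calibration at 100 000 (prevalence within 3 binomial SEs of
18.6%, CP consultation mean within 2 SEs of 15.3); odds-ratio recovery over
50 replicates × 50 000 (per-level CI coverage ≥ 0.86 — three binomial SDs
below the nominal 95% at 50 replicates — and mean coverage ≥ 0.90). The
acceptance script reruns the whole pipeline at n = 100 000.

Degenerate inputs: an all-tied IMD column assigns everyone quintile 1 with
a warning; an empty register reports rate 0 with a warning; a constant
outcome, a rank-deficient design, unknown provider/mode cells, orphan
events and post-extraction dates all raise immediately with the offending
entity named.

## Known limitations

* The shipped condition/medication vocabulary is synthetic; real SNOMED-CT /
  EMIS code lists must be supplied for use on real extracts, and tier
  assignments there are a clinical, not software, decision.
* Independence of demographic fields and of comparator LTCs from CP is a
  simulation convenience; adjusted and unadjusted contrasts coincide in
  expectation here, which is exactly why planted-parameter recovery is
  testable — but real confounding structure is absent.
* Costing covers primary-care consultations only: no medication,
  secondary-care or social-care costs, no discounting.
* Single 12-month cross-section; no longitudinal trajectories, no
  practice-level clustering or random effects.
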