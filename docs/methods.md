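# Methods

## Screening model

A criterion is a boolean predicate over one patient record. The predicate
language has eight primitives — drug-class presence/absence (ATC code-prefix
sets with optional exclusions, e.g. neuroleptics = N05A minus N05AN),
treatment duration thresholds, diagnosis labels from a closed vocabulary,
co-prescription of two classes, qualifier flags, an age comparison, distinct
drug counts within a class, and duplicate-class detection at the ATC
chemical-subgroup level (first five code characters) — combined with
`all`/`any`/`not`. The catalog is data (YAML), so rules can be edited,
extended or replaced without touching the engine; sections with no shipped
rules (STOPP E and J, START D and I) are declared extension points.

Counting follows the medication-review literature: only drugs taken on a
regular basis are screened (as-needed/SOS entries are invisible to every
rule and count), a fixed-dose combination is one medication, one drug may
fire several criteria (a benzodiazepine prescribed ≥28 days fires both the
duration rule D5 and the falls-risk rule K1), and one PIM/PPO means one
distinct fired criterion. Rules that require clinical judgement (e.g.
neuroleptics in dementia "unless symptoms are severe") consume an explicit
qualifier flag; if the flag is not recorded the rule gives the benefit of
the doubt and does not fire. This makes screening conservative under
incomplete records, which is the realistic failure mode in long-term-care
data.

The anticholinergic-burden rule (STOPP N) is operationalized as ≥2
concurrent drugs from a declared anticholinergic prefix list, since no
burden scale is universally agreed.

## Charlson comorbidity index

The age-adjusted variant: classic 1987 condition weights (1 for heart
failure, cerebrovascular disease, dementia, chronic pulmonary disease,
rheumatic disease, peptic ulcer, uncomplicated diabetes; 2 for hemiplegia,
renal disease, diabetes with end-organ damage, non-metastatic tumour; 6 for
metastatic disease) plus one point per completed decade from 50–59, capped
at 4. Graded conditions are scored once at their most severe level. The
age-adjusted variant was chosen because a median CCI of 6 at median age 82 —
the regime this package targets — is only attainable with age points; the
index is monotone in added conditions, which is property-tested.

## Synthetic cohort generator

The generator emulates a post-acute/long-term-care population: ~64% female,
age ~ Normal(81.6, 7.4) truncated at the ≥65 inclusion bound, hospital
provenience 50.9%, high dependency (88.8%) and fall risk (81.4%), and the
tabulated comorbidity prevalences (hypertension 68.3% … metastatic tumour
3.1%; prostatic conditions sampled only in men). The regular-medication
count follows a negative binomial (mean 8.84, sd 3.32) truncated to [0, 25],
giving median 9 and >90% polypharmacy. Drugs are assigned conditionally on
diagnoses (antidepressants follow depression, ACE inhibitors follow heart
failure/hypertension, bronchodilators follow COPD, …) with coverage
probabilities chosen so that each shipped criterion has a realistic nonzero
firing rate; remaining slots are padded from a neutral filler list that
matches no rule class. Comorbidities are otherwise sampled independently —
no empirical joint distribution is available for this population, so
independence is the documented default.

What the generator does **not** emulate: joint covariate correlations beyond
the explicit conditional links, longitudinal medication histories, dose
strengths, and free-text clinical nuance. Tests that pass on synthetic
cohorts therefore demonstrate the correctness of the screening and
statistical machinery under known ground truth, not the field accuracy of
any particular prevalence estimate.

Randomness: one root seed; patient *i* consumes a substream derived from
(seed, *i*), so each record is a pure function of the seed and its index and
cohorts are prefix-stable (growing *n* never changes earlier patients).
`plant_outcome` draws a Bernoulli outcome from logit(p) = β₀ + Σβᵢxᵢ over
the covariate frame, for parameter-recovery and coverage experiments.

## Statistics

**2×2 screen.** OR = ad/bc; Woolf CI exp(ln OR ± z·√(1/a+1/b+1/c+1/d));
two-sided Wald p from z = ln OR / SE. A zero cell leaves the estimate
undefined and the row renders as a dash (no silent continuity correction; a
Haldane–Anscombe +0.5 option exists but is off by default, matching how
such tables are printed). Reported precision: OR/CI half-up to 2 decimals,
p to 3, percentages to 1. No multiplicity adjustment is applied at the
univariate stage. Quartiles use linear interpolation between order
statistics; SDs are sample (n−1) SDs.

**Logistic regression.** IRLS from an intercept-at-observed-logit start,
with step-halving so the log-likelihood never decreases; convergence when
max |score| < 1e−8 or the relative log-likelihood change < 1e−10, capped at
25 iterations. Frequency weights allow grouped 2×2 fits, whose exp(β)
equals the cross-product OR (tested to 6 significant digits, and
cross-checked against statsmodels). Rank-deficient designs raise an error
naming the collinear columns; |β| > 30 flags quasi-separation and marks the
fit non-converged rather than reporting meaningless Wald statistics.

**Forward selection.** At each step the candidate with the smallest Wald
p-value enters if p < 0.05 (the default of the statistical software
tradition this mirrors); selection stops when no candidate qualifies, and
the final report lists terms with p < 0.1. The default candidate pool in
the pipeline is the univariate-significant set; an arbitrary pool can be
supplied, covering the alternative reading in which all non-degenerate
covariates compete. An empty pool returns the intercept-only fit with a
note.

**Calibration and discrimination.** Hosmer–Lemeshow uses 10 quantile groups
of fitted risk (ties stay together via quantile binning; degenerate groups
with expected 0 or n merge with a neighbour), statistic
Σ(O−E)²/(E(1−E/n_g)), df = groups − 2. The chi-square reference is
asymptotic: the calibration-null simulations use n = 1,000 per replicate so
the risk deciles are well filled — at substantially smaller n the reference
is visibly approximate, which is a known property of the test, not of this
implementation. AUC is the Mann–Whitney rank statistic with half credit for
ties. The "simultaneously maximized sensitivity/specificity" cutoff is
interpreted as the threshold maximizing min(sensitivity, specificity), with
ties broken toward the larger sum and then the smaller threshold; a Youden
criterion would be a one-line variant.

## Pipeline determinism

All artifacts are pure functions of (seed, configuration, catalog):
provenance headers carry the seed and catalog version but deliberately no
wall-clock timestamp, so reruns are byte-identical — the stronger and
testable reproducibility contract.

## Problem sizes

Simulation-based validation uses: type-I error of the Wald test at
n = 2,000 × 1,000 replicates; coefficient recovery and CI coverage on a
5,000-patient cohort × 200 planted outcomes; calibration-null uniformity at
n = 1,000 × 500–1,000 replicates; AUC oracle fixtures up to 200 points;
rule-engine oracle cohorts of 50 patients. These sizes give Monte-Carlo
error comfortably below the tolerances asserted while keeping a full run in
tens of seconds.

## Known limitations

The diagnosis vocabulary is a controlled label set, not ICD-9-CM/ICD-10
ingestion; long-acting vs short-acting opioids are distinguished by a
declared code list because the ATC hierarchy does not encode release form;
dose-strength arithmetic (e.g. "full therapeutic dosage" for PPIs) is
delegated to a qualifier flag; and the shipped catalog covers the criteria
subset relevant to this care setting, not all 81 + 34 version-2 criteria.
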