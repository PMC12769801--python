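# Methods

This note documents the model, the rule semantics, the tunable parameters,
the synthetic-data design, and the numerical/design choices behind
`pacpheno`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The phenotype model

The package operationalises a fixed, chart-review-style rule set for asthma
ascertainment over longitudinal records. The model has two layers:

1. **Text processing** turns each dated note into asserted concept mentions:
   section segmentation (line-anchored headers from a configurable
   dictionary), rule-based sentence splitting, literal-phrase lexicon
   matching (case-insensitive, longest match per position), and
   assertion/experiencer resolution.
2. **Criteria evaluation** folds mentions and structured observations into a
   per-patient, per-criterion table of *earliest satisfaction dates*,
   applies the definite/probable logic and the exclusions, and derives the
   index date.

Evidence is **cumulative**: once a criterion is first satisfied on date *d*,
it is treated as satisfied from *d* onward. This matches how a retrospective
chart review reads a record ("has this patient ever had documented X by this
date?"). The one rule evaluated over the whole record rather than
cumulatively is the "FEV₁ consistently <50% predicted" exclusion, since
"consistently" is a statement about the whole trajectory; we require at
least two readings, all below 50% predicted, and date the exclusion at the
second reading.

Condition 1 combines primary concepts across notes (cough with wheezing or
dyspnea; or cough/dyspnea with wheeze on examination); its satisfaction date
is the date the last required component first appears. The index date is the
minimum over qualifying routes of the date that route completes:

- physician-diagnosis route: first credited diagnosis date;
- probable route: max(first condition-1 date, first condition-2 date);
- definite-by-criteria route: max(conditions 1 and 2, second-earliest minor
  criterion date).

Because the probable route is a subset of the definite-by-criteria route,
the index date for any non-diagnosis case reduces to the probable route's
date; the code keeps all three routes explicit because the minimum-over-
routes definition is the contract, not the simplification.

## Assertion and experiencer semantics

Negation uses a NegEx-style scope window: a trigger (denies, denied, no,
not, without, negative for, no evidence of, never) within `negation_window`
tokens **before** the concept, not interrupted by a scope terminator (but,
however, except, although), negates the mention. The default window is 5
tokens, the common choice for clinical negation scope. Hypothetical triggers
(if, should, return if) use the same window and mark mentions that are
discarded from evidence — a conservative choice, since "return if wheezing
recurs" documents no event. A relative term anywhere in the sentence
(mother, father, family history, sibling, ...) or a family-history section
label sets experiencer to *other*; such mentions never count as patient
evidence regardless of assertion.

Section constraint: the physician-diagnosis concept is credited only from
diagnosis / impression-assessment / plan sections; symptom concepts are
credited from any non-family-history section. Both lists are configurable in
the lexicon file.

## Parameters that matter

| parameter | default | unit / meaning |
|---|---|---|
| `eosinophil_threshold` | 300 | cells/μL; criterion requires strictly greater |
| `pft_low_threshold` | 70 | % predicted; low reading must be strictly below |
| `pft_improvement_threshold` | 20 | %; inclusive ("at least 20% improvement") |
| `methacholine_decline_threshold` | 20 | %; inclusive |
| `fev1_exclusion_threshold` | 50 | % predicted, "consistently below" exclusion |
| `igg_exclusion_threshold` | 2.0 | mg/mL hypogammaglobulinemia cutoff |
| `bd_response_threshold` | 12 | % FEV₁ improvement accepted as a favorable bronchodilator response when only numbers are available (the criteria give no number; 12% is the conventional spirometric reversibility cutoff) |
| `ige_threshold` | None | "elevated serum IgE" has no published cutoff, so by default only an elevated/normal flag counts; a numeric kU/L cutoff can be configured |
| `min_episodes` | 1 | distinct symptom-evidence dates condition 1 must span; whether the original criteria required recurrence over ≥2 dates is unstated, so one qualifying combination suffices by default |
| `foreign_body_window_days` | 365 | half-width of the "at or about the index date" window; "about" is unquantified, a year is the natural record-review horizon |
| `admit_former_smoker` | False | "nonsmoker" means the latest documented status is "never"; former/current/unknown fail (conservative, configurable) |
| `negation_window` | 5 | tokens |

Dates are day-granular (note timestamps truncated); an evidence item's date
is its note or observation date — the records carry no finer event dating.
Character offsets are 0-based half-open.

The nonsmoker criterion needs an age gate (≥14 years). Demographics travel
as an optional `birth_date` key on note records; when absent the age gate is
assumed met, which is correct for adult corpora and avoids silently dropping
the criterion.

## Synthetic corpus

No clinical data ship with the package, so the generator produces the study
conditions the pipeline assumes: ~5% asthma prevalence (matching a
validation-cohort setting), 60% of cases definite, 2–5 notes per adult
patient over 2000–2009, distractor rates of 0.3 for negated-symptom and
family-history sentences, a 2% exclusion rate, and threshold-straddling
observations (eosinophils sampled both ≤300 and >300, low/normal FEV₁,
boundary improvements). Cases receive canonical criterion sentences spread
over their timeline; the planted index date is computed analytically as the
date the last required component appears. The versioned canonical fixture
(`data/canonical_corpus.yaml`: n=500, seed 12345) is the regression surface
used by the tests.

What the generator does **not** emulate: realistic clinical prose, spelling
variation, cross-sentence negation, temporal expressions ("last spring"),
documentation bias between provider types, or contradictory records.
Passing the synthetic end-to-end tests therefore demonstrates that the rule
logic, assertion handling, sectioning, thresholds, and date arithmetic are
correct — not that the lexicon or context rules would achieve any particular
accuracy on real notes, where recall is limited by surface-form coverage.

`perturb_negate_all` rewrites every canonical affirmed evidence sentence
(including the diagnosis-section line) into a negated form and relabels the
ground truth to *none*; a correct assertion layer must then predict zero
asthma. The rewrite is idempotent.

## Statistics

Criterion validity: unweighted Cohen kappa, agreement, sensitivity,
specificity, PPV, NPV, accuracy from the 2×2 cross-tabulation. A
zero-denominator metric is reported as undefined, never as 0. The degenerate
single-category table with perfect agreement defines kappa = 1. Construct
validity: univariable odds ratios by the 2×2 cross-product with Wald 95%
CIs (z fixed at 1.96), identical to single-covariate logistic estimates, so
no iterative fitter is involved; a zero cell is an error unless the
Haldane–Anscombe +0.5 correction is requested. No multiple-testing
adjustment and no kappa confidence intervals are computed. Display rounding
is half away from zero: integers for percentages, 1 decimal for ORs/CIs,
2 decimals for kappa and agreement (with a 1e-9 epsilon so decimal halves
stored just below .5 round upward). Note that a specificity of 99.50%
displays as 100% under this rule even where a source table prints 99; raw
values are always available alongside the display values.

## Testing strategy

- Unit tests pin every operation's contract, including the threshold
  boundary cases (300 vs 301 eosinophils, 20% improvement, 70% predicted).
- Property tests (hypothesis, derandomised) cover the assertion-flip
  invariant, kappa label-swap invariance, and OR inversion under exposure
  relabelling.
- The classifier and index-date logic are checked against an independent
  brute-force oracle that re-evaluates the criteria from scratch at every
  timeline date, on 1,000 random small evidence sets.
- kappa and the OR/CI agree with scikit-learn and statsmodels on random
  tables (the implementations here are closed-form; the libraries serve as
  independent cross-checks only).
- End-to-end: exact recovery of labels and index dates on the noise-free
  n=500 corpus, sensitivity/specificity ≥0.95 on the distractor fixture, and
  zero predicted prevalence after `perturb_negate_all`.

Problem sizes (n=500 corpora, 1,000 oracle trials, 100 random tables) keep
the whole suite in the single-digit seconds while leaving each check
statistically meaningful.

## Known limitations

- The lexicon is a curated default, not a learned or published vocabulary;
  real deployments must extend it and re-validate.
- Negation scope is window-based; long-range or post-positioned negation
  ("wheezing was not observed") is not modelled by default triggers.
- Remission/relapse dating and severity phenotyping are out of scope.
- Equivalence with any specific production NLP system is not claimed — only
  conformance to the rule semantics documented here.
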