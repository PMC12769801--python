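# pacpheno

A rule-based computable phenotype for asthma over EHR-style clinical notes.

`pacpheno` reads a corpus of dated free-text notes plus a table of structured
observations (labs, pulmonary-function tests, smoking status), extracts
asserted asthma-relevant evidence, evaluates a fixed set of predetermined
asthma criteria (PAC) per patient, assigns a **definite / probable / none /
excluded** status with an **index date** (the first date the criteria are
met), and validates the result against a reference standard with the usual
diagnostic-accuracy and construct-validity statistics.

It is aimed at EHR-phenotyping and epidemiology groups who need a
transparent, auditable alternative to code-based asthma ascertainment: every
classification is backed by an evidence trail (which criterion, which date,
which note span or observation) that mirrors manual chart review.

## The criteria

A patient has **definite** asthma if a physician made an asthma diagnosis,
or if all three conditions hold; **probable** asthma if only the first two
hold:

1. history of cough with wheezing and/or dyspnea, *or* cough and/or dyspnea
   plus wheezing at examination (evidence may accumulate across notes);
2. substantial variability in symptoms, or symptom-free periods of weeks;
3. two or more minor criteria: nocturnal cough-and-wheeze sleep disturbance;
   nonsmoker (≥14 years); nasal polyps; blood eosinophilia >300 cells/μL;
   positive skin tests or elevated serum IgE; history of hay fever, infantile
   eczema, or antigen-triggered symptoms; PFTs with FEV₁ or FVC <70%
   predicted and another test with ≥20% improvement to FEV₁ >70% predicted
   (or methacholine challenge with ≥20% FEV₁ decline); or a favorable
   bronchodilator response.

Eight exclusion conditions (cystic fibrosis, PiZZ α₁-antitrypsin, bullous
emphysema or pulmonary fibrosis, consistent FEV₁ <50% predicted or diminished
diffusion capacity, hypogammaglobulinemia, tracheobronchial foreign body near
the index date, wheeze only with anesthesia/medications, other major chest
disease) veto the classification.

The NLP layer is deliberately simple and fully configurable: a literal-phrase
lexicon (longest match per position), line-anchored section headers, and a
NegEx-style token window for negation/hypothetical assertion plus a
family-history experiencer rule. Only affirmed, patient-experienced mentions
count; a physician diagnosis is credited only from diagnosis/impression/plan
sections.

## Worked example

There are no deposited clinical data (notes are PHI), so the package ships a
seeded generator that emulates multi-note patient timelines with controllable
negation and family-history distractors, threshold-straddling lab values, and
known ground truth:

```bash
pacpheno generate --out demo --n 40 --seed 3
pacpheno classify --corpus demo/notes.jsonl --observations demo/observations.csv \
    --out demo/status.csv --trail demo/trail.tsv
pacpheno validate --pred demo/status.csv --labels demo/ground_truth.csv
```

which prints:

```
Concordance with reference standard
-----------------------------------
                 algorithm+   algorithm-
reference+                1            0
reference-                0           39

kappa       = 1.00
agreement   = 1.00
sensitivity = 100%
specificity = 100%
PPV         = 100%
NPV         = 100%
accuracy    = 100%
```

Here the 40-patient synthetic corpus contains one true asthma case; the
pipeline recovers it, with no false positives, so agreement with the
planted ground truth is perfect (kappa 1.0). On real notes the interesting
output is `demo/status.csv` (one row per patient: granular class, binary
flag, index date) and `demo/trail.tsv`, the per-criterion audit log.
`pacpheno replay-index` re-classifies at a grid of historical cutoff dates to
show when each patient first met the criteria.

The library surface mirrors the CLI: `read_corpus` / `read_observations`,
`Lexicon.default()`, `extract_mentions`, `build_evidence`, `classify`,
`determine_index_date`, and the statistics in `pacpheno.evaluation`.

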