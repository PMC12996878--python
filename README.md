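# nsburden

Negative symptoms of schizophrenia — blunted (flat) affect, alogia, avolition,
asociality, and anhedonia — are rarely captured by structured EHR fields, yet
they shape functioning, treatment need, and cost. `nsburden` is a tested
implementation of a retrospective negative-symptom burden analysis for linked
EHR + administrative-claims data, aimed at health-services researchers and
clinical-NLP engineers:

1. **Rule-based NLP phenotyping** of clinical notes: HTML stripping, sentence
   segmentation with clinical-abbreviation guards, word-boundary-anchored
   lexicon matching with Levenshtein fuzzy expansion for misspellings, and
   sentence-scoped exclusion of negation / question / goal / family-history
   framings. Patient-level output: one flag per symptom domain.
2. **Quality control**: patient x domain confusion matrices with precision,
   recall, and F1 = 2PR/(P+R) against gold chart-review labels.
3. **Cohort building**: index date = first schizophrenia diagnosis
   (ICD-9 295.xx / ICD-10-CM F20.x) in the study window; eligibility (age >= 18,
   >= 2 outpatient schizophrenia encounters, 12-month lookback, no
   dementia/cognitive-impairment exclusion diagnosis); continuous-enrollment
   linkage; baseline Charlson Comorbidity Index (original weights, Quan ICD
   mappings), psychiatric comorbidity flags, and BMI.
4. **Outcomes**: per-patient-per-year (PPPY) utilization and cost summaries
   over the 12 months post-index, with Welch *t* and chi-square contrasts.
5. **Adjusted estimates**: a two-part cost model (logistic for Pr(cost > 0),
   gamma GLM with log link for E[cost | cost > 0], so E[Y] = p·mu) and an NB2
   negative binomial admissions model, both adjusted for age, gender, race,
   region, CCI, and six psychiatric comorbidities. Adjusted group means use
   recycled predictions (marginal standardization) with percentile-bootstrap
   intervals.
6. **Synthetic data**: a generator that plants symptom mentions, decoy
   sentences, misspellings, eligibility violations, Bernoulli x gamma costs,
   and negative binomial admissions with known coefficients — so the whole
   pipeline is testable end to end with no data download.

## Worked example

```python
from nsburden import ClinicalNote, annotate_corpus, default_lexicon
from nsburden.annotator import mentions_to_frame

notes = [
    ClinicalNote("n1", "p1", "2020-03-14",
                 "<p>Pt seen for follow up.</p>"
                 "<p>Exam notable for flat affect and pverty of speech.</p>"),
    ClinicalNote("n2", "p1", "2020-05-02",
                 "No poor hygiene noted. Mother has history of apathy."),
    ClinicalNote("n3", "p2", "2021-01-20", "Patient is engaged and cheerful."),
]
mentions, profiles = annotate_corpus(notes, default_lexicon(), fuzzy=True)
print(mentions_to_frame(mentions)[
    ["note_id", "domain", "matched_variant", "retained", "exclusion_reason"]
].to_string(index=False))
```

prints

```
note_id         domain  matched_variant  retained exclusion_reason
     n1 blunted_affect      flat affect      True             none
     n1         alogia pverty of speech      True             none
     n2      avolition     poor hygiene     False         negation
     n2      anhedonia           apathy     False   family_history
```

The markup is stripped, the misspelling "pverty of speech" is recovered by
fuzzy expansion (edit distance 1 from "poverty"), and the negated and
family-history sentences are excluded, so patient `p1` ends up flagged for
blunted affect and alogia only, and `p2` for nothing.

The same stages run from a shell:

```bash
nsburden generate --config smoke --out bundle/
nsburden annotate --notes bundle/notes.csv --out nlp/
nsburden evaluate --pred nlp/profiles.csv --gold bundle/gold.csv --out metrics.csv
nsburden cohort --data-dir bundle/ --profiles nlp/profiles.csv --out cohort/
nsburden analyze outcomes --cohort cohort/cohort.csv --claims bundle/claims.csv --out out/
```

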