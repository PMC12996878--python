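# Methods

## The phenotype

Negative symptoms are the absence or reduction of normal emotion and
behaviour in schizophrenia. The package uses the standard five-domain latent
structure — blunted (flat) affect, alogia, avolition, asociality, anhedonia —
grouped into an experiential dimension (avolition, asociality, anhedonia) and
an expressive dimension (alogia, blunted affect). A patient is "documented
positive" for a domain when at least one retained mention of that domain
occurs anywhere in their clinical notes; `any_negative_symptom` is the OR
over domains.

## NLP annotator

**Preprocessing.** Notes exported from ambulatory EHRs often embed HTML.
`strip_html` removes tags with the standard library's lenient parser, decodes
entities, maps block-level tags to newlines (so adjacent paragraphs cannot
fuse into one sentence), and collapses runs of whitespace. It never raises;
malformed markup falls back to a crude tag strip.

**Segmentation.** Sentences end at `.`, `!`, `?`, or a newline. A period is
not a boundary inside a decimal number, after a guarded clinical abbreviation
(`Dr.`, `pt.`, `vs.`, `e.g.`, single-letter initials, ...), or when not
followed by whitespace. Spans are 0-based half-open character intervals;
concatenating sentences recovers the input up to inter-sentence whitespace.

**Matching.** Every lexicon variant compiles to a case-insensitive regular
expression anchored so a match may not be flanked by letters or digits
("apathy" never fires inside "apathyxyz"). Overlaps resolve
longest-match-first, ties to the leftmost match, then lexicographically by
pattern id — fully deterministic. This ordering is what lets "loss of
interest in activities" (avolition) win over its prefix "loss of interest"
(anhedonia) when the longer phrase is present.

**Fuzzy matching.** The term inventory can be expanded against the corpus
vocabulary: any corpus token within Levenshtein distance 1 of a variant token
spawns a new variant. Guardrails: only tokens of length >= 5, only entries
flagged `fuzzy_eligible` (short phrases like "no friends" are not), at most
one fuzzy token per multi-token phrase, expansion always from curated
variants (hence idempotent), and a derived variant that collides with another
entry's curated term — or is derived by two domains at once — is dropped as
uninformative. The Levenshtein implementation is an iterative two-row dynamic
programme, property-tested against a recursive oracle and an independent
alignment library.

**Exclusion rules.** Exclusion is sentence-scoped: if a rule fires, every
mention in the sentence is excluded with the first firing reason in the fixed
precedence negation > question > goal > family_history. The cue inventories
are package defaults, overridable in code:

* negation — pre-trigger cues (`no`, `not`, `denies`, `denied`, `without`,
  `absent`, `negative for`, `w/o`) occurring outside every matched span and
  before at least one match; the "no" inside "no response" does not negate;
* question — terminal `?`, or a leading interrogative token (`any`, `does`,
  `is`, `are`, `do`, `have`) followed by a hit;
* goal — leading `goal:`/`plan:` label, or `goal(s) of` / `working toward`;
* family history — kinship nouns or `family history` / `FH`.

## Evaluation

The evaluation unit is the (patient, domain) pair, mirroring patient-level
chart review. Precision = tp/(tp+fp), recall = tp/(tp+fn),
F1 = 2PR/(P+R) = 2tp/(2tp+fp+fn). Zero denominators yield 0 and are flagged
(`undefined`) rather than propagating NaN. Gold patients without a prediction
count as predicted-negative and are logged.

## Cohort

Study window 2016-01-01 .. 2023-02-28; index date = first schizophrenia
diagnosis (prefix match on dot-stripped `295` / `F20`) in the window.
Eligibility, applied in a fixed precedence so attrition reasons partition the
input: index exists; age >= 18 at index; >= 2 outpatient schizophrenia
encounters on or after the window start; any EHR activity >= 365 days before
index ("activity" = any recorded event, since charting systems differ); no
lifetime diagnosis from the exclusion-condition mapping (dementia,
frontotemporal lobe disease, prion disease, autism spectrum disorder,
epilepsy, intellectual disability, multiple sclerosis, Parkinson's disease,
stroke, traumatic brain injury — shipped as an editable CSV because condition
names, not code lists, are the specification). The linked subcohort requires
continuous medical **and** pharmacy enrollment over [index, index+364], with
gaps <= 30 days bridged (the usual claims convention).

Baseline covariates use the pre-index year [index-365, index-1]. The CCI uses
original Charlson weights with the Quan ICD-10 (and core ICD-9) mappings;
severity hierarchies (complicated diabetes, metastatic tumor, severe liver
disease) suppress their milder forms so the score equals the weighted flag
sum. Hypertension is tracked as a flag with weight 0: it appears in the
comorbidity panel this package reports, but it is not a Charlson component.
BMI is the closest positive value to the index within the pre-index year,
ties toward the earlier record.

## Outcomes and adjusted models

All outcome measures cover [index, index+364]; with a fixed one-year window
PPPY equals the raw annual value. Hospitalizations count unique admission
ids; hospitalized days sum lengths of stay truncated at the window end.
Continuous contrasts use Welch's *t* by default; 2x2 contrasts use chi-square
without continuity correction when all expected counts are >= 5 (Yates
otherwise). A claim is schizophrenia-related iff a schizophrenia code is
attached to the line.

Costs are semicontinuous, so the adjusted cost analysis is the canonical
two-part model: logistic regression for Pr(cost > 0) on all patients, gamma
GLM (log link) for the conditional mean on spenders, expected cost = product.
Zeros live in part 1 only — no log(y + c) transforms. Admissions use NB2
negative binomial regression, dispersion estimated by maximum likelihood from
a Poisson + moment-estimator start; if the MLE fails, the Poisson
coefficients with the moment dispersion are returned and flagged. Perfect
separation in part 1 raises a diagnostic error naming the part.

Covariates: age, gender, race, region, CCI, and anxiety, bipolar disorder,
depression, panic disorder, PTSD, substance use disorder. Reference levels
are fixed (male, White, Northeast, flag absent) so coefficients are
reproducible; empty categories are dropped to keep the design full rank.

Adjusted group means use recycled predictions: set the exposure to
"documented negative symptoms" for every patient, predict, average; repeat
with the exposure off. This population-average standardization — rather than
prediction at covariate means — matches the estimand of an adjusted PPPY
mean. Uncertainty comes from a nonparametric percentile bootstrap over
patients (default 500 replicates, seed required, refits warm-started);
both the coefficient Wald *p* and a bootstrap sign-test *p* are reported
because either convention is defensible for the adjusted contrast.

## Synthetic data generator

The generator emulates the three study inputs. Notes are assembled from
neutral filler sentences plus planted lexicon phrases in positive templates,
decoys wrapping a phrase in a negation/question/goal/family-history frame,
and misspellings created by one random unit edit of a token (length >= 6,
fuzz-eligible entries only, never colliding with another lexicon token or a
cue word) — so with decoy and misspelling rates at zero the annotator must
reproduce gold exactly, and at default rates every planted mention remains
recoverable in principle. Structured tables violate each eligibility rule
independently at configured rates so every attrition path is exercised.
Annual costs are drawn Bernoulli(p) x Gamma(shape, mean e^lp) and admissions
gamma-Poisson (NB2), with named-coefficient linear predictors over the model
covariate set; claim lines then decompose the totals by setting. One seed
drives everything through per-table substreams.

Named configurations: `smoke` (n=400, seconds, all violation paths),
`benchmark` (n=2500, one domain per NS patient, ~500 notes per domain,
default decoy/misspelling rates), `paper_calibration` (n=12,000, NS
prevalence 17.5%), and `recovery` (n=5000, non-trivial covariate effects for
parameter-recovery simulations).

**Calibration choices.** In `paper_calibration` the outcome models carry the
exposure effect only (other coefficients 0), so the planted marginal means
equal the published benchmark values exactly: cost $26,291 vs $32,187
(part-1 probability 0.96 in both groups), admissions 0.3 vs 0.4 per year
(ratio 4/3), mean length of stay 13 days (hence 3.9 vs 5.2 hospitalized days
per year). Covariate prevalences still differ by exposure group, mirroring
the published descriptive contrasts. The gamma shape is 2.0 (coefficient of
variation ~0.7): real annual-cost distributions are more dispersed, but this
choice makes the planted means estimable to within a few percent at the
configured cohort size; treat it as a calibration parameter, not a claim
about real cost data. Admission dates are drawn so stays end inside the
follow-up year, keeping the planted day means exact (the summarizer still
truncates arbitrary input at the window end).

## Problem sizes used

The packaged checks run at the configured study sizes: the NLP benchmark at
2,500 patients (~5,000 notes), the calibrated cohort at 12,000 patients
(~1M claim lines, 500 bootstrap replicates), and parameter recovery at 200
replicates of n=5,000.

## What passing tests do and do not show

The generator's language is templated: planted phrases always appear in
well-formed sentences, decoys always contain an explicit cue, filler
vocabulary avoids near-neighbours of lexicon tokens. Passing the synthetic
benchmarks therefore demonstrates correctness of the mechanics (matching,
exclusion logic, aggregation, eligibility, model fitting, standardization),
not clinical NLP performance on real charts, where section headers,
templated questionnaires, copy-forward text, and unlisted cue variants all
degrade precision and recall. Likewise the claims generator draws from the
same family the models assume; recovery there validates the estimation code,
not robustness to misspecification.

## Other limitations

* The default lexicon covers the published core inventory plus obvious
  inflections; site-specific synonym lists should be supplied as data.
* Exclusion cues are sentence-scoped; no dependency-parse negation scoping,
  section detection, or machine-learned phenotyping (deliberate non-goals).
* Domain flags are monotone in the note set only with fuzzy expansion off;
  with fuzzy expansion, adding notes changes the corpus vocabulary and can
  (rarely) retract an ambiguous derived variant.
* ICD prefix matching pools ICD-9 and ICD-10 code spaces; the packaged
  mappings avoid cross-version ambiguity, but custom mappings should, too.
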