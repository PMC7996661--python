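# Methods

## Pipeline model and assumptions

`occmine` treats occupation extraction as three coupled decisions per
document: *where* occupation-bearing narrative lives (section extraction),
*which* character spans mention an occupation (mention detection), and
*whose* occupation each mention is (relation classification), followed by a
safety rule (the healthcare filter) and patient-level aggregation. The
pipeline assumes notes are English, that personal-history narrative is
introduced by recognizable headers, and that temporality is not recoverable
from the text — whether an occupation is current or past is deliberately
out of scope, as is mapping occupations onto social-class schemata.

### Section extraction

Headers match line-anchored and case-insensitively, delimited by a colon or
the line end, so both `Personal History:` on its own line and
`Personal History: Worked as a builder.` are recognized. A section runs
from the end of its header to the next known header (personal-history or
stop list: medication, mental state, risk, plan, …) or end of document.
The header lists are configuration (`ph_headers`, `stop_headers`); there is
no statistical section classifier. Text outside every section is still
processed — it simply lacks the section feature, and mentions there
default toward non-patient attribution.

### Mention detection

The gazetteer arm does case-insensitive longest-match, left to right,
non-overlapping, over token sequences; entries carry a normalized label, a
mention kind (*title* like "builder" vs *description* like "construction")
and a status flag (student, unemployed, retired, carer, self-employed —
legitimate targets, and in practice the most frequent ones). The
statistical arm is a first-order linear-chain CRF over BIO tags, written
in-package (numpy/scipy): exact negative log-likelihood with
forward–backward gradients, L2 penalty `c2 = 0.1`, L-BFGS capped at 100
iterations, Viterbi decoding with ties broken by label index. Features per
token: lowercase surface, capitalization and digit flags, gazetteer-hit
flag, kinship-cue flag, clinician-cue flag, section-membership flag, and
the same for neighbours within ±2 tokens, plus a bias. The feature
vocabulary freezes in first-seen training order, the optimizer starts from
zero, and no randomness enters training, so identical corpora give
identical models; the training seed is recorded in model metadata for
provenance. Tokenization is a small deterministic regex (word runs with
internal hyphen/apostrophe, single punctuation marks); its version string
is stored in the model and checked at prediction time.

Arm merging: candidates from both arms are resolved longest-span-wins; on
a length tie the gazetteer candidate wins because it carries a
normalization; remaining ties go left to right. CRF-only spans whose
surface has no gazetteer entry receive the reserved label `other` — kept in
the output for audit, excluded from patient profiles (such unnormalizable
extractions are too imprecise to trust).

### Relation classification

A linear SVM (`LinearSVC`, C = 1.0, one-vs-rest) over five features:
nearest preceding pronoun within the sentence (he/she/they/none), kinship
cue within 5 tokens to the left, clinician cue within 5 tokens
(dr, consultant, cpn, seen, reviewed, assessed, referred, discussed),
personal-history membership, and capped distance to sentence start.
Probability-like scores are a softmax over the decision margins — chosen
over Platt scaling to keep prediction deterministic without cross-
validation randomness. Precedence is fixed: clinician cue > kinship cue >
model prediction when its top score ≥ 0.4 > positional default (`patient`
inside a personal-history section, `other_person` outside). Clinician
wins over kinship on a joint fire: misattributing a clinician's occupation
to anyone else is the dominant error mode, so the rules err that way.

### Healthcare filter

A configurable list of health/social-care labels (psychiatrists and
doctors, nurses, therapists, psychologists/counsellors, social-care roles).
Any annotation with a filtered label and relation `patient` is re-assigned
relation `clinician`; nothing is deleted, so stage counts are conserved and
the pre-filter condition is recoverable with `--no-filter`. The filter is
idempotent. A consequence mirrored deliberately from the clinical setting:
the pipeline never outputs a patient-held healthcare occupation, so
patients who genuinely hold such jobs are missed.

### Evaluation

Matching between gold and predicted annotations is one-to-one and of
maximum cardinality (Hopcroft–Karp), computed per document and pooled
(micro-average). Strict mode requires identical span and relation;
`span_only` drops the relation requirement; `lenient_overlap` accepts ≥1
character of overlap with relation equality. Maximum matching was chosen
over greedy left-to-right selection because greedy is provably suboptimal
under overlap matching (nested spans); the test suite checks equivalence
against brute-force enumeration. 0/0 ratios are reported as null, never 0.
Cohen's kappa uses marginal-based chance agreement; units are a repo
convention stated in every report: per-token binary decisions for mention
agreement, span-overlap-aligned mention pairs for relation agreement.

### Cohort analysis

Profiles merge, per patient, the coded occupational status (13 opaque
categories, kept as codes 1–13) with the set of normalized patient-relation
extracted labels (minus `other`, minus filtered labels). The binary
outcome *occupation recorded* is true when either source is non-empty.
Association models are standard maximum-likelihood logistic regressions
(statsmodels): crude per predictor; service-adjusted (events quartile +
bed-days band, excluding the predictor itself when it is a service
variable); fully adjusted over all predictors. Wald 95% CIs per level,
reference level OR ≡ 1 with empty CI, and a likelihood-ratio test per
variable from nested-model deviance. Perfect separation is flagged and the
affected level reported as null rather than an absurd estimate.
Collinearity handling is the caller's responsibility. This stage is
deliberately bought, not built — the bespoke content of the package is
everything upstream of it.

## The synthetic corpus: what it emulates and what it does not

Template-based generation with slot-filling from lexicons was chosen over
any learned language model so that ground truth is exact and the generator
auditable: text and gold spans are written from the same builder, so
surfaces always equal their slices. One `numpy` generator seeded from the
single config seed drives everything; the same config is byte-identical
across runs.

Defaults (the study conditions for all tests):

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 500 | patients per corpus |
| `docs_per_patient` | 3.0 | mean of a 1 + Poisson draw |
| `p_personal_history_section` | 0.8 | chance a document has a PH section |
| `p_patient_mention` | 0.35 | per-sentence patient-occupation rate |
| `p_family_mention` | 0.20 | per-sentence family-occupation rate |
| `p_clinician_trap` | 0.10 | per-sentence (and per-intro) clinician trap rate |
| `noise` | 0.15 | distractor "work"-idiom sentences, never annotated |
| `p_out_of_lexicon` | 0.08 | chance a personal occupation is absent from the gazetteer |
| `structured_field_completeness` | 0.14 | fraction of patients with a coded status |

Occupation frequencies are a ranked categorical distribution in which the
statuses student (0.25) and unemployed (0.24) dominate, followed by carer,
self-employed and retired, with the remaining mass spread uniformly over
~120 specific titles. Patients carry a personal set of 1–3 occupations
reused across their documents; each patient's documents all land in one
split to prevent leakage (the document-to-patient structure of the real
gold standard is not public, so this is the conservative choice). With
these rates a 500-patient corpus yields roughly 1200 personal-history
documents, comfortably supporting the 257/77/666 train/validation/test
protocol, and a median of 1–2 distinct extracted occupation types per
patient — the real register shows more (multiple occupations per patient
are common there); the generator's rate is a configurable stand-in, not a
claim about real notes.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: free narrative variability, misspellings,
negation, temporal expressions, coreference, ambiguous domestic-task
sentences ("she did several things, such as cleaning, cooking"), and
patient-held healthcare occupations. Performance on this corpus is an
upper bound; the pipeline's measured precision/recall floor (≥ 0.75
strict, patient scope, held-out) is asserted as a floor precisely because
synthetic text is easier than clinical text.

`simulate_profiles` is separate from text generation: it draws covariates
independently and the outcome from a logistic model in the service-contact
category only (default OR 2.0 for high vs none, other covariates null by
construction), so the crude model is correctly specified and
parameter-recovery and null-uniformity checks are exact by design.

## Numerical choices and degenerate inputs

* Character offsets are 0-based half-open over Unicode code points.
* Standoff serialization orders annotations by (start, end, relation);
  exact duplicates collapse on read; conflicting annotations on the same
  span are kept for the evaluator to resolve.
* CRF: zero initialization, L-BFGS, 100-iteration cap; Viterbi tie-break
  toward lower label index; dangling `I` tags open a new span.
* SVM scores: softmax over margins; binary edge case handled explicitly.
* Empty corpora: precision/recall of nothing-vs-nothing is null/null;
  kappa of zero units is null; empty profile summaries are null.
* Training raises on empty splits, annotation-free splits, and
  single-relation (degenerate) splits.
* Wald CIs use z = 1.959964; a standard error above 50 on the logit scale
  is treated as separation and nulled.

## Known limitations

* The gazetteer and filter list are starter sets; real deployments need
  locally curated vocabularies (the originals were assembled against tens
  of thousands of real documents and are not public).
* The CRF feature template is a faithful-in-spirit reconstruction; the
  original application's exact feature set is not published in full.
* No temporality, no coreference, no negation handling, no social-class
  mapping, no de-identification — all out of scope by design.
* Patient-held healthcare occupations are structurally unreachable (see
  the filter section above).
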