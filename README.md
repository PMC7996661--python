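# occmine

Text mining occupations from psychiatric clinical free text.

## The problem

Occupation is a core indicator of socioeconomic position and a key factor in
recovery from mental illness, yet electronic health records rarely capture
it in coded form: a structured occupational-status field is typically
populated for only a small minority of patients (on the order of 14%).
Clinicians do describe occupations — the patient's, their relatives', and
their own colleagues' — in narrative *personal history* sections of
psychiatric assessments. `occmine` is a pipeline for extracting those
occupation mentions from free text, attributing each one to its holder, and
turning the result into patient-level occupation records for epidemiological
analysis of who does and does not have occupation recorded.

## The method

The pipeline runs per document, in order:

1. **Age gate** — documents of patients under 16 never enter a corpus.
2. **Section extraction** — line-anchored, case-insensitive header rules
   locate personal-history sections ("Personal history", "Social history",
   …) running to the next recognized clinical header.
3. **Mention detection** — two arms used in combination: case-insensitive
   longest-match against an occupation gazetteer (~150 titles, descriptions
   and status terms; every hit carries a normalized label), and a
   linear-chain **conditional random field** over BIO tags with lexical,
   shape, gazetteer, cue and section features in a ±2 token window, which
   recovers out-of-lexicon occupations from context. Overlaps resolve
   longer-span-wins, gazetteer on ties; CRF-only spans with no
   normalization get the label `other`.
4. **Relation classification** — each mention is attributed to
   `patient`, `family`, `clinician` or `other_person` by a linear **SVM**
   over context features (preceding pronoun, kinship cue, clinician cue,
   section membership, sentence position), with cue rules taking
   precedence: a clinician cue forces `clinician`, a kinship cue forces
   `family`.
5. **Healthcare filter** — any health/social-care occupation still
   attributed to the patient is re-labelled as clinician-held (re-labelled,
   not deleted, so the output stays auditable). Clinician names in notes
   are the dominant false-positive mode; the pipeline consequently never
   outputs a patient-held healthcare occupation, a documented limitation.

Evaluation uses the strict criterion — a predicted annotation is a true
positive only if span **and** relation are exact — with micro-averaged
precision P = TP/(TP+FP) and recall R = TP/(TP+FN), plus Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) for annotator agreement. Patient-level profiles
merge extractions with the structured field; `occupation recorded` (either
source) is then modelled with crude, service-contact-adjusted and fully
adjusted logistic regressions with Wald CIs and likelihood-ratio tests.

Because real clinical text cannot be shipped, the package includes a
seeded, template-based synthetic-corpus generator that emulates the
statistical structure the pipeline assumes — personal-history sections,
family and clinician mentions, clinician "traps" ("Seen by Dr Patel,
consultant psychiatrist"), distractor idioms ("working on his anxiety"),
status-dominated occupation frequencies, and ~14% structured-field
completeness — with every gold span written from the same source as the
text.

## Worked example

```python
from occmine import (SynthConfig, generate_corpus, split_corpus,
                     default_gazetteer, default_healthcare_filter,
                     train_mention_model, train_relation_model)
from occmine.pipeline import extract_document
from occmine.types import ClinicalDocument, DocType

corpus, _, _ = generate_corpus(SynthConfig(n_patients=150, seed=2))
corpus = split_corpus(corpus, 100, 15, 35, seed=3)
gaz = default_gazetteer()
mm = train_mention_model(corpus, gaz, seed=4)
rm = train_relation_model(corpus, seed=5)

note = ClinicalDocument(
    doc_id="demo", patient_id="p0", doc_type=DocType.EVENT,
    patient_age_at_doc=34,
    text=("Seen by Dr Okafor, consultant psychiatrist.\n"
          "Personal History:\n"
          "He works as a panel beater. His wife is a teacher. "
          "He has been working on his anxiety.\n"
          "Plan:\nContinue support.\n"))
for a in extract_document(note, mm, rm, gaz, default_healthcare_filter()):
    print(a.span.start, a.span.end, repr(a.surface), a.label, a.relation.value)
```

prints

```
19 42 'consultant psychiatrist' psychiatrist clinician
76 88 'panel beater' other patient
104 111 'teacher' teacher family
```

The clinician's occupation is attributed to the clinician (not the
patient), the out-of-lexicon "panel beater" is recovered by the CRF from
context (label `other`: it has no gazetteer normalization), the wife's
occupation goes to the family member, and the "working on his anxiety"
idiom yields nothing. Runnable narrative scripts, one per capability, live
in `examples/`.

## Command-line interface

A thin CLI mirrors the pipeline stages:

```bash
occmine synth --out corpus_dir --seed 1
occmine train --corpus corpus_dir --out models --seed 1
occmine extract --corpus corpus_dir --models models --out run1
occmine evaluate --gold corpus_dir --pred run1 --mode strict_span_and_relation
occmine run-all --out everything --seed 1
```

`occmine extract --no-filter` reproduces the pre-filter condition;
`occmine agree` computes inter-annotator kappas between two annotation
directories.
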