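"""Score predicted annotations against gold and compute Cohen's kappa.

Precision/recall use the strict criterion: span AND relation must both be
exact for a true positive.  Kappa is shown on a hand-sized agreement table.
"""

from occmine import (
    MatchMode,
    Scope,
    SynthConfig,
    default_gazetteer,
    default_healthcare_filter,
    generate_corpus,
    kappa_from_table,
    precision_recall,
    split_corpus,
    train_mention_model,
    train_relation_model,
)
from occmine.pipeline import extract_document
from occmine.types import Split

corpus, _, _ = generate_corpus(SynthConfig(n_patients=80, seed=6))
corpus = split_corpus(corpus, 50, 15, 60, seed=7)
gaz = default_gazetteer()
mention_model = train_mention_model(corpus, gaz, seed=8)
relation_model = train_relation_model(corpus, seed=9)

test_docs = corpus.docs_in(Split.TEST)
gold = {d.doc_id: corpus.annotations_for(d.doc_id) for d in test_docs}
pred = {d.doc_id: extract_document(d, mention_model, relation_model, gaz,
                                   default_healthcare_filter())
        for d in test_docs}

for scope in Scope:
    r = precision_recall(gold, pred, MatchMode.STRICT, scope)
    print(f"{scope.value:15} precision={r.precision:.3f} "
          f"recall={r.recall:.3f} (tp={r.tp} fp={r.fp} fn={r.fn})")

# chance-corrected agreement on a 2x2 decision table: observed agreement
# 0.80, chance agreement 0.52, kappa (0.80-0.52)/(1-0.52)
print("kappa for table (50,10;10,30):",
      round(kappa_from_table([[50, 10], [10, 30]]), 4))
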