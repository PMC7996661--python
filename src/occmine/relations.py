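"""Relation classification and the healthcare-occupation filter.

Every detected occupation mention must be attributed to a holder: the
patient, a family member, a clinician involved in the patient's care, or
some other person.  Attribution combines a linear SVM over lexical-context
features with cue rules that take precedence (clinician cue, then kinship
cue): clinician names in notes are the dominant false-positive mode, so the
rules err on the side of not crediting the patient.

The healthcare filter is the final safety net: any health/social-care
occupation still attributed to the patient is re-labelled as clinician-held.
The filter re-labels rather than deletes, so clinician-occupation
extractions remain available for audit.
"""

from __future__ import annotations

import dataclasses
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .mentions import CLINICIAN_CUES, _kinship_set
from .sections import SectionSpan, extract_personal_history, in_any_section
from .tokenizer import Token, sentence_start_index, tokenize
from .types import (
    ClinicalDocument,
    GoldCorpus,
    OccupationAnnotation,
    Relation,
    Split,
)

logger = logging.getLogger(__name__)

RELATION_LABELS = [r.value for r in Relation]

PRONOUNS = frozenset({"he", "she", "they"})

CUE_WINDOW = 5          # tokens to the left scanned for kinship/clinician cues
CONFIDENCE_FLOOR = 0.4  # below this the positional default applies
MAX_SENT_DISTANCE = 10  # distance-to-sentence-start values are capped here


def featurize_relation(mention: OccupationAnnotation, doc: ClinicalDocument,
                       sections: list[SectionSpan],
                       tokens: Optional[list[Token]] = None) -> dict:
    """Deterministic feature dict for one mention in its document context."""
    if tokens is None:
        tokens = tokenize(doc.text)
    kinship = _kinship_set()

    before = [t for t in tokens if t.span.end <= mention.span.start]
    sent_start = sentence_start_index(doc.text, mention.span.start)
    in_sentence = [t for t in before if t.span.start >= sent_start]

    pronoun = "none"
    for tok in reversed(in_sentence):
        if tok.lower in PRONOUNS:
            pronoun = tok.lower
            break

    window = before[-CUE_WINDOW:]
    kin_cue = any(t.lower in kinship for t in window)
    clin_cue = any(t.lower in CLINICIAN_CUES for t in window)

    return {
        "pronoun": pronoun,
        "kin_cue": kin_cue,
        "clin_cue": clin_cue,
        "in_section": in_any_section(mention.span.start, sections),
        "sent_distance": min(len(in_sentence), MAX_SENT_DISTANCE),
    }


@dataclass
class RelationModel:
    """Linear SVM relation classifier with training metadata.

    Probability-like scores are a softmax over the decision-function margins
    (one-vs-rest); they sum to 1 per mention.
    """

    vectorizer: DictVectorizer
    svm: LinearSVC
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def labels_(self) -> list[str]:
        return list(self.svm.classes_)

    def scores(self, features: dict) -> dict[str, float]:
        x = self.vectorizer.transform([features])
        margins = self.svm.decision_function(x)[0]
        if np.ndim(margins) == 0:  # binary: one margin for classes_[1]
            margins = np.array([-float(margins), float(margins)])
        z = np.exp(margins - np.max(margins))
        probs = z / z.sum()
        return dict(zip(self.svm.classes_, probs))

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RelationModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a RelationModel")
        return model


def train_relation_model(corpus: GoldCorpus, seed: int = 0,
                         split: Split = Split.TRAIN,
                         C: float = 1.0) -> RelationModel:
    """Train the SVM on gold mentions of the corpus' training split."""
    feats: list[dict] = []
    labels: list[str] = []
    for doc in sorted(corpus.docs_in(split), key=lambda d: d.doc_id):
        sections = extract_personal_history(doc)
        tokens = tokenize(doc.text)
        for ann in corpus.annotations_for(doc.doc_id):
            if ann.relation is None:
                continue
            feats.append(featurize_relation(ann, doc, sections, tokens))
            labels.append(ann.relation.value)
    if not feats:
        raise ValueError("no gold mentions with relations in the training split")
    if len(set(labels)) < 2:
        raise ValueError(
            f"degenerate training split: single relation label {labels[0]!r}")

    vectorizer = DictVectorizer(sparse=False)  # feature space is tiny
    X = vectorizer.fit_transform(feats)
    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(X, labels)
    return RelationModel(vectorizer=vectorizer, svm=svm, seed=seed,
                         metadata={"n_mentions": len(labels), "C": C})


def classify_relation(mention: OccupationAnnotation, doc: ClinicalDocument,
                      sections: list[SectionSpan], model: RelationModel,
                      rules_enabled: bool = True,
                      tokens: Optional[list[Token]] = None) -> Relation:
    """Assign the relation for one mention.

    Precedence: clinician cue > kinship cue > model prediction (when its
    top score reaches the confidence floor) > positional default (patient
    inside a personal-history section, other_person outside).
    """
    features = featurize_relation(mention, doc, sections, tokens)
    if rules_enabled and features["clin_cue"]:
        return Relation.CLINICIAN
    if rules_enabled and features["kin_cue"]:
        return Relation.FAMILY
    scores = model.scores(features)
    top_label = max(scores, key=lambda k: (scores[k], k))
    if scores[top_label] >= CONFIDENCE_FLOOR:
        return Relation(top_label)
    return Relation.PATIENT if features["in_section"] else Relation.OTHER_PERSON


def classify_relations(doc: ClinicalDocument,
                       mentions: list[OccupationAnnotation],
                       model: RelationModel,
                       sections: Optional[list[SectionSpan]] = None,
                       rules_enabled: bool = True) -> list[OccupationAnnotation]:
    """Relation-classify every mention of a document."""
    if sections is None:
        sections = extract_personal_history(doc)
    tokens = tokenize(doc.text)
    return [
        dataclasses.replace(
            m, relation=classify_relation(m, doc, sections, model,
                                          rules_enabled, tokens))
        for m in mentions
    ]


def apply_healthcare_filter(
    annotations: Iterable[OccupationAnnotation],
    filter_labels: Iterable[str],
) -> list[OccupationAnnotation]:
    """Re-assign patient-held healthcare occupations to the clinician.

    Nothing is deleted: an annotation whose label is on the filter list and
    whose relation is ``patient`` comes back with relation ``clinician``;
    everything else is unchanged.  Idempotent.
    """
    filter_set = {lab.lower() for lab in filter_labels}
    if not filter_set:
        logger.warning("healthcare filter list is empty; filter is a no-op")
    out = []
    for ann in annotations:
        if ann.relation is Relation.PATIENT and ann.label in filter_set:
            ann = dataclasses.replace(ann, relation=Relation.CLINICIAN)
        out.append(ann)
    return out
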