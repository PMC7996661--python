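"""Relation classification, cue-rule precedence and the healthcare filter."""

import itertools

import pytest

from occmine.relations import (
    CONFIDENCE_FLOOR,
    apply_healthcare_filter,
    classify_relation,
    featurize_relation,
    train_relation_model,
)
from occmine.resources import default_healthcare_filter
from occmine.sections import extract_personal_history
from occmine.types import (
    ClinicalDocument,
    DocType,
    GoldCorpus,
    MentionKind,
    OccupationAnnotation,
    Relation,
    Split,
    TextSpan,
)


def _doc(text):
    return ClinicalDocument(doc_id="d", patient_id="p", doc_type=DocType.EVENT,
                            text=text, patient_age_at_doc=40)


def _mention(doc, surface, label=None):
    start = doc.text.index(surface)
    return OccupationAnnotation(
        span=TextSpan(start, start + len(surface)), surface=surface,
        mention_kind=MentionKind.TITLE, label=label or surface.lower())


class TestFeatures:
    def test_kinship_cue(self):
        doc = _doc("Mother is a teacher.")
        feats = featurize_relation(_mention(doc, "teacher"), doc, [])
        assert feats["kin_cue"] is True
        assert feats["clin_cue"] is False

    def test_clinician_cue(self):
        doc = _doc("Seen by Dr Smith, consultant psychiatrist.")
        feats = featurize_relation(_mention(doc, "psychiatrist"), doc, [])
        assert feats["clin_cue"] is True

    def test_preceding_pronoun_within_sentence(self):
        doc = _doc("He was tired. She works as a nurse.")
        feats = featurize_relation(_mention(doc, "nurse"), doc, [])
        assert feats["pronoun"] == "she"

    def test_determinism(self):
        doc = _doc("Her husband is an accountant.")
        m = _mention(doc, "accountant")
        assert featurize_relation(m, doc, []) == featurize_relation(m, doc, [])


class _StubModel:
    """Duck-typed stand-in whose scores are fixed, for rule-precedence tests."""

    def __init__(self, label, confidence=0.9):
        self.label = label
        self.confidence = confidence

    def scores(self, features):
        rest = (1 - self.confidence) / 3
        return {lab: (self.confidence if lab == self.label else rest)
                for lab in ("patient", "family", "clinician", "other_person")}


class TestPrecedence:
    def test_kinship_override(self, trained):
        doc = _doc("Personal History:\nher husband is an accountant.\n")
        sections = extract_personal_history(doc)
        rel = classify_relation(_mention(doc, "accountant"), doc, sections,
                                trained.relation_model)
        assert rel is Relation.FAMILY

    def test_clinician_override(self, trained):
        doc = _doc("reviewed by Dr A, psychiatrist.")
        rel = classify_relation(_mention(doc, "psychiatrist"), doc, [],
                                trained.relation_model)
        assert rel is Relation.CLINICIAN

    def test_rules_disabled_leaves_model_label(self):
        doc = _doc("her husband is an accountant.")
        rel = classify_relation(_mention(doc, "accountant"), doc, [],
                                _StubModel("patient"), rules_enabled=False)
        assert rel is Relation.PATIENT

    def test_precedence_truth_table(self):
        """Exhaustive check of cue flags x model label against the stated
        precedence: clinician cue > kinship cue > confident model >
        positional default."""
        for kin, clin, in_sec, model_label in itertools.product(
                [False, True], [False, True], [False, True],
                ["patient", "family", "clinician", "other_person"]):
            pre = "seen by " if clin else ""
            kin_txt = "mother " if kin else ""
            body = f"{pre}{kin_txt}the builder."
            if in_sec:
                text = "Personal History:\n" + body + "\n"
            else:
                text = body
            doc = _doc(text)
            sections = extract_personal_history(doc)
            mention = _mention(doc, "builder")

            # expected outcome per the published precedence
            if clin:
                expected = Relation.CLINICIAN
            elif kin:
                expected = Relation.FAMILY
            else:
                expected = Relation(model_label)

            got = classify_relation(mention, doc, sections,
                                    _StubModel(model_label, confidence=0.9))
            assert got is expected, (kin, clin, in_sec, model_label)

    def test_low_confidence_falls_back_to_position(self):
        assert CONFIDENCE_FLOOR == 0.4
        in_doc = _doc("Personal History:\nthe builder arrived.\n")
        sections = extract_personal_history(in_doc)
        low = _StubModel("clinician", confidence=0.3)
        assert classify_relation(_mention(in_doc, "builder"), in_doc,
                                 sections, low) is Relation.PATIENT
        out_doc = _doc("the builder arrived.")
        assert classify_relation(_mention(out_doc, "builder"), out_doc,
                                 [], low) is Relation.OTHER_PERSON


class TestTraining:
    def test_single_label_split_is_degenerate(self):
        doc = _doc("Personal History:\nHe is a builder.\n")
        ann = OccupationAnnotation(
            span=TextSpan(doc.text.index("builder"),
                          doc.text.index("builder") + 7),
            surface="builder", mention_kind=MentionKind.TITLE,
            label="builder", relation=Relation.PATIENT)
        corpus = GoldCorpus(documents=[doc], annotations={"d": [ann]},
                            split={"d": Split.TRAIN})
        with pytest.raises(ValueError, match="degenerate"):
            train_relation_model(corpus)

    def test_empty_mention_set_is_error(self):
        doc = _doc("nothing here")
        corpus = GoldCorpus(documents=[doc], annotations={},
                            split={"d": Split.TRAIN})
        with pytest.raises(ValueError, match="no gold mentions"):
            train_relation_model(corpus)

    def test_same_seed_identical_scores(self, trained):
        m1 = train_relation_model(trained.corpus, seed=3)
        m2 = train_relation_model(trained.corpus, seed=3)
        feats = {"pronoun": "he", "kin_cue": False, "clin_cue": False,
                 "in_section": True, "sent_distance": 4}
        assert m1.scores(feats) == m2.scores(feats)

    def test_scores_sum_to_one(self, trained):
        feats = {"pronoun": "none", "kin_cue": False, "clin_cue": False,
                 "in_section": False, "sent_distance": 2}
        assert sum(trained.relation_model.scores(feats).values()) == \
            pytest.approx(1.0)

    def test_macro_recall_beats_chance_on_validation(self, trained):
        """Label-averaged recall on held-out gold mentions > 0.25."""
        corpus = trained.corpus
        recalls = {}
        hits: dict[str, int] = {}
        totals: dict[str, int] = {}
        for doc in corpus.docs_in(Split.VALIDATION):
            sections = extract_personal_history(doc)
            for ann in corpus.annotations_for(doc.doc_id):
                got = classify_relation(ann, doc, sections,
                                        trained.relation_model)
                lab = ann.relation.value
                totals[lab] = totals.get(lab, 0) + 1
                hits[lab] = hits.get(lab, 0) + (got is ann.relation)
        recalls = {lab: hits[lab] / totals[lab] for lab in totals}
        assert sum(recalls.values()) / len(recalls) > 0.25


class TestHealthcareFilter:
    def _ann(self, label, relation):
        return OccupationAnnotation(span=TextSpan(0, 5), surface="xxxxx",
                                    mention_kind=MentionKind.TITLE,
                                    label=label, relation=relation)

    def test_patient_healthcare_relabelled_to_clinician(self):
        out = apply_healthcare_filter(
            [self._ann("psychiatrist", Relation.PATIENT)],
            default_healthcare_filter())
        assert out[0].relation is Relation.CLINICIAN
        assert out[0].label == "psychiatrist"  # label untouched

    def test_non_healthcare_unchanged(self):
        ann = self._ann("builder", Relation.PATIENT)
        assert apply_healthcare_filter([ann], default_healthcare_filter()) \
            == [ann]

    def test_non_patient_healthcare_unchanged(self):
        ann = self._ann("nurse", Relation.FAMILY)
        assert apply_healthcare_filter([ann], default_healthcare_filter()) \
            == [ann]

    def test_nothing_deleted_and_idempotent(self):
        anns = [self._ann("nurse", Relation.PATIENT),
                self._ann("builder", Relation.PATIENT),
                self._ann("doctor", Relation.CLINICIAN)]
        filt = default_healthcare_filter()
        once = apply_healthcare_filter(anns, filt)
        assert len(once) == len(anns)
        assert apply_healthcare_filter(once, filt) == once

    def test_empty_filter_warns_and_is_noop(self, caplog):
        ann = self._ann("nurse", Relation.PATIENT)
        with caplog.at_level("WARNING"):
            out = apply_healthcare_filter([ann], frozenset())
        assert out == [ann]
        assert any("empty" in r.message for r in caplog.records)
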