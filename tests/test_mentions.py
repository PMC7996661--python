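"""Gazetteer matching, featurization and the hybrid mention detector."""

import itertools

import pytest

from occmine.gazetteer import Gazetteer, GazetteerEntry, gazetteer_match
from occmine.mentions import (
    MentionModel,
    bio_to_spans,
    detect_mentions,
    featurize,
    resolve_overlaps,
    spans_to_bio,
    train_mention_model,
)
from occmine.resources import default_gazetteer
from occmine.sections import extract_personal_history
from occmine.tokenizer import tokenize
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


def _gaz(entries):
    out = {}
    for surface, (label, kind) in entries.items():
        out[tuple(surface.split())] = GazetteerEntry(
            label=label, kind=MentionKind(kind), is_status=False)
    return Gazetteer(entries=out)


class TestGazetteerMatch:
    def test_title_match(self):
        text = "he is a builder"
        anns = gazetteer_match(tokenize(text),
                               _gaz({"builder": ("builder", "title")}), text)
        assert len(anns) == 1
        assert anns[0].label == "builder"
        assert anns[0].mention_kind is MentionKind.TITLE
        assert anns[0].surface == "builder"

    def test_description_match(self):
        text = "construction work recently"
        anns = gazetteer_match(
            tokenize(text),
            _gaz({"construction": ("construction", "description")}), text)
        assert [a.mention_kind for a in anns] == [MentionKind.DESCRIPTION]

    def test_longest_match_wins(self):
        text = "she is a social worker now"
        gaz = _gaz({"social worker": ("social worker", "title"),
                    "worker": ("worker", "title")})
        anns = gazetteer_match(tokenize(text), gaz, text)
        assert [a.surface for a in anns] == ["social worker"]

    def test_case_insensitive(self):
        text = "BUILDER on site"
        anns = gazetteer_match(tokenize(text),
                               _gaz({"builder": ("builder", "title")}), text)
        assert [a.surface for a in anns] == ["BUILDER"]


class TestBioCodec:
    def test_round_trip_on_generated_docs(self, small_synth):
        corpus = small_synth.corpus
        for doc in corpus.documents[:80]:
            tokens = tokenize(doc.text)
            gold = corpus.annotations_for(doc.doc_id)
            spans = bio_to_spans(tokens, spans_to_bio(tokens, gold))
            assert spans == [a.span for a in sorted(
                gold, key=lambda a: a.span.start)]

    def test_dangling_I_opens_span(self):
        tokens = tokenize("one two")
        assert bio_to_spans(tokens, ["I", "O"]) == [TextSpan(0, 3)]


class TestFeaturize:
    def test_section_and_gazetteer_flags(self):
        doc = _doc("Personal History:\nHe is a builder.\n")
        tokens = tokenize(doc.text)
        sections = extract_personal_history(doc)
        feats = featurize(tokens, default_gazetteer(), sections)
        by_surface = dict(zip([t.surface for t in tokens], feats))
        assert "gaz" in by_surface["builder"]
        assert "sec" in by_surface["builder"]
        assert "sec" not in by_surface["Personal"]

    def test_determinism(self):
        doc = _doc("Her mother is a teacher.")
        tokens = tokenize(doc.text)
        f1 = featurize(tokens, default_gazetteer(), [])
        f2 = featurize(tokens, default_gazetteer(), [])
        assert f1 == f2
        assert "kin" in f1[1]  # "mother"


class TestOverlapResolution:
    def _cand(self, start, end, source):
        text = "x" * 40
        return (OccupationAnnotation(
            span=TextSpan(start, end), surface=text[start:end],
            mention_kind=MentionKind.TITLE, label="l"), source)

    @staticmethod
    def _oracle(candidates):
        """Independent naive selection: repeatedly scan for the best
        remaining candidate under the published rule and drop overlaps."""
        remaining = list(candidates)
        kept = []
        while remaining:
            best = None
            for item in remaining:
                if best is None:
                    best = item
                    continue
                a, sa = item
                b, sb = best
                key_a = (-len(a.span), 0 if sa == "gaz" else 1,
                         a.span.start, a.span.end)
                key_b = (-len(b.span), 0 if sb == "gaz" else 1,
                         b.span.start, b.span.end)
                if key_a < key_b:
                    best = item
            kept.append(best[0])
            remaining = [c for c in remaining
                         if c is not best and not c[0].span.overlaps(best[0].span)]
        return sorted(kept, key=lambda a: (a.span.start, a.span.end))

    def test_matches_oracle_on_all_small_configurations(self):
        import random

        rng = random.Random(0)
        for _ in range(300):
            n = rng.randint(0, 6)
            cands = []
            for _ in range(n):
                s = rng.randint(0, 30)
                e = s + rng.randint(1, 8)
                cands.append(self._cand(s, e, rng.choice(["gaz", "crf"])))
            assert resolve_overlaps(cands) == self._oracle(cands)

    def test_tie_prefers_gazetteer(self):
        g = self._cand(0, 5, "gaz")
        c = self._cand(0, 5, "crf")
        assert resolve_overlaps([c, g]) == [g[0]]
        assert resolve_overlaps([g, c]) == [g[0]]

    def test_longer_span_wins(self):
        long_crf = self._cand(0, 10, "crf")
        short_gaz = self._cand(2, 6, "gaz")
        assert resolve_overlaps([short_gaz, long_crf]) == [long_crf[0]]


class TestDetector:
    def test_empty_gazetteer_and_no_model_yield_nothing(self):
        doc = _doc("He works as a builder in construction.")
        assert detect_mentions(doc, None, Gazetteer(entries={})) == []

    def test_distractor_alone_yields_nothing(self, trained):
        doc = _doc("Personal History:\nHe has been working on his anxiety.\n")
        anns = detect_mentions(doc, trained.mention_model,
                               default_gazetteer())
        assert anns == []

    def test_simple_section_mention(self, trained):
        doc = _doc("Personal History:\nShe is a teacher.\n")
        anns = detect_mentions(doc, trained.mention_model, default_gazetteer())
        assert [a.label for a in anns] == ["teacher"]

    def test_detected_spans_never_overlap(self, trained):
        for anns in trained.predicted.values():
            for a, b in itertools.combinations(anns, 2):
                assert not a.span.overlaps(b.span)

    def test_tokenizer_version_mismatch_rejected(self, trained):
        import dataclasses

        stale = dataclasses.replace(trained.mention_model,
                                    tokenizer_version="something-else")
        with pytest.raises(ValueError, match="tokenizer"):
            detect_mentions(_doc("text"), stale, default_gazetteer())


class TestTraining:
    def test_zero_annotations_is_error(self):
        doc = _doc("no occupations here at all")
        corpus = GoldCorpus(documents=[doc], annotations={},
                            split={"d": Split.TRAIN})
        with pytest.raises(ValueError, match="no annotations"):
            train_mention_model(corpus, default_gazetteer())

    def test_same_seed_identical_predictions(self, trained):
        corpus = trained.corpus
        gaz = default_gazetteer()
        m1 = train_mention_model(corpus, gaz, seed=7, max_iterations=25)
        val_docs = corpus.docs_in(Split.VALIDATION)
        p1 = [detect_mentions(d, m1, gaz) for d in val_docs]
        m2 = train_mention_model(corpus, gaz, seed=7, max_iterations=25)
        p2 = [detect_mentions(d, m2, gaz) for d in val_docs]
        assert p1 == p2

    def test_model_round_trips_through_file(self, trained, tmp_path):
        path = tmp_path / "model.bin"
        trained.mention_model.save(path)
        loaded = MentionModel.load(path)
        doc = _doc("Personal History:\nHe works as a plumber.\n")
        assert detect_mentions(doc, loaded, default_gazetteer()) == \
            detect_mentions(doc, trained.mention_model, default_gazetteer())


class TestHybridBeatsGazetteerAlone:
    """The union property: CRF adds recall on out-of-lexicon mentions."""

    def _recall(self, corpus, predictions):
        from occmine.evaluation import MatchMode, precision_recall

        test_ids = [d.doc_id for d in corpus.docs_in(Split.TEST)]
        gold = {i: corpus.annotations_for(i) for i in test_ids}
        report = precision_recall(gold, {i: predictions[i] for i in test_ids},
                                  mode=MatchMode.SPAN_ONLY)
        return report.recall

    def test_hybrid_recall_at_least_gazetteer_only(self, trained):
        corpus = trained.corpus
        gaz = default_gazetteer()
        gaz_only = {d.doc_id: detect_mentions(d, None, gaz)
                    for d in corpus.documents}
        hybrid = {d.doc_id: [a for a in anns]
                  for d, anns in ((d, detect_mentions(d, trained.mention_model,
                                                      gaz))
                                  for d in corpus.documents)}
        r_gaz = self._recall(corpus, gaz_only)
        r_hybrid = self._recall(corpus, hybrid)
        assert r_hybrid >= r_gaz
        # out-of-lexicon mentions exist in this corpus, so the inequality
        # is strict: the trained arm genuinely adds recall
        assert r_hybrid > r_gaz
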