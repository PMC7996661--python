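"""Occupation-mention detection: gazetteer matching combined with a CRF.

The detector has two arms, used in combination:

* a rule-based arm — case-insensitive longest-match against the occupation
  gazetteer, which carries a normalization for every hit;
* a statistical arm — a linear-chain CRF over BIO tags, trained on gold
  spans, which can recover occupation mentions absent from the gazetteer
  from their lexical context.

Overlapping detections are resolved longer-span-wins; on a length tie the
gazetteer span is kept because it carries a normalized label.  CRF-only
spans with no gazetteer normalization receive the special label ``"other"``
(excluded from patient-level profiles downstream).
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .crf import LinearChainCRF
from .gazetteer import Gazetteer, gazetteer_hit_spans, gazetteer_match
from .sections import SectionSpan, extract_personal_history, in_any_section
from .tokenizer import TOKENIZER_VERSION, Token, tokenize
from .types import (
    OTHER_LABEL,
    ClinicalDocument,
    GoldCorpus,
    MentionKind,
    OccupationAnnotation,
    Split,
    TextSpan,
)

CLINICIAN_CUES = frozenset({"dr", "consultant", "cpn", "seen", "reviewed",
                            "assessed", "referred", "discussed"})

BIO_LABELS = ["O", "B", "I"]

FEATURE_WINDOW = 2


def _kinship_set() -> frozenset[str]:
    from .resources import kinship_terms

    return frozenset(kinship_terms())


def featurize(tokens: list[Token], gazetteer: Gazetteer,
              sections: list[SectionSpan],
              window: int = FEATURE_WINDOW) -> list[list[str]]:
    """Per-token feature strings: surface, shape, lexicon cues, section flag,
    and the same for neighbours within ``window`` tokens."""
    kinship = _kinship_set()
    gaz_flags = gazetteer_hit_spans(tokens, gazetteer)

    def base(i: int) -> list[str]:
        tok = tokens[i]
        feats = [f"w={tok.lower}"]
        if tok.is_capitalized:
            feats.append("cap")
        if tok.has_digit:
            feats.append("digit")
        if gaz_flags[i]:
            feats.append("gaz")
        if tok.lower in kinship:
            feats.append("kin")
        if tok.lower in CLINICIAN_CUES:
            feats.append("clin")
        if in_any_section(tok.span.start, sections):
            feats.append("sec")
        return feats

    cache = [base(i) for i in range(len(tokens))]
    out: list[list[str]] = []
    for i in range(len(tokens)):
        feats = ["bias"] + cache[i]
        for d in range(-window, window + 1):
            if d == 0:
                continue
            j = i + d
            if 0 <= j < len(tokens):
                feats.extend(f"{d:+d}:{f}" for f in cache[j])
            else:
                feats.append(f"{d:+d}:pad")
        out.append(feats)
    return out


def spans_to_bio(tokens: list[Token],
                 annotations: list[OccupationAnnotation]) -> list[str]:
    """BIO tags from gold spans; a token is inside a span if they overlap."""
    tags = ["O"] * len(tokens)
    for ann in sorted(annotations, key=lambda a: (a.span.start, a.span.end)):
        inside = [i for i, tok in enumerate(tokens) if tok.span.overlaps(ann.span)]
        for rank, i in enumerate(inside):
            if tags[i] == "O":
                tags[i] = "B" if rank == 0 else "I"
    return tags


def bio_to_spans(tokens: list[Token], tags: list[str]) -> list[TextSpan]:
    spans: list[TextSpan] = []
    start: Optional[int] = None
    end = 0
    for tok, tag in zip(tokens, tags):
        if tag == "B":
            if start is not None:
                spans.append(TextSpan(start, end))
            start, end = tok.span.start, tok.span.end
        elif tag == "I" and start is not None:
            end = tok.span.end
        elif tag == "I":  # dangling I opens a new span
            start, end = tok.span.start, tok.span.end
        else:
            if start is not None:
                spans.append(TextSpan(start, end))
                start = None
    if start is not None:
        spans.append(TextSpan(start, end))
    return spans


@dataclass
class MentionModel:
    """Trained CRF mention detector with its training metadata."""

    crf: LinearChainCRF
    tokenizer_version: str
    corpus_hash: str
    seed: int
    feature_window: int = FEATURE_WINDOW
    feature_description: str = (
        "surface/shape/gazetteer/kinship/clinician/section flags, "
        f"window ±{FEATURE_WINDOW}"
    )
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "MentionModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a MentionModel")
        return model


def corpus_hash(corpus: GoldCorpus) -> str:
    h = hashlib.sha256()
    for doc in sorted(corpus.documents, key=lambda d: d.doc_id):
        h.update(doc.doc_id.encode())
        h.update(doc.text.encode())
    return h.hexdigest()[:16]


def train_mention_model(corpus: GoldCorpus, gazetteer: Gazetteer,
                        seed: int = 0, split: Split = Split.TRAIN,
                        c2: float = 0.1,
                        max_iterations: int = 100) -> MentionModel:
    """Train the CRF on the corpus' training split.

    Raises on an empty split or a split with no annotations at all.
    """
    docs = corpus.docs_in(split)
    if not docs:
        raise ValueError(f"no documents in split {split.value!r}")
    n_ann = sum(len(corpus.annotations_for(d.doc_id)) for d in docs)
    if n_ann == 0:
        raise ValueError("training split contains no annotations")

    X: list[list[list[str]]] = []
    y: list[list[str]] = []
    for doc in sorted(docs, key=lambda d: d.doc_id):
        tokens = tokenize(doc.text)
        sections = extract_personal_history(doc)
        X.append(featurize(tokens, gazetteer, sections))
        y.append(spans_to_bio(tokens, corpus.annotations_for(doc.doc_id)))

    crf = LinearChainCRF(c2=c2, max_iterations=max_iterations)
    crf.fit(X, y, labels=BIO_LABELS)
    return MentionModel(
        crf=crf,
        tokenizer_version=TOKENIZER_VERSION,
        corpus_hash=corpus_hash(corpus),
        seed=seed,
        metadata={"n_train_docs": len(docs), "n_train_annotations": n_ann,
                  "c2": c2, "max_iterations": max_iterations},
    )


def resolve_overlaps(
    candidates: list[tuple[OccupationAnnotation, str]]
) -> list[OccupationAnnotation]:
    """Select a non-overlapping subset: longer span wins; on a length tie the
    gazetteer candidate beats the CRF one; remaining ties go left-to-right."""

    def priority(item):
        ann, source = item
        return (-len(ann.span), 0 if source == "gaz" else 1,
                ann.span.start, ann.span.end)

    kept: list[OccupationAnnotation] = []
    for ann, _source in sorted(candidates, key=priority):
        if not any(ann.span.overlaps(k.span) for k in kept):
            kept.append(ann)
    return sorted(kept, key=lambda a: (a.span.start, a.span.end))


def detect_mentions(doc: ClinicalDocument,
                    model: Optional[MentionModel],
                    gazetteer: Gazetteer,
                    sections: Optional[list[SectionSpan]] = None,
                    ) -> list[OccupationAnnotation]:
    """Run both detector arms over a document and merge their output.

    Relations are left unset.  ``model`` may be ``None`` (gazetteer arm
    only, e.g. before any training has happened).
    """
    if sections is None:
        sections = extract_personal_history(doc)
    tokens = tokenize(doc.text)

    candidates: list[tuple[OccupationAnnotation, str]] = [
        (ann, "gaz") for ann in gazetteer_match(tokens, gazetteer, doc.text)
    ]

    if model is not None and model.crf.labels_ is not None:
        if model.tokenizer_version != TOKENIZER_VERSION:
            raise ValueError(
                f"model was trained with tokenizer "
                f"{model.tokenizer_version!r}, running {TOKENIZER_VERSION!r}")
        feats = featurize(tokens, gazetteer, sections,
                          window=model.feature_window)
        tags = model.crf.predict_single(feats)
        for span in bio_to_spans(tokens, tags):
            surface = doc.text[span.start:span.end]
            entry = gazetteer.lookup_surface(surface)
            if entry is not None:
                label, kind = entry.label, entry.kind
            else:
                label, kind = OTHER_LABEL, MentionKind.TITLE
            candidates.append((
                OccupationAnnotation(span=span, surface=surface,
                                     mention_kind=kind, label=label),
                "crf",
            ))

    return resolve_overlaps(candidates)
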