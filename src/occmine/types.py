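"""Core domain types for occupation text mining.

The unit of work is a clinical free-text document with patient metadata; the
unit of output is an occupation annotation: a character span plus a normalized
occupation label plus a *relation* saying whose occupation it is (the
patient's, a family member's, a clinician's, or someone else's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

MIN_PATIENT_AGE = 16  # documents of younger patients never enter a corpus


class DocType(str, Enum):
    ATTACHMENT = "attachment"
    EVENT = "event"
    DISCHARGE_SUMMARY = "discharge_summary"
    RISK_ASSESSMENT = "risk_assessment"
    OTHER = "other"


class MentionKind(str, Enum):
    TITLE = "title"          # e.g. "builder"
    DESCRIPTION = "description"  # e.g. "construction"


class Relation(str, Enum):
    PATIENT = "patient"
    FAMILY = "family"
    CLINICIAN = "clinician"
    OTHER_PERSON = "other_person"


class Split(str, Enum):
    TRAIN = "train"
    VALIDATION = "validation"
    TEST = "test"
    UNASSIGNED = "unassigned"


#: label given to detected mentions that cannot be normalized to a known
#: occupation; excluded from patient-level profiles downstream.
OTHER_LABEL = "other"


@dataclass(frozen=True, order=True)
class TextSpan:
    """Half-open character interval [start, end) over Unicode code points."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ClinicalDocument:
    doc_id: str
    patient_id: str
    doc_type: DocType
    text: str
    patient_age_at_doc: int

    def __post_init__(self) -> None:
        if self.patient_age_at_doc < MIN_PATIENT_AGE:
            raise ValueError(
                f"document {self.doc_id}: patient age "
                f"{self.patient_age_at_doc} is below the age gate "
                f"({MIN_PATIENT_AGE})"
            )


@dataclass(frozen=True, order=True)
class OccupationAnnotation:
    """A two-part occupation markup: the mention span and its relation.

    ``surface`` must equal the document text slice; ``label`` is the
    lowercase canonical occupation (or ``"other"`` when no normalization
    exists); ``relation`` may be ``None`` for freshly detected mentions that
    have not yet passed relation classification.
    """

    span: TextSpan
    surface: str
    mention_kind: MentionKind
    label: str
    relation: Optional[Relation] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("annotation label must be non-empty")

    def validate_against(self, text: str) -> None:
        if self.span.end > len(text):
            raise ValueError(
                f"span {self.span} exceeds text length {len(text)}"
            )
        actual = text[self.span.start:self.span.end]
        if actual != self.surface:
            raise ValueError(
                f"surface mismatch at {self.span}: "
                f"annotation says {self.surface!r}, text has {actual!r}"
            )


@dataclass
class GoldCorpus:
    """Documents paired with gold annotation sets and train/val/test splits."""

    documents: list[ClinicalDocument]
    annotations: dict[str, list[OccupationAnnotation]] = field(default_factory=dict)
    split: dict[str, Split] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_id in corpus")
        known = set(ids)
        for doc_id in self.annotations:
            if doc_id not in known:
                raise ValueError(f"annotations reference unknown doc_id {doc_id!r}")
        for doc_id in self.split:
            if doc_id not in known:
                raise ValueError(f"split references unknown doc_id {doc_id!r}")

    def doc(self, doc_id: str) -> ClinicalDocument:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    def docs_in(self, split: Split) -> list[ClinicalDocument]:
        return [d for d in self.documents
                if self.split.get(d.doc_id, Split.UNASSIGNED) is split]

    def annotations_for(self, doc_id: str) -> list[OccupationAnnotation]:
        return self.annotations.get(doc_id, [])
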