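"""Reading and writing documents, standoff annotations and sidecar tables.

Formats (all plain text, UTF-8):

* documents — one ``.txt`` file per document; sidecar metadata TSV with header
  ``doc_id  patient_id  doc_type  age``;
* annotations — one ``.ann`` per document in a BRAT-style dialect::

      T1<TAB>Occupation 10 17<TAB>builder
      A1<TAB>Relation T1 patient
      A2<TAB>Kind T1 title

* gazetteer — TSV ``surface  normalized_label  kind  is_status``;
* healthcare filter — one normalized label per line, ``#`` comments allowed;
* structured occupational-status field — TSV ``patient_id  status_code``
  with codes 1–13.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .types import (
    MIN_PATIENT_AGE,
    ClinicalDocument,
    DocType,
    MentionKind,
    OccupationAnnotation,
    Relation,
    TextSpan,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["doc_id", "patient_id", "doc_type", "age"]


def read_documents(path: str | Path, metadata_path: str | Path) -> list[ClinicalDocument]:
    """Read a directory of ``.txt`` documents with their metadata table.

    Documents whose patient is below the age gate (16 years) are excluded
    and counted in the log.  A text file without a metadata row is a hard
    error naming the doc_id.
    """
    path = Path(path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata table missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("doc_id", verify_integrity=True)

    docs: list[ClinicalDocument] = []
    n_gated = 0
    for txt_file in sorted(path.glob("*.txt")):
        doc_id = txt_file.stem
        if doc_id not in meta.index:
            raise ValueError(f"no metadata row for document {doc_id!r}")
        row = meta.loc[doc_id]
        age = int(row["age"])
        if age < MIN_PATIENT_AGE:
            n_gated += 1
            continue
        docs.append(
            ClinicalDocument(
                doc_id=doc_id,
                patient_id=str(row["patient_id"]),
                doc_type=DocType(row["doc_type"]),
                text=txt_file.read_text(encoding="utf-8"),
                patient_age_at_doc=age,
            )
        )
    if n_gated:
        logger.info("age gate excluded %d document(s) under %d years",
                    n_gated, MIN_PATIENT_AGE)
    return docs


def write_documents(docs: Iterable[ClinicalDocument], path: str | Path,
                    metadata_path: str | Path) -> None:
    """Write one ``.txt`` per document plus the metadata TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        rows.append((doc.doc_id, doc.patient_id, doc.doc_type.value,
                     doc.patient_age_at_doc))
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False)


def _annotation_sort_key(a: OccupationAnnotation):
    return (a.span.start, a.span.end,
            a.relation.value if a.relation is not None else "")


def write_standoff(annotations: Iterable[OccupationAnnotation],
                   path: str | Path) -> None:
    """Serialize annotations, deterministically ordered by (start, end, relation)."""
    lines: list[str] = []
    ordered = sorted(annotations, key=_annotation_sort_key)
    attr_counter = 0
    for i, ann in enumerate(ordered, start=1):
        lines.append(f"T{i}\tOccupation {ann.span.start} {ann.span.end}\t{ann.surface}")
        if ann.relation is not None:
            attr_counter += 1
            lines.append(f"A{attr_counter}\tRelation T{i} {ann.relation.value}")
        attr_counter += 1
        lines.append(f"A{attr_counter}\tKind T{i} {ann.mention_kind.value}")
        attr_counter += 1
        lines.append(f"A{attr_counter}\tLabel T{i} {ann.label}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def read_standoff(path: str | Path, doc: ClinicalDocument) -> list[OccupationAnnotation]:
    """Parse a standoff file, validating every span against the document text.

    Identical duplicate annotations are collapsed silently; conflicting
    annotations on the same span (different relation) are kept.  A malformed
    line is a hard error carrying its line number; a surface mismatch with
    the document text is an error, never a warning.
    """
    spans: dict[str, tuple[TextSpan, str]] = {}
    relations: dict[str, Relation] = {}
    kinds: dict[str, MentionKind] = {}
    labels: dict[str, str] = {}

    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        try:
            if line.startswith("T"):
                tid, middle, surface = line.split("\t")
                kind_tag, start_s, end_s = middle.split(" ")
                if kind_tag != "Occupation":
                    raise ValueError(f"unknown span type {kind_tag!r}")
                spans[tid] = (TextSpan(int(start_s), int(end_s)), surface)
            elif line.startswith("A"):
                _, rest = line.split("\t")
                attr, tid, value = rest.split(" ", 2)
                if attr == "Relation":
                    relations[tid] = Relation(value)
                elif attr == "Kind":
                    kinds[tid] = MentionKind(value)
                elif attr == "Label":
                    labels[tid] = value
                else:
                    raise ValueError(f"unknown attribute {attr!r}")
            else:
                raise ValueError("line must start with T or A")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc

    annotations: list[OccupationAnnotation] = []
    for tid, (span, surface) in spans.items():
        if tid not in kinds or tid not in labels:
            raise ValueError(f"{path}: span {tid} missing Kind or Label attribute")
        ann = OccupationAnnotation(
            span=span, surface=surface, mention_kind=kinds[tid],
            label=labels[tid], relation=relations.get(tid),
        )
        ann.validate_against(doc.text)
        annotations.append(ann)

    # collapse exact duplicates, keep conflicting ones; deterministic order
    return sorted(set(annotations), key=_annotation_sort_key)


def read_gazetteer_table(path: str | Path) -> pd.DataFrame:
    """Read a gazetteer TSV (surface, normalized_label, kind, is_status)."""
    df = pd.read_csv(path, sep="\t", dtype={"surface": str, "normalized_label": str,
                                            "kind": str, "is_status": int})
    expected = {"surface", "normalized_label", "kind", "is_status"}
    if set(df.columns) != expected:
        raise ValueError(f"gazetteer columns {list(df.columns)} != {sorted(expected)}")
    if (df["normalized_label"].str.len() == 0).any():
        raise ValueError("gazetteer entry with empty label")
    return df


def read_filter_list(path: str | Path) -> set[str]:
    """Read the healthcare-occupation filter: one lowercase label per line."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return out


def read_structured_fields(path: str | Path) -> pd.DataFrame:
    """Read the coded occupational-status table (patient_id, status_code 1-13)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "status_code": int})
    bad = df[(df["status_code"] < 1) | (df["status_code"] > 13)]
    if len(bad):
        raise ValueError(f"status_code outside 1-13 for patients "
                         f"{bad['patient_id'].tolist()[:5]}")
    return df


def write_corpus(corpus, out_dir: str | Path,
                 structured: Optional[pd.DataFrame] = None) -> None:
    """Write a whole corpus: txt files, ann files, metadata and split tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_documents(corpus.documents, out_dir / "docs", out_dir / "metadata.tsv")
    ann_dir = out_dir / "ann"
    ann_dir.mkdir(exist_ok=True)
    for doc in corpus.documents:
        write_standoff(corpus.annotations_for(doc.doc_id),
                       ann_dir / f"{doc.doc_id}.ann")
    split_rows = [(doc_id, split.value) for doc_id, split in sorted(corpus.split.items())]
    pd.DataFrame(split_rows, columns=["doc_id", "split"]).to_csv(
        out_dir / "splits.tsv", sep="\t", index=False)
    if structured is not None:
        structured.to_csv(out_dir / "structured_fields.tsv", sep="\t", index=False)


def read_corpus(out_dir: str | Path):
    """Read back a corpus written by :func:`write_corpus`."""
    from .types import GoldCorpus, Split

    out_dir = Path(out_dir)
    docs = read_documents(out_dir / "docs", out_dir / "metadata.tsv")
    annotations = {}
    for doc in docs:
        ann_path = out_dir / "ann" / f"{doc.doc_id}.ann"
        if ann_path.exists():
            annotations[doc.doc_id] = read_standoff(ann_path, doc)
    split: dict[str, Split] = {}
    split_path = out_dir / "splits.tsv"
    if split_path.exists():
        df = pd.read_csv(split_path, sep="\t", dtype=str)
        split = {r.doc_id: Split(r.split) for r in df.itertuples()}
    return GoldCorpus(documents=docs, annotations=annotations, split=split)
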