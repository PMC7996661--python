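"""End-to-end orchestration: read → age gate → sections → mention detection
→ relation classification → healthcare filter → write, plus the one-command
synthesize/train/evaluate/profile run used for smoke testing a deployment.

Every run writes a resolved copy of its configuration and the hashes of its
corpus and model artifacts beside its outputs, and logs per-stage counters.
The filter stage re-labels and never deletes, so annotation counts are
conserved across it.  One global seed fans out to per-stage seeds by fixed
offsets so stages can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as occ_io
from .cohort import (
    build_profiles,
    distinct_count_summary,
    fit_association_models,
    top_occupations,
)
from .evaluation import MatchMode, Scope, precision_recall
from .gazetteer import Gazetteer
from .mentions import MentionModel, corpus_hash, detect_mentions, train_mention_model
from .relations import (
    RelationModel,
    apply_healthcare_filter,
    classify_relations,
    train_relation_model,
)
from .resources import default_gazetteer, default_healthcare_filter
from .sections import DEFAULT_PH_HEADERS, DEFAULT_STOP_HEADERS, extract_personal_history
from .synth import SynthConfig, generate_corpus, split_corpus
from .types import ClinicalDocument, GoldCorpus, OccupationAnnotation, Relation, Split

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the one global seed
SEED_SYNTH, SEED_SPLIT, SEED_MENTION, SEED_RELATION = 0, 1, 2, 3


@dataclass
class PipelineConfig:
    corpus_dir: str = "corpus"
    out_dir: str = "out"
    mention_model_path: str = "mention_model.bin"
    relation_model_path: str = "relation_model.bin"
    gazetteer_path: Optional[str] = None      # None -> packaged default
    healthcare_filter_path: Optional[str] = None
    seed: int = 0
    ph_headers: list[str] = field(default_factory=lambda: list(DEFAULT_PH_HEADERS))
    stop_headers: list[str] = field(default_factory=lambda: list(DEFAULT_STOP_HEADERS))
    matching_mode: str = MatchMode.STRICT.value
    scope: str = Scope.ALL.value
    filter_enabled: bool = True
    splits: tuple[int, int, int] = (257, 77, 666)
    synth: dict = field(default_factory=dict)  # SynthConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "splits" in raw:
            raw["splits"] = tuple(raw["splits"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["splits"] = list(d["splits"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True),
                              encoding="utf-8")

    def load_gazetteer(self) -> Gazetteer:
        if self.gazetteer_path:
            return Gazetteer.from_tsv(self.gazetteer_path)
        return default_gazetteer()

    def load_filter(self) -> frozenset[str]:
        if not self.filter_enabled:
            return frozenset()
        if self.healthcare_filter_path:
            return frozenset(occ_io.read_filter_list(self.healthcare_filter_path))
        return default_healthcare_filter()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def extract_document(
    doc: ClinicalDocument,
    mention_model: Optional[MentionModel],
    relation_model: RelationModel,
    gazetteer: Gazetteer,
    filter_labels: frozenset[str],
    ph_headers=DEFAULT_PH_HEADERS,
    stop_headers=DEFAULT_STOP_HEADERS,
) -> list[OccupationAnnotation]:
    """All post-ingest stages for one document."""
    sections = extract_personal_history(doc, ph_headers, stop_headers)
    mentions = detect_mentions(doc, mention_model, gazetteer, sections)
    with_rel = classify_relations(doc, mentions, relation_model, sections)
    filtered = apply_healthcare_filter(with_rel, filter_labels)
    assert len(filtered) == len(with_rel)  # filter re-labels, never deletes
    return filtered


def run_extract(config: PipelineConfig,
                docs: Optional[list[ClinicalDocument]] = None
                ) -> dict[str, list[OccupationAnnotation]]:
    """Run the extraction pipeline over a corpus directory.

    Writes per-document ``.ann`` files plus ``extractions.tsv`` and a
    resolved config under ``config.out_dir``, and returns the annotations
    keyed by doc_id.  Models and gazetteer are checked before any document
    is processed.
    """
    mention_model = MentionModel.load(config.mention_model_path)
    relation_model = RelationModel.load(config.relation_model_path)
    gazetteer = config.load_gazetteer()
    filter_labels = config.load_filter()

    if docs is None:
        corpus_dir = Path(config.corpus_dir)
        docs = occ_io.read_documents(corpus_dir / "docs",
                                     corpus_dir / "metadata.tsv")
    out_dir = Path(config.out_dir)
    ann_dir = out_dir / "ann"
    ann_dir.mkdir(parents=True, exist_ok=True)

    counters = {"documents": 0, "mentions": 0, "patient_relations": 0,
                "filter_relabelled": 0}
    results: dict[str, list[OccupationAnnotation]] = {}
    rows = []
    for doc in sorted(docs, key=lambda d: d.doc_id):
        sections = extract_personal_history(doc, config.ph_headers,
                                            config.stop_headers)
        mentions = detect_mentions(doc, mention_model, gazetteer, sections)
        with_rel = classify_relations(doc, mentions, relation_model, sections)
        anns = apply_healthcare_filter(with_rel, filter_labels)
        counters["documents"] += 1
        counters["mentions"] += len(anns)
        counters["patient_relations"] += sum(
            a.relation is Relation.PATIENT for a in anns)
        counters["filter_relabelled"] += sum(
            a.relation != b.relation for a, b in zip(anns, with_rel))
        results[doc.doc_id] = anns
        occ_io.write_standoff(anns, ann_dir / f"{doc.doc_id}.ann")
        for a in anns:
            rows.append((doc.doc_id, doc.patient_id, a.span.start, a.span.end,
                         a.surface, a.label,
                         a.relation.value if a.relation else "",
                         int(any(s.span.start <= a.span.start < s.span.end
                                 for s in sections))))
    pd.DataFrame(rows, columns=["doc_id", "patient_id", "start", "end",
                                "surface", "label", "relation", "in_section"]
                 ).to_csv(out_dir / "extractions.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "resolved_config.yaml")
    (out_dir / "run_info.json").write_text(json.dumps({
        "counters": counters,
        "mention_model_hash": _sha256_file(Path(config.mention_model_path)),
        "relation_model_hash": _sha256_file(Path(config.relation_model_path)),
    }, indent=2, sort_keys=True), encoding="utf-8")
    logger.info("extract finished: %s", counters)
    return results


@dataclass
class PipelineResult:
    """Everything `run_all` computes, in memory."""

    corpus: GoldCorpus
    structured_fields: pd.DataFrame
    patients: pd.DataFrame
    mention_model: MentionModel
    relation_model: RelationModel
    predicted: dict[str, list[OccupationAnnotation]]       # test split
    predicted_all: dict[str, list[OccupationAnnotation]]   # whole corpus
    profiles: pd.DataFrame
    summary: dict


def run_all(config: PipelineConfig,
            write_outputs: bool = True) -> PipelineResult:
    """Synthesize → split → train → extract → evaluate → profile.

    A failure in any stage aborts with the stage name in the raised error.
    """
    stage = "synth"
    try:
        synth_cfg = SynthConfig(**{**config.synth,
                                   "seed": config.seed + SEED_SYNTH})
        corpus, structured, patients = generate_corpus(synth_cfg)

        stage = "split"
        corpus = split_corpus(corpus, *config.splits,
                              seed=config.seed + SEED_SPLIT)

        stage = "train"
        gazetteer = config.load_gazetteer()
        filter_labels = config.load_filter()
        mention_model = train_mention_model(
            corpus, gazetteer, seed=config.seed + SEED_MENTION)
        relation_model = train_relation_model(
            corpus, seed=config.seed + SEED_RELATION)

        stage = "extract"
        predicted_all: dict[str, list[OccupationAnnotation]] = {}
        for doc in corpus.documents:
            predicted_all[doc.doc_id] = extract_document(
                doc, mention_model, relation_model, gazetteer, filter_labels,
                config.ph_headers, config.stop_headers)
        test_ids = {d.doc_id for d in corpus.docs_in(Split.TEST)}
        predicted = {i: predicted_all[i] for i in test_ids}

        stage = "evaluate"
        gold_test = {i: corpus.annotations_for(i) for i in test_ids}
        report_all = precision_recall(gold_test, predicted,
                                      MatchMode(config.matching_mode),
                                      Scope.ALL)
        report_patient = precision_recall(gold_test, predicted,
                                          MatchMode(config.matching_mode),
                                          Scope.PATIENT_ONLY)
        from .evaluation import inter_annotator_agreement

        agreement = inter_annotator_agreement(
            corpus.docs_in(Split.TEST), gold_test, predicted)

        stage = "profile"
        by_patient: dict[str, list[OccupationAnnotation]] = {}
        for doc in corpus.documents:
            by_patient.setdefault(doc.patient_id, []).extend(
                predicted_all[doc.doc_id])
        profiles = build_profiles(by_patient, structured, filter_labels,
                                  patients)
        top = top_occupations(profiles, k=5)
        dsummary = distinct_count_summary(profiles)
        n = len(profiles)
        structured_only = profiles["structured_status"].notna().mean()
        combined = profiles["has_occupation"].mean()

        summary = {
            "n_patients": n,
            "n_documents": len(corpus.documents),
            "test_precision_all": report_all.precision,
            "test_recall_all": report_all.recall,
            "test_precision_patient_only": report_patient.precision,
            "test_recall_patient_only": report_patient.recall,
            "pipeline_vs_gold_kappa_mention": agreement.kappa_title,
            "pipeline_vs_gold_kappa_relation": agreement.kappa_relation,
            "structured_only_fraction": float(structured_only),
            "combined_fraction": float(combined),
            "top_occupations": top.to_dict(orient="records"),
            "distinct_per_patient": dataclasses.asdict(dsummary),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        occ_io.write_corpus(corpus, out_dir / "corpus", structured)
        patients.to_csv(out_dir / "corpus" / "patients.tsv", sep="\t",
                        index=False)
        mention_model.save(out_dir / "mention_model.bin")
        relation_model.save(out_dir / "relation_model.bin")
        prof_out = profiles.copy()
        prof_out["extracted_labels"] = prof_out["extracted_labels"].map(
            lambda labs: "|".join(labs))
        prof_out.to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
        top.to_csv(out_dir / "top_occupations.tsv", sep="\t", index=False)
        summary["corpus_hash"] = corpus_hash(corpus)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
        config.to_yaml(out_dir / "resolved_config.yaml")

    return PipelineResult(
        corpus=corpus, structured_fields=structured, patients=patients,
        mention_model=mention_model, relation_model=relation_model,
        predicted=predicted, predicted_all=predicted_all,
        profiles=profiles, summary=summary)


def fit_associations_for(result: PipelineResult) -> pd.DataFrame:
    """Association models over a pipeline result's profiles."""
    return fit_association_models(result.profiles)
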