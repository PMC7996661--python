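"""Scoring predicted annotations against gold, and inter-annotator agreement.

Precision is the proportion of predicted occupation annotations that are
correct; recall is the proportion of gold annotations that were found.  The
default matching mode is *strict*: a predicted annotation is a true positive
only when both its span and its relation are exactly right.  ``span_only``
ignores the relation; ``lenient_overlap`` accepts any character overlap but
still requires the relation to match.  Matching is one-to-one and of maximum
cardinality.

Cohen's kappa is reported for two unit conventions, stated in every report:
occupation-mention agreement over per-token binary decisions (inside any
mention vs not), and relation agreement over mention pairs aligned by span
overlap.  Undefined ratios (0/0) are ``None``, never 0, so empty-corpus runs
cannot masquerade as perfect or failing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import networkx as nx

from .tokenizer import tokenize
from .types import ClinicalDocument, OccupationAnnotation, Relation


class MatchMode(str, Enum):
    STRICT = "strict_span_and_relation"
    SPAN_ONLY = "span_only"
    LENIENT = "lenient_overlap"


class Scope(str, Enum):
    ALL = "all_relations"
    PATIENT_ONLY = "patient_only"


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    matching_mode: MatchMode
    scope: Scope

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


@dataclass(frozen=True)
class AgreementReport:
    kappa_title: Optional[float]
    kappa_relation: Optional[float]
    n_title_units: int
    n_relation_units: int
    units_note: str = ("title: per-token binary (inside any mention); "
                       "relation: mention pairs aligned by span overlap")


def _compatible(g: OccupationAnnotation, p: OccupationAnnotation,
                mode: MatchMode) -> bool:
    if mode is MatchMode.STRICT:
        return g.span == p.span and g.relation == p.relation
    if mode is MatchMode.SPAN_ONLY:
        return g.span == p.span
    return g.span.overlaps(p.span) and g.relation == p.relation


def match_annotations(
    gold: Sequence[OccupationAnnotation],
    predicted: Sequence[OccupationAnnotation],
    mode: MatchMode = MatchMode.STRICT,
) -> tuple[list[tuple[OccupationAnnotation, OccupationAnnotation]],
           list[OccupationAnnotation], list[OccupationAnnotation]]:
    """One-to-one maximum matching between gold and predicted annotations.

    Returns (matched pairs, unmatched gold, unmatched predicted).  Nodes are
    offered to the matcher in span order, so the result is deterministic.
    """
    gold = sorted(gold, key=lambda a: (a.span.start, a.span.end))
    predicted = sorted(predicted, key=lambda a: (a.span.start, a.span.end))
    graph = nx.Graph()
    g_nodes = [("g", i) for i in range(len(gold))]
    p_nodes = [("p", j) for j in range(len(predicted))]
    graph.add_nodes_from(g_nodes, bipartite=0)
    graph.add_nodes_from(p_nodes, bipartite=1)
    for i, g in enumerate(gold):
        for j, p in enumerate(predicted):
            if _compatible(g, p, mode):
                graph.add_edge(("g", i), ("p", j))
    matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=g_nodes) \
        if graph.number_of_edges() else {}

    pairs = []
    matched_g, matched_p = set(), set()
    for i in range(len(gold)):
        partner = matching.get(("g", i))
        if partner is not None:
            j = partner[1]
            pairs.append((gold[i], predicted[j]))
            matched_g.add(i)
            matched_p.add(j)
    unmatched_gold = [g for i, g in enumerate(gold) if i not in matched_g]
    unmatched_pred = [p for j, p in enumerate(predicted) if j not in matched_p]
    return pairs, unmatched_gold, unmatched_pred


def _restrict(anns: Sequence[OccupationAnnotation],
              scope: Scope) -> list[OccupationAnnotation]:
    if scope is Scope.PATIENT_ONLY:
        return [a for a in anns if a.relation is Relation.PATIENT]
    return list(anns)


def precision_recall(
    gold: dict[str, list[OccupationAnnotation]],
    predicted: dict[str, list[OccupationAnnotation]],
    mode: MatchMode = MatchMode.STRICT,
    scope: Scope = Scope.ALL,
) -> EvaluationReport:
    """Micro-averaged precision/recall, pooling counts over documents."""
    tp = fp = fn = 0
    for doc_id in sorted(set(gold) | set(predicted)):
        g = _restrict(gold.get(doc_id, []), scope)
        p = _restrict(predicted.get(doc_id, []), scope)
        pairs, un_g, un_p = match_annotations(g, p, mode)
        tp += len(pairs)
        fn += len(un_g)
        fp += len(un_p)
    return EvaluationReport(tp=tp, fp=fp, fn=fn, matching_mode=mode, scope=scope)


# ---------------------------------------------------------------- agreement

def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> Optional[float]:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), marginal-based chance agreement.

    Returns ``None`` for zero units; returns 1.0 when both annotators are
    constant and identical (p_e = 1 edge case).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("annotator label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        return None
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    cats = set(ca) | set(cb)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in cats)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def kappa_from_table(table: Sequence[Sequence[int]]) -> Optional[float]:
    """Kappa from a square agreement table (rows: annotator A, cols: B)."""
    labels_a: list[int] = []
    labels_b: list[int] = []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            labels_a.extend([i] * count)
            labels_b.extend([j] * count)
    return cohens_kappa(labels_a, labels_b)


def _token_decisions(doc: ClinicalDocument,
                     anns: Sequence[OccupationAnnotation]) -> list[bool]:
    tokens = tokenize(doc.text)
    return [any(t.span.overlaps(a.span) for a in anns) for t in tokens]


def inter_annotator_agreement(
    documents: Sequence[ClinicalDocument],
    annotator_a: dict[str, list[OccupationAnnotation]],
    annotator_b: dict[str, list[OccupationAnnotation]],
) -> AgreementReport:
    """Agreement between two annotators over a shared document set."""
    title_a: list[bool] = []
    title_b: list[bool] = []
    rel_a: list[str] = []
    rel_b: list[str] = []
    for doc in documents:
        a = annotator_a.get(doc.doc_id, [])
        b = annotator_b.get(doc.doc_id, [])
        title_a.extend(_token_decisions(doc, a))
        title_b.extend(_token_decisions(doc, b))
        # relation units: mentions aligned by span overlap alone
        overlap_pairs, _, _ = _span_overlap_pairs(a, b)
        for ga, gb in overlap_pairs:
            if ga.relation is not None and gb.relation is not None:
                rel_a.append(ga.relation.value)
                rel_b.append(gb.relation.value)
    return AgreementReport(
        kappa_title=cohens_kappa(title_a, title_b),
        kappa_relation=cohens_kappa(rel_a, rel_b),
        n_title_units=len(title_a),
        n_relation_units=len(rel_a),
    )


def _span_overlap_pairs(a: Sequence[OccupationAnnotation],
                        b: Sequence[OccupationAnnotation]):
    """Maximum one-to-one alignment by span overlap alone (relation ignored)."""
    a = sorted(a, key=lambda x: (x.span.start, x.span.end))
    b = sorted(b, key=lambda x: (x.span.start, x.span.end))
    graph = nx.Graph()
    a_nodes = [("a", i) for i in range(len(a))]
    graph.add_nodes_from(a_nodes, bipartite=0)
    graph.add_nodes_from((("b", j) for j in range(len(b))), bipartite=1)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.span.overlaps(y.span):
                graph.add_edge(("a", i), ("b", j))
    matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=a_nodes) \
        if graph.number_of_edges() else {}
    pairs = []
    matched_a, matched_b = set(), set()
    for i in range(len(a)):
        partner = matching.get(("a", i))
        if partner is not None:
            pairs.append((a[i], b[partner[1]]))
            matched_a.add(i)
            matched_b.add(partner[1])
    un_a = [x for i, x in enumerate(a) if i not in matched_a]
    un_b = [y for j, y in enumerate(b) if j not in matched_b]
    return pairs, un_a, un_b
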