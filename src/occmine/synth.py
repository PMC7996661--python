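"""Seeded synthetic psychiatric-note corpus with exact ground truth.

The generator is template-based on purpose: every occupation mention is
written into the text and into the gold standard from the same source, so
gold surface strings always equal their text slices and the corpus is fully
auditable.  It emulates the statistical structure the pipeline assumes:

* a configurable fraction of documents carry a *personal history* narrative
  section where patient and family occupations are described;
* clinician "trap" sentences ("Seen by Dr Jones, consultant psychiatrist")
  put healthcare occupations in the text that must not be attributed to the
  patient;
* distractor sentences use non-occupation "work" idioms ("working on his
  anxiety") and carry no gold annotation;
* occupation frequencies are a ranked categorical distribution dominated by
  the occupational statuses "student" and "unemployed";
* a coded occupational-status structured field exists for only ~14% of
  patients, the completeness that motivates text mining in the first place.

One global seed drives all randomness; the same config and seed give a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .resources import (
    default_gazetteer,
    default_healthcare_filter,
    kinship_terms,
    out_of_lexicon_occupations,
    surname_pool,
)
from .sections import DEFAULT_PH_HEADERS
from .types import (
    ClinicalDocument,
    DocType,
    GoldCorpus,
    MentionKind,
    OccupationAnnotation,
    Relation,
    Split,
    TextSpan,
)

# occupational statuses behaving like adjectives ("is currently unemployed")
_ADJECTIVAL_STATUSES = frozenset({"unemployed", "retired", "self-employed"})

#: ranked default frequencies; statuses dominate, mirroring a register where
#: "student" and "unemployed" head the distribution, with a long tail of
#: specific titles sharing the remaining mass.
_STATUS_WEIGHTS = {
    "student": 0.25,
    "unemployed": 0.24,
    "carer": 0.11,
    "self-employed": 0.07,
    "retired": 0.06,
}

_DISTRACTORS = (
    "He has been working on his anxiety.",
    "She is working through her grief with support.",
    "They are doing some work on sleep hygiene.",
    "The team will work towards discharge.",
    "He finds it hard to work out what triggers these episodes.",
    "She is working towards her recovery goals.",
)

_FILLERS = (
    "Sleep has been poor recently.",
    "Appetite is reduced.",
    "Reports low mood over the past month.",
    "No thoughts of self-harm expressed.",
    "Attends appointments regularly.",
    "Lives alone in a first-floor flat.",
    "Enjoys walking and reading.",
    "Mood appeared brighter today.",
    "Denies any substance use.",
    "Engaging well with the care plan.",
)

_INTROS = (
    "Attended the outpatient department today.",
    "Telephone contact with the patient.",
    "Home visit completed this afternoon.",
    "Routine follow-up appointment.",
)

_STOP_SECTIONS = (
    "Medication:\nNo changes to current prescription.\n",
    "Plan:\nContinue current level of support.\n",
    "Risk:\nNo acute concerns identified.\n",
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus.

    ``docs_per_patient`` is the mean of a 1 + Poisson draw, so every patient
    has at least one document.  The per-sentence emission probabilities
    apply inside personal-history sections (patient/family mentions) and
    throughout the note body (clinician traps); ``noise`` is the chance of a
    distractor "work"-idiom sentence carrying no gold annotation.
    """

    n_patients: int = 500
    docs_per_patient: float = 3.0
    p_personal_history_section: float = 0.8
    p_patient_mention: float = 0.35
    p_family_mention: float = 0.20
    p_clinician_trap: float = 0.10
    noise: float = 0.15
    p_out_of_lexicon: float = 0.08
    occupation_frequency: Optional[dict[str, float]] = None
    structured_field_completeness: float = 0.14
    sentences_per_section: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.docs_per_patient < 1.0:
            raise ValueError("docs_per_patient must be >= 1")
        probs = {
            "p_personal_history_section": self.p_personal_history_section,
            "p_patient_mention": self.p_patient_mention,
            "p_family_mention": self.p_family_mention,
            "p_clinician_trap": self.p_clinician_trap,
            "noise": self.noise,
            "p_out_of_lexicon": self.p_out_of_lexicon,
            "structured_field_completeness": self.structured_field_completeness,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if (self.p_patient_mention + self.p_family_mention
                + self.p_clinician_trap + self.noise) > 1.0:
            raise ValueError("per-sentence emission probabilities sum above 1")


class SyntheticCorpus(NamedTuple):
    corpus: GoldCorpus
    structured_fields: pd.DataFrame   # patient_id, status_code (1-13)
    patients: pd.DataFrame            # per-patient covariates


class _DocBuilder:
    """Accumulates text pieces while recording exact annotation offsets."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0
        self.annotations: list[OccupationAnnotation] = []

    def add(self, text: str) -> None:
        self._parts.append(text)
        self._len += len(text)

    def add_mention(self, pre: str, term: str, post: str,
                    label: str, kind: MentionKind, relation: Relation) -> None:
        start = self._len + len(pre)
        self.add(pre + term + post)
        self.annotations.append(OccupationAnnotation(
            span=TextSpan(start, start + len(term)), surface=term,
            mention_kind=kind, label=label, relation=relation))

    @property
    def text(self) -> str:
        return "".join(self._parts)


def _occupation_pool(config: SynthConfig):
    """(terms, weights, entries) for patient/family occupation sampling.

    Healthcare occupations are excluded: the corpus, like the pipeline,
    never attributes health/social-care occupations to the patient.
    """
    gaz = default_gazetteer()
    filt = default_healthcare_filter()
    if config.occupation_frequency is not None:
        freq = dict(config.occupation_frequency)
    else:
        freq = {}
        tail_terms = []
        for key, entry in sorted(gaz.entries.items()):
            surface = " ".join(key)
            if entry.label in filt:
                continue
            if surface in _STATUS_WEIGHTS:
                freq[surface] = _STATUS_WEIGHTS[surface]
            elif surface == entry.label:  # one canonical surface per label
                tail_terms.append(surface)
        tail_mass = 1.0 - sum(freq.values())
        for t in tail_terms:
            freq[t] = tail_mass / len(tail_terms)
    terms = sorted(freq)
    weights = np.array([freq[t] for t in terms], dtype=float)
    weights = weights / weights.sum()
    return terms, weights


def _pick_patient_terms(rng: np.random.Generator, terms, weights,
                        oov: tuple[str, ...], p_oov: float) -> list[str]:
    """A patient's personal occupation set: 1-3 terms, possibly one OOV."""
    k = int(rng.integers(1, 4))
    chosen = list(rng.choice(terms, size=k, replace=False, p=weights))
    if p_oov > 0 and rng.random() < p_oov * k:
        chosen[int(rng.integers(0, k))] = str(rng.choice(oov))
    return chosen


_GENDERS = ("male", "female", "other")
_PRONOUNS = {
    "male": ("He", "he", "his", "s", "is", "has"),
    "female": ("She", "she", "her", "s", "is", "has"),
    "other": ("They", "they", "their", "", "are", "have"),
}


def _term_entry(term: str):
    gaz = default_gazetteer()
    entry = gaz.lookup_surface(term)
    if entry is not None:
        return entry.label, entry.kind
    return term.lower(), MentionKind.TITLE  # out-of-lexicon title


def _article(term: str) -> str:
    return "an" if term[:1] in "aeiou" else "a"


def _patient_sentence(b: _DocBuilder, rng: np.random.Generator,
                      term: str, pron) -> None:
    P, _, _, s, is_, has = pron
    label, kind = _term_entry(term)
    a = _article(term)
    if kind is MentionKind.DESCRIPTION:
        forms = [
            (f"{P} work{s} in ", "."),
            (f"{P} used to work in ", "."),
            (f"{P} {has} a background in ", "."),
        ]
    elif term in _ADJECTIVAL_STATUSES:
        forms = [
            (f"{P} {is_} currently ", "."),
            (f"{P} {is_} ", " at present."),
        ]
    else:
        forms = [
            (f"{P} work{s} as {a} ", "."),
            (f"{P} {is_} {a} ", " by trade."),
            (f"{P} {has} been working as {a} ", " for several years."),
            (f"Currently employed as {a} ", "."),
            (f"{P} previously worked as {a} ", "."),
        ]
    pre, post = forms[int(rng.integers(0, len(forms)))]
    b.add_mention(pre, term, post + " ", label, kind, Relation.PATIENT)


def _family_sentence(b: _DocBuilder, rng: np.random.Generator,
                     terms, weights, pron) -> None:
    _, _, poss, _, _, _ = pron
    kin = str(rng.choice(kinship_terms()))
    term = str(rng.choice(terms, p=weights))
    label, kind = _term_entry(term)
    poss_cap = poss.capitalize()
    a = _article(term)
    if kind is MentionKind.DESCRIPTION:
        forms = [(f"{poss_cap} {kin} works in ", ".")]
    elif term in _ADJECTIVAL_STATUSES:
        forms = [(f"{poss_cap} {kin} is ", ".")]
    else:
        forms = [
            (f"{poss_cap} {kin} is {a} ", "."),
            (f"{poss_cap} {kin} works as {a} ", "."),
        ]
    pre, post = forms[int(rng.integers(0, len(forms)))]
    b.add_mention(pre, term, post + " ", label, kind, Relation.FAMILY)


_TRAPS = (
    # (pre with {name}/{poss} slots, term, post, label)
    ("Seen by Dr {name}, ", "consultant psychiatrist", ".", "psychiatrist"),
    ("Reviewed by Dr {name}, ", "psychiatrist", ", earlier today.", "psychiatrist"),
    ("Seen by {name}, ", "CPN", ", for follow-up.", "psychiatric nurse"),
    ("Assessed by the duty ", "social worker", " this morning.", "social worker"),
    ("Discussed with {poss} ", "care coordinator", ".", "care coordinator"),
    ("Referred to the ", "community psychiatric nurse", ".", "psychiatric nurse"),
)


def _trap_sentence(b: _DocBuilder, rng: np.random.Generator, pron) -> None:
    _, _, poss, _, _, _ = pron
    pre, term, post, label = _TRAPS[int(rng.integers(0, len(_TRAPS)))]
    name = str(rng.choice(surname_pool()))
    pre = pre.format(name=name, poss=poss)
    b.add_mention(pre, term, post + " ", label, MentionKind.TITLE,
                  Relation.CLINICIAN)


def generate_corpus(config: SynthConfig) -> SyntheticCorpus:
    """Generate the corpus, the structured-status table and patient covariates."""
    rng = np.random.default_rng(config.seed)
    terms, weights = _occupation_pool(config)
    oov = out_of_lexicon_occupations()

    documents: list[ClinicalDocument] = []
    annotations: dict[str, list[OccupationAnnotation]] = {}
    patient_rows = []
    structured_rows = []
    doc_counter = 0

    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        age = int(rng.integers(16, 91))
        gender = str(rng.choice(_GENDERS, p=[0.48, 0.51, 0.01]))
        pron = _PRONOUNS[gender]
        patient_rows.append({
            "patient_id": patient_id,
            "age_band": _age_band(age),
            "gender": gender,
            "ethnicity": str(rng.choice(
                ["white_british", "black_caribbean", "black_african",
                 "other", "not_known"],
                p=[0.40, 0.10, 0.05, 0.20, 0.25])),
            "marital": str(rng.choice(
                ["married", "single", "divorced", "widowed", "not_known"],
                p=[0.14, 0.41, 0.05, 0.05, 0.35])),
            "deprivation": str(rng.choice(
                ["least_deprived", "q2", "q3", "most_deprived", "not_known"],
                p=[0.233, 0.234, 0.233, 0.234, 0.066])),
            "diagnosis": str(rng.choice(
                ["mood", "organic", "substance", "psychotic", "other",
                 "not_known"],
                p=[0.11, 0.09, 0.08, 0.05, 0.45, 0.22])),
            "events_quartile": str(rng.choice(
                ["none", "low", "moderate", "high"],
                p=[0.15, 0.25, 0.20, 0.40])),
            "bed_days": str(rng.choice(
                ["none", "low", "moderate", "high"],
                p=[0.91, 0.005, 0.031, 0.054])),
        })
        if rng.random() < config.structured_field_completeness:
            structured_rows.append({"patient_id": patient_id,
                                    "status_code": int(rng.integers(1, 14))})

        personal_terms = _pick_patient_terms(
            rng, terms, weights, oov, config.p_out_of_lexicon)
        n_docs = 1 + int(rng.poisson(max(config.docs_per_patient - 1.0, 0.0)))
        for _ in range(n_docs):
            doc_id = f"D{doc_counter:06d}"
            doc_counter += 1
            b = _DocBuilder()
            b.add(str(rng.choice(_INTROS)) + " ")
            if rng.random() < config.p_clinician_trap:
                _trap_sentence(b, rng, pron)
            b.add("\n")
            if rng.random() < config.p_personal_history_section:
                b.add(str(rng.choice(DEFAULT_PH_HEADERS)).title() + ":\n")
                lo, hi = config.sentences_per_section
                for _ in range(int(rng.integers(lo, hi + 1))):
                    u = rng.random()
                    if u < config.p_patient_mention:
                        term = str(rng.choice(personal_terms))
                        _patient_sentence(b, rng, term, pron)
                    elif u < config.p_patient_mention + config.p_family_mention:
                        _family_sentence(b, rng, terms, weights, pron)
                    elif u < (config.p_patient_mention + config.p_family_mention
                              + config.p_clinician_trap):
                        _trap_sentence(b, rng, pron)
                    elif u < (config.p_patient_mention + config.p_family_mention
                              + config.p_clinician_trap + config.noise):
                        b.add(str(rng.choice(_DISTRACTORS)) + " ")
                    else:
                        b.add(str(rng.choice(_FILLERS)) + " ")
                b.add("\n")
            b.add(str(rng.choice(_STOP_SECTIONS)))
            doc_type = DocType(str(rng.choice(
                [t.value for t in DocType],
                p=[0.35, 0.35, 0.1, 0.1, 0.1])))
            documents.append(ClinicalDocument(
                doc_id=doc_id, patient_id=patient_id, doc_type=doc_type,
                text=b.text, patient_age_at_doc=age))
            annotations[doc_id] = b.annotations

    corpus = GoldCorpus(documents=documents, annotations=annotations)
    structured = pd.DataFrame(structured_rows,
                              columns=["patient_id", "status_code"])
    patients = pd.DataFrame(patient_rows)
    return SyntheticCorpus(corpus=corpus, structured_fields=structured,
                           patients=patients)


def _age_band(age: int) -> str:
    if age < 30:
        return "16-29"
    if age < 50:
        return "30-49"
    if age < 70:
        return "50-69"
    if age < 90:
        return "70-89"
    return "90+"


def split_corpus(corpus: GoldCorpus, n_train: int, n_validation: int,
                 n_test: int, seed: int = 0) -> GoldCorpus:
    """Assign eligible documents to train/validation/test splits.

    Eligible documents are those containing a personal-history section.
    All documents of one patient land in the same split (no leakage), so
    split sizes may deviate from the requested counts by whole-patient
    rounding; when the requested total equals the number of eligible
    documents, every eligible document is assigned.
    """
    from .sections import extract_personal_history

    eligible = [d for d in corpus.documents if extract_personal_history(d)]
    requested = n_train + n_validation + n_test
    if requested > len(eligible):
        raise ValueError(
            f"requested {requested} documents "
            f"({n_train}/{n_validation}/{n_test}) but only {len(eligible)} "
            f"contain a personal-history section")

    by_patient: dict[str, list[str]] = {}
    for d in eligible:
        by_patient.setdefault(d.patient_id, []).append(d.doc_id)

    rng = np.random.default_rng(seed)
    patient_ids = sorted(by_patient)
    rng.shuffle(patient_ids)

    deficits = {Split.TRAIN: n_train, Split.VALIDATION: n_validation,
                Split.TEST: n_test}
    order = [Split.TRAIN, Split.VALIDATION, Split.TEST]
    split: dict[str, Split] = {}
    for pid in patient_ids:
        open_splits = [s for s in order if deficits[s] > 0]
        if not open_splits:
            break
        target = max(open_splits, key=lambda s: deficits[s])
        for doc_id in by_patient[pid]:
            split[doc_id] = target
        deficits[target] -= len(by_patient[pid])

    return GoldCorpus(documents=corpus.documents,
                      annotations=corpus.annotations, split=split)


# ------------------------------------------------------- profile simulation

def simulate_profiles(
    n_patients: int = 2000,
    baseline_logit: float = -0.6,
    or_by_events: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient profiles with a *known* missingness model, for calibration.

    The binary outcome (occupation recorded) follows a logistic model in the
    service-contact (events) category only; every other covariate is drawn
    independently of the outcome, i.e. is null by construction.  The default
    odds ratio for high-vs-no service contact is 2.0.
    """
    if or_by_events is None:
        or_by_events = {"none": 1.0, "low": 1.4, "moderate": 1.7, "high": 2.0}
    rng = np.random.default_rng(seed)
    levels = list(or_by_events)
    events = rng.choice(levels, size=n_patients, p=[0.25, 0.30, 0.25, 0.20])
    logits = baseline_logit + np.log(
        np.array([or_by_events[e] for e in events]))
    outcome = rng.random(n_patients) < 1.0 / (1.0 + np.exp(-logits))
    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n_patients)],
        "events_quartile": pd.Categorical(events, categories=levels),
        "gender": rng.choice(["male", "female"], size=n_patients),
        "age_band": rng.choice(["16-29", "30-49", "50-69", "70-89", "90+"],
                               size=n_patients,
                               p=[0.25, 0.36, 0.23, 0.13, 0.03]),
        "bed_days": rng.choice(["none", "low", "moderate", "high"],
                               size=n_patients, p=[0.91, 0.005, 0.031, 0.054]),
        "has_occupation": outcome,
    })
    return df
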