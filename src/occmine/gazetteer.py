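"""Dictionary (gazetteer) of occupation surface forms.

Each entry maps a lowercased surface phrase — possibly multi-word — to its
normalized occupation label, with a mention kind (a *title* like "builder"
or a *description* like "construction") and a flag for occupational-status
terms (student, unemployed, retired, carer, self-employed, ...), which are
legitimate extraction targets in their own right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .tokenizer import Token
from .types import MentionKind, OccupationAnnotation, TextSpan


@dataclass(frozen=True)
class GazetteerEntry:
    label: str
    kind: MentionKind
    is_status: bool

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gazetteer entry with empty label")


@dataclass
class Gazetteer:
    #: lowercased surface token tuple -> entry
    entries: dict[tuple[str, ...], GazetteerEntry] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Gazetteer":
        from .io import read_gazetteer_table
        from .tokenizer import tokenize

        df = read_gazetteer_table(path)
        entries: dict[tuple[str, ...], GazetteerEntry] = {}
        for row in df.itertuples():
            key = tuple(t.lower for t in tokenize(str(row.surface)))
            entries[key] = GazetteerEntry(
                label=str(row.normalized_label).lower(),
                kind=MentionKind(row.kind),
                is_status=bool(row.is_status),
            )
        return cls(entries=entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_len(self) -> int:
        return max((len(k) for k in self.entries), default=0)

    def lookup_tokens(self, lowered: tuple[str, ...]):
        return self.entries.get(lowered)

    def lookup_surface(self, surface: str):
        from .tokenizer import tokenize

        return self.entries.get(tuple(t.lower for t in tokenize(surface)))

    def labels(self) -> set[str]:
        return {e.label for e in self.entries.values()}


def gazetteer_match(tokens: list[Token], gazetteer: Gazetteer,
                    text: str) -> list[OccupationAnnotation]:
    """Case-insensitive longest-match, left to right, non-overlapping.

    Relations are left unset; the relation classifier assigns them later.
    """
    matches: list[OccupationAnnotation] = []
    i = 0
    n = len(tokens)
    max_len = gazetteer.max_len
    while i < n:
        hit = None
        hit_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(tokens[i + j].lower for j in range(length))
            entry = gazetteer.lookup_tokens(key)
            if entry is not None:
                hit, hit_len = entry, length
                break
        if hit is None:
            i += 1
            continue
        span = TextSpan(tokens[i].span.start, tokens[i + hit_len - 1].span.end)
        matches.append(OccupationAnnotation(
            span=span,
            surface=text[span.start:span.end],
            mention_kind=hit.kind,
            label=hit.label,
        ))
        i += hit_len
    return matches


def gazetteer_hit_spans(tokens: list[Token], gazetteer: Gazetteer) -> list[bool]:
    """Per-token flag: token lies inside some longest-match gazetteer hit."""
    flags = [False] * len(tokens)
    i = 0
    n = len(tokens)
    max_len = gazetteer.max_len
    while i < n:
        hit_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            if gazetteer.lookup_tokens(
                    tuple(tokens[i + j].lower for j in range(length))) is not None:
                hit_len = length
                break
        if hit_len:
            for j in range(hit_len):
                flags[i + j] = True
            i += hit_len
        else:
            i += 1
    return flags
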