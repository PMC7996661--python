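"""Deterministic regex tokenizer.

Tokens are maximal runs of word characters (with an optional internal
apostrophe or hyphen, so "self-employed" and "O'Brien" stay whole) or single
punctuation marks.  Token spans index into the original text, so the text is
always reconstructible from tokens plus the gaps between them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .types import TextSpan

TOKENIZER_VERSION = "occmine-regex-1"

_TOKEN_RE = re.compile(r"\w+(?:[-']\w+)*|[^\w\s]")


@dataclass(frozen=True)
class Token:
    span: TextSpan
    surface: str

    @property
    def lower(self) -> str:
        return self.surface.lower()

    @property
    def is_capitalized(self) -> bool:
        return self.surface[:1].isupper()

    @property
    def has_digit(self) -> bool:
        return any(c.isdigit() for c in self.surface)


def tokenize(text: str) -> list[Token]:
    """Split text into tokens whose spans tile it without overlap."""
    return [
        Token(span=TextSpan(m.start(), m.end()), surface=m.group())
        for m in _TOKEN_RE.finditer(text)
    ]


def detokenize(text: str, tokens: list[Token]) -> str:
    """Reassemble the original text from token surfaces and the gaps of *text*."""
    pieces: list[str] = []
    pos = 0
    for tok in tokens:
        pieces.append(text[pos:tok.span.start])
        pieces.append(tok.surface)
        pos = tok.span.end
    pieces.append(text[pos:])
    return "".join(pieces)


_SENTENCE_END = re.compile(r"[.!?]\s|\n")


def sentence_start_index(text: str, offset: int) -> int:
    """Character offset of the start of the sentence containing *offset*."""
    start = 0
    for m in _SENTENCE_END.finditer(text, 0, offset):
        start = m.end()
    return start
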