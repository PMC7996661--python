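"""Personal-history section extraction.

Psychiatric assessments typically carry a narrative "personal history"
section describing the patient's background — occupation, education, family —
and it is the region of the note where occupation extraction is most
reliable.  Headers are matched line-anchored and case-insensitively,
tolerating a trailing colon and whitespace; a section runs from the end of
its header line to the next recognized header (personal-history or stop
header) or the end of the document.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .types import ClinicalDocument, TextSpan

DEFAULT_PH_HEADERS = (
    "personal history",
    "background history",
    "social history",
    "family and personal history",
)

DEFAULT_STOP_HEADERS = (
    "medication",
    "mental state",
    "mental state examination",
    "risk",
    "risk assessment",
    "plan",
    "diagnosis",
    "presenting complaint",
    "history of presenting illness",
    "impression",
    "current situation",
    "past psychiatric history",
    "medical history",
)


@dataclass(frozen=True)
class SectionSpan:
    span: TextSpan
    header_matched: str


def _header_regex(patterns: tuple[str, ...] | list[str]) -> re.Pattern:
    alts = "|".join(re.escape(p) for p in sorted(patterns, key=len, reverse=True))
    # a header sits at line start and is delimited by ":" or the line end;
    # section content may follow the colon on the same line
    return re.compile(rf"^[ \t]*({alts})[ \t]*(?::[ \t]*|$)",
                      re.IGNORECASE | re.MULTILINE)


def extract_personal_history(
    doc: ClinicalDocument,
    ph_headers: tuple[str, ...] | list[str] = DEFAULT_PH_HEADERS,
    stop_headers: tuple[str, ...] | list[str] = DEFAULT_STOP_HEADERS,
) -> list[SectionSpan]:
    """Locate personal-history sections; empty list when no header matches.

    Returned spans are non-overlapping and in document order.  Downstream
    stages treat text outside every span as out-of-section.
    """
    if not ph_headers:
        raise ValueError("ph_headers must be non-empty")
    text = doc.text
    ph_re = _header_regex(tuple(ph_headers))
    any_re = _header_regex(tuple(ph_headers) + tuple(stop_headers))

    sections: list[SectionSpan] = []
    pos = 0
    while True:
        m = ph_re.search(text, pos)
        if m is None:
            break
        body_start = m.end()
        while body_start < len(text) and text[body_start] == "\n":
            body_start += 1
        nxt = any_re.search(text, body_start)
        body_end = nxt.start() if nxt else len(text)
        if body_end > body_start:
            sections.append(SectionSpan(span=TextSpan(body_start, body_end),
                                        header_matched=m.group(1)))
        pos = max(body_end, body_start)
        if pos >= len(text):
            break
    return sections


def in_any_section(offset: int, sections: list[SectionSpan]) -> bool:
    return any(s.span.start <= offset < s.span.end for s in sections)
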