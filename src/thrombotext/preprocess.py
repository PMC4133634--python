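"""Sentence segmentation, tokenization and rule-based section splitting.

French radiology reports are free text but follow a stable layout: a
section title on its own line ("Indication :", "Technique :",
"Résultats :", "Conclusion :") followed by the section contents.  The
splitter maps title lines to section types through a configurable
synonym table; text before the first recognized title is the patient
identification block, and unrecognized title-looking lines open UNKNOWN
sections.

All units (tokens, sentence spans, sections) carry character offsets into
the source text and are offset-faithful: the unit's surface equals the
source substring.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .model import Section, SectionType

# ---------------------------------------------------------------------------
# normalization

_WS_RE = re.compile(r"\s+")


def fold(
    text: str,
    case: bool = True,
    diacritics: bool = True,
    collapse_ws: bool = True,
) -> str:
    """Normalize text: case-fold, strip diacritics, collapse whitespace runs.

    Used consistently by the corpus query and the lexicon matcher so that
    "Embolie  Pulmonaire" and "embolie pulmonaire" compare equal.
    """
    if case:
        text = text.casefold()
    if diacritics:
        text = "".join(
            ch for ch in unicodedata.normalize("NFKD", text)
            if not unicodedata.combining(ch)
        )
    if collapse_ws:
        text = _WS_RE.sub(" ", text).strip()
    return text


# ---------------------------------------------------------------------------
# tokenization

@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    @property
    def lower(self) -> str:
        return self.surface.lower()


# Words may contain internal hyphens ("phlebo-scan" stays whole); an
# apostrophe ends a token only when glued to a following word, which
# detaches French clitics: "d'embolie" -> "d'", "embolie".
_TOKEN_RE = re.compile(r"\w+(?:-\w+)*(?:['’](?=\w))?|[^\w\s]")


def tokenize(text: str) -> list[Token]:
    """Split text into maximal word / punctuation tokens with offsets."""
    return [
        Token(m.group(0), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


# ---------------------------------------------------------------------------
# sentence segmentation

#: Final-period abbreviations that never close a sentence.
ABBREVIATIONS = frozenset({
    "m", "mme", "mlle", "dr", "pr", "cf", "ref", "art", "fig",
    "resp", "etc", "env", "max", "min", "vol",
})

_SENT_END_RE = re.compile(r"[.!?]+")
_UPPER_OR_DIGIT_RE = re.compile(r"[A-ZÀ-Ý0-9]")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans partitioning the non-whitespace text.

    A boundary requires sentence-final punctuation followed by whitespace
    and an uppercase letter, digit or newline; a period after a listed
    abbreviation does not split.
    """
    boundaries: list[int] = []
    for m in _SENT_END_RE.finditer(text):
        end = m.end()
        if end >= len(text):
            continue
        follow = text[end:end + 2]
        if not follow[:1].isspace():
            continue
        rest = text[end:].lstrip(" \t")
        if not (rest.startswith("\n") or _UPPER_OR_DIGIT_RE.match(rest[:1])):
            continue
        if m.group(0) == ".":
            prev = re.search(r"(\w+)\.\Z", text[:end])
            if prev and prev.group(1).lower() in ABBREVIATIONS:
                continue
        boundaries.append(end)

    spans: list[tuple[int, int]] = []
    cursor = 0
    for b in boundaries + [len(text)]:
        chunk = text[cursor:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((cursor + lead, b - trail))
        cursor = b
    return spans


# ---------------------------------------------------------------------------
# section splitting

#: Default synonym table mapping a folded header title to a section type.
#: Configuration, not a reconstruction: header wording varies by site.
DEFAULT_HEADERS: dict[str, SectionType] = {
    "identification": SectionType.IDENTIFICATION,
    "patient": SectionType.IDENTIFICATION,
    "indication": SectionType.INDICATION,
    "indications": SectionType.INDICATION,
    "renseignements cliniques": SectionType.INDICATION,
    "technique": SectionType.PROTOCOL,
    "techniques": SectionType.PROTOCOL,
    "protocole": SectionType.PROTOCOL,
    "protocole d'examen": SectionType.PROTOCOL,
    "resultat": SectionType.RESULTS,
    "resultats": SectionType.RESULTS,
    "description": SectionType.RESULTS,
    "conclusion": SectionType.CONCLUSION,
    "conclusions": SectionType.CONCLUSION,
    "synthese": SectionType.CONCLUSION,
}

# A title line: at most four words, optionally ending with a colon.
_HEADER_LINE_RE = re.compile(r"^\s*(?P<title>[^\s:][^:\n]{0,60}?)\s*:?\s*$")
_MAX_HEADER_WORDS = 4


def _classify_header(
    line: str, headers: dict[str, SectionType]
) -> tuple[SectionType, str] | None:
    m = _HEADER_LINE_RE.match(line)
    if not m:
        return None
    title = m.group(1)
    folded = fold(title)
    if folded in headers:
        return headers[folded], title
    # unrecognized but header-shaped: short line ending with a colon
    if line.rstrip().endswith(":") and len(title.split()) <= _MAX_HEADER_WORDS:
        return SectionType.UNKNOWN, title
    return None


def split_sections(
    text: str, headers: dict[str, SectionType] | None = None
) -> list[Section]:
    """Split a report into typed sections on recognized title lines.

    Text before the first title becomes the IDENTIFICATION section; each
    section span excludes its title line (kept as metadata) and is
    trimmed to its non-whitespace extent.  Absent sections are simply not
    produced.
    """
    if headers is None:
        headers = DEFAULT_HEADERS
    # line offsets
    lines: list[tuple[int, str]] = []
    pos = 0
    for line in text.splitlines(keepends=True):
        lines.append((pos, line))
        pos += len(line)

    openers: list[tuple[int, int, SectionType, str]] = []  # (line_start, content_start, type, title)
    for start, line in lines:
        hit = _classify_header(line.rstrip("\n"), headers)
        if hit is not None:
            openers.append((start, start + len(line), hit[0], hit[1]))

    sections: list[Section] = []

    def _add(stype: SectionType, start: int, end: int, title: str) -> None:
        chunk = text[start:end]
        stripped = chunk.strip()
        if not stripped:
            return
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        sections.append(Section(stype, start + lead, end - trail, title))

    if not openers:
        _add(SectionType.IDENTIFICATION, 0, len(text), "")
        return sections

    _add(SectionType.IDENTIFICATION, 0, openers[0][0], "")
    for i, (_, content_start, stype, title) in enumerate(openers):
        next_start = openers[i + 1][0] if i + 1 < len(openers) else len(text)
        _add(stype, content_start, next_start, title)
    return sections
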