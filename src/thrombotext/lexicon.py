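"""Concept lexicon loading and dictionary-based concept pre-annotation.

The matcher is deliberately simple: a left-to-right, longest-match-first
scan anchored at token boundaries over case- and diacritic-folded text.
Token anchoring prevents an abbreviation such as "EP" from firing inside
an unrelated word.  Matches never overlap; after a match the scan
resumes at the first token past it.

The original 1242-term lexicon (674 anatomy, 278 thrombopathology, 207
incidental-finding terms, remainder exam and post-partum vocabulary) is
not redistributable; the package bundles a ~60-term demonstration
lexicon in the same tab-separated format (term, concept type,
provenance) and loads user lexicons of any size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import ConceptAnnotation, ConceptType, Report
from .preprocess import fold, tokenize

_TYPE_NAMES = {t.value: t for t in ConceptType}

#: Provenance priority when duplicate rows give the same term+type:
#: clinically-sourced entries shadow terminology-derived ones.
PROVENANCE_ORDER = ("clinical", "core", "finding")


class LexiconError(ValueError):
    pass


@dataclass
class Lexicon:
    """Mapping from normalized term to concept type (+ provenance tag)."""

    entries: dict[str, tuple[ConceptType, str]] = field(default_factory=dict)

    def add(self, term: str, concept_type: ConceptType,
            provenance: str = "core") -> None:
        key = fold(term)
        if not key:
            raise LexiconError("empty lexicon term")
        if key in self.entries:
            old_type, old_prov = self.entries[key]
            if old_type is not concept_type:
                raise LexiconError(
                    f"conflicting concept types for term {term!r}: "
                    f"{old_type.value} vs {concept_type.value}"
                )
            # same term+type from two sources: keep the higher-priority tag
            def rank(p: str) -> int:
                return (PROVENANCE_ORDER.index(p)
                        if p in PROVENANCE_ORDER else len(PROVENANCE_ORDER))
            if rank(provenance) < rank(old_prov):
                self.entries[key] = (concept_type, provenance)
            return
        self.entries[key] = (concept_type, provenance)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return fold(term) in self.entries

    def type_of(self, term: str) -> ConceptType:
        return self.entries[fold(term)][0]

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ctype, _ in self.entries.values():
            out[ctype.value] = out.get(ctype.value, 0) + 1
        return out


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a tab-separated lexicon: term, concept type, provenance.

    Terms are normalized on load; duplicate identical rows collapse,
    conflicting types for one term raise a :class:`LexiconError` naming
    the term, unknown concept types raise too.
    """
    lex = Lexicon()
    content = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise LexiconError(
                f"{path}:{lineno}: expected term<TAB>concept_type"
            )
        term, type_name = parts[0], parts[1]
        provenance = parts[2] if len(parts) > 2 else "core"
        if type_name not in _TYPE_NAMES:
            raise LexiconError(
                f"{path}:{lineno}: unknown concept type {type_name!r}"
            )
        lex.add(term, _TYPE_NAMES[type_name], provenance)
    if not lex.entries:
        warnings.warn(f"lexicon {path} is empty")
    return lex


def bundled_lexicon() -> Lexicon:
    """The demonstration lexicon shipped with the package."""
    ref = resources.files("thrombotext").joinpath("data/lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def match(report: Report, lexicon: Lexicon) -> list[ConceptAnnotation]:
    """Dictionary concept recognition over one report.

    Returns non-overlapping annotations sorted by start offset, ids
    numbered ``T1..Tn`` in document order.
    """
    if not lexicon.entries:
        return []
    max_tokens = max(
        len(tokenize(term)) for term in lexicon.entries
    )
    tokens = tokenize(report.text)
    out: list[ConceptAnnotation] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_tokens, len(tokens) - i), 0, -1):
            start = tokens[i].start
            end = tokens[i + n - 1].end
            key = fold(report.text[start:end])
            entry = lexicon.entries.get(key)
            if entry is not None:
                hit = (n, start, end, entry[0])
                break
        if hit is None:
            i += 1
            continue
        n, start, end, ctype = hit
        out.append(
            ConceptAnnotation(
                f"T{len(out) + 1}", ctype, start, end,
                report.text[start:end],
            )
        )
        i += n
    return out
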