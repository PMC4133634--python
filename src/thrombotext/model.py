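"""Core data model for sectioned radiology reports and their annotations.

A report is a UTF-8 text with an ordered list of non-overlapping sections
(identification, indication, protocol, results, conclusion).  Annotations
follow a five-concept scheme: thromboembolic conditions (``ThromboPat``),
clinically relevant findings (``K``), post-partum status (``PP``),
anatomical sites (``Anatomy``) and diagnostic procedures (``Exam``).
Condition concepts carry assertion modalities (positive / negative /
hypothetical, plus previously-known and incidental for findings) and
participate in two relation types: ``Location_of`` (condition -> anatomy)
and ``Reveals`` (exam -> condition).

All character offsets are 0-based, half-open, counted in Unicode code
points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SectionType(enum.Enum):
    IDENTIFICATION = "IDENTIFICATION"
    INDICATION = "INDICATION"
    PROTOCOL = "PROTOCOL"
    RESULTS = "RESULTS"
    CONCLUSION = "CONCLUSION"
    UNKNOWN = "UNKNOWN"


class ConceptType(enum.Enum):
    ANATOMY = "Anatomy"
    THROMBO_PAT = "ThromboPat"
    EXAM = "Exam"
    K = "K"
    PP = "PP"


class Modality(enum.Enum):
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    HYPOTHETICAL = "Hypothetical"
    KNOWN = "Known"
    INCIDENTAL = "Incidental"


class RelationType(enum.Enum):
    LOCATION_OF = "Location_of"
    REVEALS = "Reveals"


#: Concept types a given modality may attach to.
MODALITY_TARGETS: dict[Modality, frozenset[ConceptType]] = {
    Modality.POSITIVE: frozenset({ConceptType.THROMBO_PAT, ConceptType.K}),
    Modality.NEGATIVE: frozenset({ConceptType.THROMBO_PAT, ConceptType.K}),
    Modality.HYPOTHETICAL: frozenset({ConceptType.THROMBO_PAT, ConceptType.K}),
    Modality.KNOWN: frozenset({ConceptType.K}),
    Modality.INCIDENTAL: frozenset({ConceptType.K}),
}

#: Medical-condition concept types (possible Location_of first arguments,
#: Reveals second arguments).
CONDITION_TYPES = frozenset(
    {ConceptType.THROMBO_PAT, ConceptType.K, ConceptType.PP}
)


class IntegrityError(ValueError):
    """An annotation violates the scheme or does not match its text."""


@dataclass(frozen=True)
class Section:
    section_type: SectionType
    start: int
    end: int
    header: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid section span [{self.start}, {self.end})"
            )


@dataclass
class Report:
    report_id: str
    text: str
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for sec in self.sections:
            if sec.start < prev_end:
                raise ValueError(
                    f"report {self.report_id}: overlapping or unordered "
                    f"sections at offset {sec.start}"
                )
            if sec.end > len(self.text):
                raise ValueError(
                    f"report {self.report_id}: section end {sec.end} beyond "
                    f"text length {len(self.text)}"
                )
            prev_end = sec.end

    def section_at(self, offset: int) -> Section | None:
        """Section containing a character offset, or None in a gap."""
        for sec in self.sections:
            if sec.start <= offset < sec.end:
                return sec
        return None

    def section_text(self, section_type: SectionType) -> str:
        return " ".join(
            self.text[s.start:s.end]
            for s in self.sections
            if s.section_type is section_type
        )


@dataclass(frozen=True)
class ConceptAnnotation:
    ann_id: str
    concept_type: ConceptType
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"{self.ann_id}: invalid span [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ModalityAnnotation:
    ann_id: str
    target: str  # ConceptAnnotation id
    modality: Modality


@dataclass(frozen=True)
class RelationAnnotation:
    ann_id: str
    relation_type: RelationType
    arg1: str  # concept id
    arg2: str  # concept id


@dataclass(frozen=True)
class GoldLabels:
    report_id: str
    pe: int
    dvt: int
    incidentaloma: int

    def __post_init__(self) -> None:
        for name in ("pe", "dvt", "incidentaloma"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"label {name} must be 0 or 1")


@dataclass
class AnnotationSet:
    """Concepts, modalities and relations for one report, with scheme checks."""

    concepts: list[ConceptAnnotation] = field(default_factory=list)
    modalities: list[ModalityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def concept_by_id(self) -> dict[str, ConceptAnnotation]:
        return {c.ann_id: c for c in self.concepts}

    def validate(self, text: str | None = None) -> None:
        """Check referential integrity and the annotation-scheme constraints.

        With ``text`` given, additionally check that each concept's surface
        string equals the text at its offsets.
        """
        by_id = self.concept_by_id()
        if len(by_id) != len(self.concepts):
            raise IntegrityError("duplicate concept annotation ids")
        if text is not None:
            for c in self.concepts:
                if c.end > len(text):
                    raise IntegrityError(
                        f"{c.ann_id}: span [{c.start}, {c.end}) beyond text"
                    )
                if text[c.start:c.end] != c.surface:
                    raise IntegrityError(
                        f"{c.ann_id}: surface {c.surface!r} != text span "
                        f"{text[c.start:c.end]!r}"
                    )
        for m in self.modalities:
            target = by_id.get(m.target)
            if target is None:
                raise IntegrityError(
                    f"{m.ann_id}: dangling modality target {m.target}"
                )
            if target.concept_type not in MODALITY_TARGETS[m.modality]:
                raise IntegrityError(
                    f"{m.ann_id}: modality {m.modality.value} cannot attach "
                    f"to concept type {target.concept_type.value}"
                )
        for r in self.relations:
            a1, a2 = by_id.get(r.arg1), by_id.get(r.arg2)
            if a1 is None or a2 is None:
                raise IntegrityError(
                    f"{r.ann_id}: dangling relation argument"
                )
            if r.relation_type is RelationType.LOCATION_OF:
                if a1.concept_type not in CONDITION_TYPES:
                    raise IntegrityError(
                        f"{r.ann_id}: Location_of arg1 must be a condition, "
                        f"got {a1.concept_type.value}"
                    )
                if a2.concept_type is not ConceptType.ANATOMY:
                    raise IntegrityError(
                        f"{r.ann_id}: Location_of arg2 must be Anatomy, got "
                        f"{a2.concept_type.value}"
                    )
            else:  # Reveals
                if a1.concept_type is not ConceptType.EXAM:
                    raise IntegrityError(
                        f"{r.ann_id}: Reveals arg1 must be Exam, got "
                        f"{a1.concept_type.value}"
                    )
                if a2.concept_type not in CONDITION_TYPES:
                    raise IntegrityError(
                        f"{r.ann_id}: Reveals arg2 must be a condition, got "
                        f"{a2.concept_type.value}"
                    )
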