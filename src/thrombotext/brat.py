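"""Reading and writing the Brat standoff annotation format.

Brat stores annotations in a ``.ann`` file next to the ``.txt`` it
annotates: ``T`` lines for entities (type + character span + surface
copy), ``A`` lines for attributes and ``R`` lines for relations.  Two
attribute dialects occur in the wild and both are accepted on read::

    A1\tNegative T1           # binary attribute, name is the value
    A1\tModality T1 Negative  # valued attribute

On write the binary-attribute dialect is emitted.  Discontinuous spans
(semicolon-separated fragments) are rejected: the scheme here only uses
contiguous mentions.
"""

from __future__ import annotations

from .model import (
    AnnotationSet,
    ConceptAnnotation,
    ConceptType,
    IntegrityError,
    Modality,
    ModalityAnnotation,
    RelationAnnotation,
    RelationType,
)

_CONCEPT_NAMES = {t.value: t for t in ConceptType}
_MODALITY_NAMES = {m.value: m for m in Modality}
_RELATION_NAMES = {r.value: r for r in RelationType}


class BratParseError(ValueError):
    """A .ann line that does not follow the standoff conventions."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_entity(lineno: int, ann_id: str, body: str, rest: list[str],
                  text: str) -> ConceptAnnotation:
    if ";" in body:
        raise BratParseError(
            lineno, "discontinuous spans are not supported"
        )
    parts = body.split()
    if len(parts) != 3:
        raise BratParseError(lineno, f"malformed entity line: {body!r}")
    type_name, start_s, end_s = parts
    if type_name not in _CONCEPT_NAMES:
        raise BratParseError(lineno, f"unknown concept type {type_name!r}")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise BratParseError(lineno, f"non-integer offsets in {body!r}")
    surface = rest[0] if rest else ""
    ann = ConceptAnnotation(ann_id, _CONCEPT_NAMES[type_name], start, end,
                            surface)
    if end > len(text) or text[start:end] != surface:
        raise IntegrityError(
            f"{ann_id}: surface {surface!r} does not match text span "
            f"[{start}, {end}) = {text[start:end]!r}"
        )
    return ann


def _parse_attribute(lineno: int, ann_id: str,
                     body: str) -> ModalityAnnotation:
    parts = body.split()
    if len(parts) == 2:  # binary dialect: <Value> <Tid>
        value, target = parts
    elif len(parts) == 3:  # valued dialect: <Name> <Tid> <Value>
        _, target, value = parts
    else:
        raise BratParseError(lineno, f"malformed attribute line: {body!r}")
    if value not in _MODALITY_NAMES:
        raise BratParseError(lineno, f"unknown modality {value!r}")
    return ModalityAnnotation(ann_id, target, _MODALITY_NAMES[value])


def _parse_relation(lineno: int, ann_id: str,
                    body: str) -> RelationAnnotation:
    parts = body.split()
    if len(parts) != 3:
        raise BratParseError(lineno, f"malformed relation line: {body!r}")
    type_name = parts[0]
    if type_name not in _RELATION_NAMES:
        raise BratParseError(lineno, f"unknown relation type {type_name!r}")
    args = {}
    for p in parts[1:]:
        if ":" not in p:
            raise BratParseError(lineno, f"malformed relation argument {p!r}")
        role, ref = p.split(":", 1)
        args[role] = ref
    if set(args) != {"Arg1", "Arg2"}:
        raise BratParseError(
            lineno, f"relation needs Arg1 and Arg2, got {sorted(args)}"
        )
    return RelationAnnotation(ann_id, _RELATION_NAMES[type_name],
                              args["Arg1"], args["Arg2"])


def read_brat(text_content: str, ann_content: str) -> AnnotationSet:
    """Parse standoff annotations and validate them against the text.

    Raises :class:`BratParseError` on a malformed line (naming the line
    number) and :class:`~thrombotext.model.IntegrityError` when an entity
    surface disagrees with its offsets or a reference dangles.
    """
    annset = AnnotationSet()
    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise BratParseError(lineno, f"expected tab-separated fields: "
                                         f"{line!r}")
        ann_id, body, rest = fields[0], fields[1], fields[2:]
        if ann_id.startswith("T"):
            annset.concepts.append(
                _parse_entity(lineno, ann_id, body, rest, text_content)
            )
        elif ann_id.startswith("A"):
            annset.modalities.append(_parse_attribute(lineno, ann_id, body))
        elif ann_id.startswith("R"):
            annset.relations.append(_parse_relation(lineno, ann_id, body))
        else:
            raise BratParseError(
                lineno, f"unsupported annotation id prefix in {ann_id!r}"
            )
    annset.validate(text_content)
    return annset


def write_brat(annotations: AnnotationSet) -> str:
    """Serialize to standoff text: T lines first, then A, then R.

    Ids are renumbered sequentially; a read-after-write round trip
    reproduces the annotation set up to that renumbering.
    """
    annotations.validate()
    lines: list[str] = []
    id_map: dict[str, str] = {}
    for i, c in enumerate(annotations.concepts, start=1):
        new_id = f"T{i}"
        id_map[c.ann_id] = new_id
        lines.append(
            f"{new_id}\t{c.concept_type.value} {c.start} {c.end}\t{c.surface}"
        )
    for i, m in enumerate(annotations.modalities, start=1):
        lines.append(f"A{i}\t{m.modality.value} {id_map[m.target]}")
    for i, r in enumerate(annotations.relations, start=1):
        lines.append(
            f"R{i}\t{r.relation_type.value} "
            f"Arg1:{id_map[r.arg1]} Arg2:{id_map[r.arg2]}"
        )
    return "".join(line + "\n" for line in lines)
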