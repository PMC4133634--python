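"""Brat standoff parsing, writing, validation and round-trip identity."""

import pytest
from hypothesis import given, strategies as st

from thrombotext.brat import BratParseError, read_brat, write_brat
from thrombotext.model import (
    AnnotationSet,
    ConceptAnnotation,
    ConceptType,
    IntegrityError,
    Modality,
    ModalityAnnotation,
    RelationAnnotation,
    RelationType,
)

TEXT = "à 10 char embolie pulmonaire et le reste du texte ici"


def test_parse_entity_line():
    annset = read_brat(TEXT, "T1\tThromboPat 10 28\tembolie pulmonaire\n")
    (c,) = annset.concepts
    assert c.concept_type is ConceptType.THROMBO_PAT
    assert (c.start, c.end, c.surface) == (10, 28, "embolie pulmonaire")


@pytest.mark.parametrize("line", [
    "A1\tNegative T1",            # binary-attribute dialect
    "A1\tModality T1 Negative",   # valued-attribute dialect
])
def test_parse_attribute_both_dialects(line):
    ann = "T1\tThromboPat 10 28\tembolie pulmonaire\n" + line + "\n"
    annset = read_brat(TEXT, ann)
    (m,) = annset.modalities
    assert m.target == "T1" and m.modality is Modality.NEGATIVE


def test_parse_relation_line():
    ann = ("T1\tThromboPat 10 28\tembolie pulmonaire\n"
           "T2\tAnatomy 0 1\tà\n"
           "R1\tLocation_of Arg1:T1 Arg2:T2\n")
    annset = read_brat(TEXT, ann)
    (r,) = annset.relations
    assert r.relation_type is RelationType.LOCATION_OF
    assert (r.arg1, r.arg2) == ("T1", "T2")


def test_malformed_line_names_line_number():
    ann = "T1\tThromboPat 10 28\tembolie pulmonaire\nT2\tbogus\n"
    with pytest.raises(BratParseError, match="line 2"):
        read_brat(TEXT, ann)


def test_surface_offset_mismatch_is_integrity_error():
    with pytest.raises(IntegrityError):
        read_brat(TEXT, "T1\tThromboPat 10 28\twrong surface here\n")


def test_discontinuous_span_rejected():
    with pytest.raises(BratParseError, match="discontinuous"):
        read_brat(TEXT, "T1\tThromboPat 0 1;3 5\tà 1\n")


def test_dangling_modality_target_rejected():
    with pytest.raises(IntegrityError, match="dangling"):
        read_brat(TEXT, "A1\tNegative T9\n")


@pytest.mark.parametrize("ctype,modality", [
    ("Anatomy", "Negative"),   # assertion modalities only on conditions
    ("Exam", "Positive"),
    ("ThromboPat", "Incidental"),  # incidental/known only on findings (K)
    ("ThromboPat", "Known"),
])
def test_modality_scheme_violations_rejected(ctype, modality):
    ann = f"T1\t{ctype} 10 28\tembolie pulmonaire\nA1\t{modality} T1\n"
    with pytest.raises(IntegrityError):
        read_brat(TEXT, ann)


@pytest.mark.parametrize("t1,t2,rel", [
    ("Anatomy", "ThromboPat", "Location_of"),  # args swapped
    ("Exam", "Anatomy", "Reveals"),            # Reveals needs a condition
    ("ThromboPat", "K", "Location_of"),        # arg2 must be Anatomy
])
def test_relation_scheme_violations_rejected(t1, t2, rel):
    ann = (f"T1\t{t1} 0 1\tà\nT2\t{t2} 2 4\t10\n"
           f"R1\t{rel} Arg1:T1 Arg2:T2\n")
    with pytest.raises(IntegrityError):
        read_brat(TEXT, ann)


def test_write_empty_and_single():
    assert write_brat(AnnotationSet()) == ""
    annset = AnnotationSet(concepts=[
        ConceptAnnotation("T1", ConceptType.K, 0, 1, "à")
    ])
    assert write_brat(annset) == "T1\tK 0 1\tà\n"


def test_write_dangling_reference_rejected():
    annset = AnnotationSet(
        modalities=[ModalityAnnotation("A1", "T1", Modality.NEGATIVE)]
    )
    with pytest.raises(IntegrityError):
        write_brat(annset)


def _canonical(annset: AnnotationSet):
    """Id-free canonical form for round-trip comparison."""
    by_id = annset.concept_by_id()
    key = {cid: (c.concept_type.value, c.start, c.end, c.surface)
           for cid, c in by_id.items()}
    return (
        sorted(key.values()),
        sorted((m.modality.value, key[m.target]) for m in annset.modalities),
        sorted((r.relation_type.value, key[r.arg1], key[r.arg2])
               for r in annset.relations),
    )


def test_round_trip_concept_modality_relation():
    ann = ("T5\tThromboPat 10 28\tembolie pulmonaire\n"
           "T9\tAnatomy 0 1\tà\n"
           "A2\tPositive T5\n"
           "R4\tLocation_of Arg1:T5 Arg2:T9\n")
    annset = read_brat(TEXT, ann)
    out = write_brat(annset)
    lines = out.splitlines()
    assert [ln[0] for ln in lines] == ["T", "T", "A", "R"]
    assert _canonical(read_brat(TEXT, out)) == _canonical(annset)


_MOD_FOR = {
    ConceptType.THROMBO_PAT: [Modality.POSITIVE, Modality.NEGATIVE,
                              Modality.HYPOTHETICAL],
    ConceptType.K: list(Modality),
}


@st.composite
def annotated_text(draw):
    words = draw(st.lists(
        st.text(alphabet="abcdeéfgàh", min_size=1, max_size=6),
        min_size=3, max_size=15,
    ))
    text = " ".join(words)
    # carve non-overlapping spans out of the text
    n_spans = draw(st.integers(0, min(6, len(text) // 3)))
    bounds = sorted(draw(st.lists(
        st.integers(0, len(text)), min_size=2 * n_spans,
        max_size=2 * n_spans, unique=True,
    )))
    concepts, modalities, relations = [], [], []
    for i in range(n_spans):
        start, end = bounds[2 * i], bounds[2 * i + 1]
        if start >= end:
            continue
        ctype = draw(st.sampled_from(list(ConceptType)))
        cid = f"T{len(concepts) + 1}"
        concepts.append(
            ConceptAnnotation(cid, ctype, start, end, text[start:end])
        )
        if ctype in _MOD_FOR and draw(st.booleans()):
            modalities.append(ModalityAnnotation(
                f"A{len(modalities) + 1}", cid,
                draw(st.sampled_from(_MOD_FOR[ctype])),
            ))
    conditions = [c for c in concepts if c.concept_type in
                  (ConceptType.THROMBO_PAT, ConceptType.K, ConceptType.PP)]
    anatomies = [c for c in concepts if c.concept_type is ConceptType.ANATOMY]
    exams = [c for c in concepts if c.concept_type is ConceptType.EXAM]
    if conditions and anatomies and draw(st.booleans()):
        relations.append(RelationAnnotation(
            "R1", RelationType.LOCATION_OF,
            draw(st.sampled_from(conditions)).ann_id,
            draw(st.sampled_from(anatomies)).ann_id,
        ))
    if exams and conditions and draw(st.booleans()):
        relations.append(RelationAnnotation(
            f"R{len(relations) + 1}", RelationType.REVEALS,
            draw(st.sampled_from(exams)).ann_id,
            draw(st.sampled_from(conditions)).ann_id,
        ))
    return text, AnnotationSet(concepts, modalities, relations)


@given(annotated_text())
def test_round_trip_property(case):
    """Any valid annotation set survives write -> read up to renumbering."""
    text, annset = case
    assert _canonical(read_brat(text, write_brat(annset))) == \
        _canonical(annset)


def test_parsed_surfaces_match_text(small_corpus):
    reports, annsets, _ = small_corpus
    for r in reports[:20]:
        out = write_brat(annsets[r.report_id])
        parsed = read_brat(r.text, out)
        for c in parsed.concepts:
            assert r.text[c.start:c.end] == c.surface
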