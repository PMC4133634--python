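"""Balanced split construction, task evaluation, inter-annotator agreement."""

import pytest

from thrombotext.experiment import (
    SplitSpec,
    compute_iaa,
    default_replication,
    evaluate_task,
    make_split,
    task_label,
)
from thrombotext.model import (
    AnnotationSet,
    ConceptAnnotation,
    ConceptType,
    GoldLabels,
    RelationAnnotation,
    RelationType,
)


def _labels(n_pos, n_neg):
    labels = {}
    ids = []
    for i in range(n_pos + n_neg):
        rid = f"r{i:04d}"
        ids.append(rid)
        labels[rid] = GoldLabels(rid, int(i < n_pos), 0, 0)
    return ids, labels


def test_split_counts_triple_replication():
    """40 positives and 400 negatives left after the test draw,
    replication x3: 120 positive instances + 120 negatives."""
    ids, labels = _labels(40, 500)
    spec = SplitSpec(n_test=100, positive_replication=3, seed=0)
    train, test = make_split(ids, labels, "pe", spec)
    assert len(test) == 100
    pos = [r for r in train if labels[r].pe == 1]
    neg = [r for r in train if labels[r].pe == 0]
    n_pos_remaining = sum(1 for r in ids if labels[r].pe and r not in test)
    assert len(pos) == 3 * n_pos_remaining
    assert len(neg) == len(pos)
    assert len(set(neg)) == len(neg)  # negatives sampled w/o replacement


def test_no_test_report_in_train():
    ids, labels = _labels(40, 400)
    train, test = make_split(ids, labels, "pe",
                             SplitSpec(100, 3, seed=1))
    assert set(train).isdisjoint(test)


def test_split_reproducible_and_test_shared_across_tasks():
    ids, labels = _labels(60, 300)
    spec = SplitSpec(80, 3, seed=5)
    t1 = make_split(ids, labels, "pe", spec)
    t2 = make_split(ids, labels, "pe", spec)
    assert t1 == t2
    _, test_pe = make_split(ids, labels, "pe", spec)
    _, test_inc = make_split(ids, labels, "incidentaloma",
                             SplitSpec(80, 5, seed=5))
    assert test_pe == test_inc


def test_replication_one_equal_classes_keeps_all():
    ids, labels = _labels(100, 120)
    train, test = make_split(ids, labels, "pe", SplitSpec(20, 1, seed=2))
    pos = sum(labels[r].pe for r in train)
    assert pos == len(train) - pos  # balanced


def test_fewer_negatives_than_needed_warns_and_uses_all():
    ids, labels = _labels(80, 50)
    with pytest.warns(UserWarning, match="negatives"):
        train, _ = make_split(ids, labels, "pe", SplitSpec(10, 3, seed=3))
    neg = [r for r in train if labels[r].pe == 0]
    assert len(set(neg)) == len(neg)


def test_task_labels_and_replication_defaults():
    g = GoldLabels("r", 1, 0, 1)
    assert [task_label(g, t) for t in
            ("pe", "dvt", "pe_dvt", "incidentaloma")] == [1, 0, 1, 1]
    assert default_replication("incidentaloma") == 5
    assert default_replication("dvt") == 3
    with pytest.raises(ValueError):
        task_label(g, "bogus")


def _eval_from_counts(tp, fp, fn, tn):
    gold, preds = {}, {}
    i = 0
    for n, (p, t) in [(tp, (1, 1)), (fp, (1, 0)), (fn, (0, 1)),
                      (tn, (0, 0))]:
        for _ in range(n):
            rid = f"r{i}"
            preds[rid] = p
            gold[rid] = GoldLabels(rid, t, t, t)
            i += 1
    return evaluate_task(preds, gold, "pe")


def test_evaluate_printed_triple():
    """Confusion counts realizing the printed naive-Bayes baseline row
    for the venous-thrombosis task: P=0.42, R=0.89 give F=0.57."""
    res = _eval_from_counts(tp=16, fp=22, fn=2, tn=60)
    assert round(res.precision, 2) == 0.42
    assert round(res.recall, 2) == 0.89
    assert round(res.f_measure, 2) == 0.57


def test_evaluate_perfect_and_degenerate():
    perfect = _eval_from_counts(tp=10, fp=0, fn=0, tn=90)
    assert (perfect.precision, perfect.recall, perfect.f_measure) == \
        (1.0, 1.0, 1.0)
    silent = _eval_from_counts(tp=0, fp=0, fn=5, tn=95)
    assert silent.recall == 0.0 and silent.f_measure == 0.0


# ---------------------------------------------------------------------------
# inter-annotator agreement

def _ents(spans, ctype=ConceptType.K, prefix="T"):
    return [
        ConceptAnnotation(f"{prefix}{i + 1}", ctype, s, e, "x" * (e - s))
        for i, (s, e) in enumerate(spans)
    ]


def _sets(concepts_a, concepts_b, rel_a=(), rel_b=()):
    return (
        {"r1": AnnotationSet(concepts=list(concepts_a),
                             relations=list(rel_a))},
        {"r1": AnnotationSet(concepts=list(concepts_b),
                             relations=list(rel_b))},
    )


def test_identical_sets_full_agreement():
    ents = _ents([(0, 5), (10, 15)])
    a, b = _sets(ents, ents)
    for mode in ("exact", "inexact"):
        res = compute_iaa(a, b, mode)
        assert res.entity_overall.f_measure == 1.0


def test_shifted_spans_exact_zero_inexact_full():
    a, b = _sets(_ents([(0, 5)]), _ents([(1, 6)]))
    assert compute_iaa(a, b, "exact").entity_overall.f_measure == 0.0
    assert compute_iaa(a, b, "inexact").entity_overall.f_measure == 1.0


def _ten_entity_fixture():
    """7 exact matches, 2 overlap-only, 1 unmatched on each side."""
    spans_a = [(i * 20, i * 20 + 5) for i in range(7)]
    spans_b = list(spans_a)
    spans_a += [(200, 210), (300, 310)]      # overlap-only pairs
    spans_b += [(205, 215), (305, 315)]
    spans_a += [(400, 405)]                  # unmatched in A
    spans_b += [(500, 505)]                  # unmatched in B
    return _sets(_ents(spans_a), _ents(spans_b, prefix="U"))


def test_constructed_ten_entity_agreement():
    a, b = _ten_entity_fixture()
    exact = compute_iaa(a, b, "exact").entity_overall
    inexact = compute_iaa(a, b, "inexact").entity_overall
    assert 100 * exact.f_measure == pytest.approx(70.0)
    assert 100 * inexact.f_measure == pytest.approx(90.0)


def test_f_symmetric_precision_recall_swap():
    a, b = _ten_entity_fixture()
    fwd = compute_iaa(a, b, "inexact").entity_overall
    rev = compute_iaa(b, a, "inexact").entity_overall
    assert fwd.precision == rev.recall
    assert fwd.recall == rev.precision
    assert fwd.f_measure == pytest.approx(rev.f_measure)


def test_inexact_at_least_exact_on_generated_annotations(
    small_corpus, lexicon
):
    from thrombotext.lexicon import match

    reports, gold, _ = small_corpus
    pre = {
        r.report_id: AnnotationSet(concepts=match(r, lexicon))
        for r in reports[:30]
    }
    gold30 = {rid: gold[rid] for rid in pre}
    exact = compute_iaa(gold30, pre, "exact").entity_overall.f_measure
    inexact = compute_iaa(gold30, pre, "inexact").entity_overall.f_measure
    assert inexact >= exact


def test_relation_agreement_requires_matched_arguments():
    ca = _ents([(0, 5)], ConceptType.THROMBO_PAT) + \
        _ents([(10, 15)], ConceptType.ANATOMY, prefix="S")
    rel_a = [RelationAnnotation("R1", RelationType.LOCATION_OF,
                                "T1", "S1")]
    # annotator B shifts the anatomy span by one character
    cb = _ents([(0, 5)], ConceptType.THROMBO_PAT) + \
        _ents([(11, 16)], ConceptType.ANATOMY, prefix="S")
    rel_b = [RelationAnnotation("R1", RelationType.LOCATION_OF,
                                "T1", "S1")]
    a, b = _sets(ca, cb, rel_a, rel_b)
    assert compute_iaa(a, b, "exact").relation_overall.f_measure == 0.0
    assert compute_iaa(a, b, "inexact").relation_overall.f_measure == 1.0


def test_disjoint_reports_rejected():
    a = {"r1": AnnotationSet()}
    b = {"r2": AnnotationSet()}
    with pytest.raises(ValueError, match="disjoint"):
        compute_iaa(a, b)
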