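"""Train/test construction, task evaluation and inter-annotator agreement.

The class distribution of CTA/CTV reports is heavily skewed towards
negatives, so training sets are rebalanced by positive replication: the
held-out test set (default 100 reports) stays imbalanced to reflect
clinical reality, while in the remaining reports each positive is
replicated (x3 for the thromboembolic tasks, x5 for incidental
findings) and negatives are subsampled without replacement down to the
replicated-positive count.  Cross-validation is deliberately not used:
replicated copies of a positive would land in both folds and bias the
estimate.

Inter-annotator agreement is scored as F-measure between two annotation
sets: entities match exactly (identical span and concept type) or
inexactly (overlapping span, identical type), paired greedily one-to-one
in start-offset order; a relation matches when its type is identical and
both arguments are matched entities.  Per-category F plus a
micro-averaged overall F are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AnnotationSet, ConceptAnnotation, GoldLabels
from .query import EvalResult

TASKS = ("pe", "dvt", "pe_dvt", "incidentaloma")


def task_label(gold: GoldLabels, task: str) -> int:
    if task == "pe":
        return gold.pe
    if task == "dvt":
        return gold.dvt
    if task == "pe_dvt":  # PE and/or DVT, the disjunction of the two
        return int(gold.pe or gold.dvt)
    if task == "incidentaloma":
        return gold.incidentaloma
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def default_replication(task: str) -> int:
    """x5 for the rarer incidental-finding positives, x3 otherwise."""
    return 5 if task == "incidentaloma" else 3


@dataclass(frozen=True)
class SplitSpec:
    n_test: int = 100
    positive_replication: int = 3
    seed: int = 0
    adjust_negatives: bool = True

    def __post_init__(self) -> None:
        if self.n_test <= 0:
            raise ValueError("n_test must be positive")
        if self.positive_replication < 1:
            raise ValueError("positive_replication must be >= 1")


def make_split(
    report_ids: list[str],
    labels: dict[str, GoldLabels],
    task: str,
    spec: SplitSpec,
) -> tuple[list[str], list[str]]:
    """Return (train ids with multiplicity, test ids).

    The test set is sampled uniformly without replacement and is shared
    across tasks for a given seed; the train side is task-dependent
    through the positive/negative partition.
    """
    if spec.n_test >= len(report_ids):
        raise ValueError("n_test must be smaller than the corpus")
    missing = [r for r in report_ids if r not in labels]
    if missing:
        raise ValueError(f"labels missing for reports: {missing[:5]}")
    rng = np.random.default_rng(spec.seed)
    ids = sorted(report_ids)
    test = sorted(rng.choice(ids, size=spec.n_test, replace=False).tolist())
    test_set = set(test)
    remainder = [r for r in ids if r not in test_set]
    positives = [r for r in remainder if task_label(labels[r], task) == 1]
    negatives = [r for r in remainder if task_label(labels[r], task) == 0]
    train = positives * spec.positive_replication
    if spec.adjust_negatives:
        n_neg = len(train)
        if n_neg > len(negatives):
            warnings.warn(
                f"task {task}: only {len(negatives)} negatives available "
                f"for {n_neg} replicated positives; using all"
            )
            n_neg = len(negatives)
        train += sorted(
            rng.choice(negatives, size=n_neg, replace=False).tolist()
        )
    else:
        train += negatives
    return train, test


def evaluate_task(
    predictions: dict[str, int],
    gold: dict[str, GoldLabels],
    task: str,
) -> EvalResult:
    """Document-level precision / recall / F for one binary task."""
    tp = fp = fn = tn = 0
    for report_id, pred in predictions.items():
        truth = task_label(gold[report_id], task)
        if pred == 1 and truth == 1:
            tp += 1
        elif pred == 1 and truth == 0:
            fp += 1
        elif pred == 0 and truth == 1:
            fn += 1
        else:
            tn += 1
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# inter-annotator agreement

def _entity_match(
    a: ConceptAnnotation, b: ConceptAnnotation, mode: str
) -> bool:
    if a.concept_type is not b.concept_type:
        return False
    if mode == "exact":
        return a.start == b.start and a.end == b.end
    return a.start < b.end and b.start < a.end  # span overlap


def _pair_entities(
    ents_a: list[ConceptAnnotation],
    ents_b: list[ConceptAnnotation],
    mode: str,
) -> dict[str, str]:
    """Greedy one-to-one pairing in start-offset order; a -> b ids."""
    order = lambda e: (e.start, e.end, e.ann_id)
    pairs: dict[str, str] = {}
    taken: set[str] = set()
    for a in sorted(ents_a, key=order):
        for b in sorted(ents_b, key=order):
            if b.ann_id in taken:
                continue
            if _entity_match(a, b, mode):
                pairs[a.ann_id] = b.ann_id
                taken.add(b.ann_id)
                break
    return pairs


@dataclass
class IAAResult:
    mode: str
    entity_by_category: dict[str, EvalResult] = field(default_factory=dict)
    entity_overall: EvalResult = EvalResult(0, 0, 0)
    relation_by_category: dict[str, EvalResult] = field(default_factory=dict)
    relation_overall: EvalResult = EvalResult(0, 0, 0)


def compute_iaa(
    annots_a: dict[str, AnnotationSet],
    annots_b: dict[str, AnnotationSet],
    mode: str = "exact",
) -> IAAResult:
    """Agreement between two annotators over a common set of reports.

    Annotator A is the reference: recall counts A's annotations as the
    denominator, precision counts B's.  Overall scores micro-average the
    per-category counts.
    """
    if mode not in ("exact", "inexact"):
        raise ValueError("mode must be 'exact' or 'inexact'")
    common = set(annots_a) & set(annots_b)
    if not common:
        raise ValueError("annotation sets cover disjoint reports")

    ent_counts: dict[str, list[int]] = {}   # category -> [tp, fp, fn]
    rel_counts: dict[str, list[int]] = {}

    for report_id in sorted(common):
        sa, sb = annots_a[report_id], annots_b[report_id]
        pairs = _pair_entities(sa.concepts, sb.concepts, mode)
        by_id_a = sa.concept_by_id()
        by_id_b = sb.concept_by_id()

        matched_b = set(pairs.values())
        for a in sa.concepts:
            cat = a.concept_type.value
            c = ent_counts.setdefault(cat, [0, 0, 0])
            if a.ann_id in pairs:
                c[0] += 1
            else:
                c[2] += 1
        for b in sb.concepts:
            if b.ann_id not in matched_b:
                c = ent_counts.setdefault(b.concept_type.value, [0, 0, 0])
                c[1] += 1

        # relations: both arguments must be paired entities
        def rel_key(r, by_id):
            return (
                f"{r.relation_type.value}:"
                f"{by_id[r.arg1].concept_type.value}:"
                f"{by_id[r.arg2].concept_type.value}"
            )

        matched_rel_b: set[str] = set()
        for ra in sa.relations:
            cat = rel_key(ra, by_id_a)
            c = rel_counts.setdefault(cat, [0, 0, 0])
            hit = None
            for rb in sb.relations:
                if rb.ann_id in matched_rel_b:
                    continue
                if (rb.relation_type is ra.relation_type
                        and pairs.get(ra.arg1) == rb.arg1
                        and pairs.get(ra.arg2) == rb.arg2):
                    hit = rb
                    break
            if hit is not None:
                matched_rel_b.add(hit.ann_id)
                c[0] += 1
            else:
                c[2] += 1
        for rb in sb.relations:
            if rb.ann_id not in matched_rel_b:
                c = rel_counts.setdefault(rel_key(rb, by_id_b), [0, 0, 0])
                c[1] += 1

    def summarize(
        counts: dict[str, list[int]]
    ) -> tuple[dict[str, EvalResult], EvalResult]:
        by_cat = {
            cat: EvalResult(tp=c[0], fp=c[1], fn=c[2])
            for cat, c in sorted(counts.items())
        }
        overall = EvalResult(
            tp=sum(c[0] for c in counts.values()),
            fp=sum(c[1] for c in counts.values()),
            fn=sum(c[2] for c in counts.values()),
        )
        return by_cat, overall

    result = IAAResult(mode=mode)
    result.entity_by_category, result.entity_overall = summarize(ent_counts)
    result.relation_by_category, result.relation_overall = summarize(
        rel_counts
    )
    return result
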