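"""End-to-end run: corpus -> selection -> annotation -> features ->
balanced split -> classifier -> evaluation -> agreement.

A declarative :class:`RunConfig` (YAML-loadable) drives every stage;
one seed governs the generator, the split and nothing else (both
classifiers are deterministic), so identical configs produce identical
outputs.  Every written artifact starts with a provenance header naming
the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import corpus_io
from .classifiers import (
    predict_maxent_many,
    predict_nb_many,
    train_maxent,
    train_nb,
)
from .experiment import (
    SplitSpec,
    TASKS,
    compute_iaa,
    default_replication,
    evaluate_task,
    task_label,
)
from .features import FeatureConfig, FeatureSpace
from .lexicon import bundled_lexicon, load_lexicon, match
from .model import AnnotationSet
from .query import DEFAULT_LIST_A, DEFAULT_LIST_B, QuerySpec, load_term_list, select_reports
from .synthetic import DEFAULT_JOINT_PE_DVT, GeneratorConfig, generate_corpus

log = logging.getLogger("thrombotext")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    # corpus: either a directory of .txt/.ann + labels file, or generated
    corpus_dir: str | None = None
    labels_file: str | None = None
    n_reports: int = 600
    noise: float = 0.0
    lexicon_file: str | None = None
    list_a_file: str | None = None
    list_b_file: str | None = None
    annotations: str = "gold"  # features use gold or matcher annotations
    classifier: str = "maxent"  # nb | maxent
    nb_alpha: float = 1.0
    maxent_l1: float = 0.0
    maxent_l2: float = 1.0
    n_test: int = 100
    feature: dict = field(default_factory=lambda: {
        "use_text": True, "ngram_order": 1, "stopword_filter": True,
        "use_annotations": True,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location does not change identity
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"config_hash={config.digest()} seed={config.seed}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the per-task evaluation summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.digest(), "seed": config.seed,
                     "tasks": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrap

    # --- corpus ---------------------------------------------------------
    def _corpus():
        if config.corpus_dir:
            reports, annsets = corpus_io.read_corpus(config.corpus_dir)
            if not config.labels_file:
                raise ValueError("labels_file required with corpus_dir")
            labels = corpus_io.read_labels(config.labels_file)
            return reports, annsets, labels
        gen = GeneratorConfig(
            n_reports=config.n_reports,
            joint_pe_dvt=dict(DEFAULT_JOINT_PE_DVT),
            seed=config.seed,
            noise=config.noise,
        )
        reports, annsets, labels = generate_corpus(gen)
        corpus_io.write_corpus(out / "corpus", reports, annsets)
        corpus_io.write_labels(out / "labels.tsv", labels,
                               header_comment=_provenance(config))
        return reports, annsets, labels

    reports, gold_annsets, labels = stage("corpus")(_corpus)

    # --- selection ------------------------------------------------------
    def _select():
        list_a = (load_term_list(config.list_a_file)
                  if config.list_a_file else DEFAULT_LIST_A)
        list_b = (load_term_list(config.list_b_file)
                  if config.list_b_file else DEFAULT_LIST_B)
        selected = select_reports(reports, QuerySpec(frozenset(list_a),
                                                     frozenset(list_b)))
        with open(out / "selected.txt", "w", encoding="utf-8") as fh:
            fh.write(f"# {_provenance(config)}\n")
            for rid in sorted(selected):
                fh.write(rid + "\n")
        return selected

    selected = stage("select")(_select)
    summary["n_selected"] = len(selected)

    # --- pre-annotation -------------------------------------------------
    def _annotate():
        lex = (load_lexicon(config.lexicon_file)
               if config.lexicon_file else bundled_lexicon())
        pre = {}
        for r in reports:
            pre[r.report_id] = AnnotationSet(concepts=match(r, lex))
        corpus_io.write_corpus(out / "pre_ann", reports, pre)
        return pre

    matcher_annsets = stage("annotate")(_annotate)

    annsets = gold_annsets if config.annotations == "gold" else matcher_annsets

    # --- classification per task ---------------------------------------
    feat_config = FeatureConfig(**config.feature)
    by_id = {r.report_id: r for r in reports}

    def _classify():
        rows = []
        for task in TASKS:
            spec = SplitSpec(
                n_test=config.n_test,
                positive_replication=default_replication(task),
                seed=config.seed,
            )
            train_ids, test_ids = make_split_ids(reports, labels, task, spec)
            space = FeatureSpace(feat_config).fit(
                [by_id[i] for i in sorted(set(train_ids))], annsets
            )
            train_vecs = space.transform(
                [by_id[i] for i in train_ids], annsets
            )
            test_vecs = space.transform([by_id[i] for i in test_ids], annsets)
            X_train = [train_vecs[i] for i in train_ids]
            y_train = [task_label(labels[i], task) for i in train_ids]
            X_test = [test_vecs[i] for i in test_ids]
            if config.classifier == "nb":
                model = train_nb(X_train, y_train, space.n_features,
                                 alpha=config.nb_alpha)
                preds = predict_nb_many(model, X_test)
            else:
                model = train_maxent(X_train, y_train, space.n_features,
                                     l1=config.maxent_l1,
                                     l2=config.maxent_l2)
                preds = predict_maxent_many(model, X_test)
            predictions = {i: p[0] for i, p in zip(test_ids, preds)}
            res = evaluate_task(predictions, labels, task)
            rows.append((task, res))
            summary["tasks"][task] = {
                "tp": res.tp, "fp": res.fp, "fn": res.fn, "tn": res.tn,
                "precision": res.precision, "recall": res.recall,
                "f_measure": res.f_measure,
            }
        with open(out / "evaluation.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# {_provenance(config)}\n")
            fh.write("task\tclassifier\ttp\tfp\tfn\ttn\tprecision\trecall"
                     "\tf_measure\n")
            for task, res in rows:
                fh.write(
                    f"{task}\t{config.classifier}\t{res.tp}\t{res.fp}\t"
                    f"{res.fn}\t{res.tn}\t{res.precision:.4f}\t"
                    f"{res.recall:.4f}\t{res.f_measure:.4f}\n"
                )
        return rows

    stage("classify")(_classify)

    # --- agreement gold vs matcher pre-annotation -----------------------
    def _iaa():
        if not gold_annsets:
            return None
        scores = {}
        for mode in ("exact", "inexact"):
            res = compute_iaa(gold_annsets, matcher_annsets, mode=mode)
            scores[mode] = res
        with open(out / "iaa.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# {_provenance(config)}\n")
            fh.write("mode\tcategory\ttp\tfp\tfn\tf_measure\n")
            for mode, res in scores.items():
                for cat, er in [("entities_overall", res.entity_overall),
                                *res.entity_by_category.items(),
                                ("relations_overall", res.relation_overall),
                                *res.relation_by_category.items()]:
                    fh.write(f"{mode}\t{cat}\t{er.tp}\t{er.fp}\t{er.fn}\t"
                             f"{er.f_measure:.4f}\n")
        summary["iaa"] = {
            mode: res.entity_overall.f_measure
            for mode, res in scores.items()
        }
        return scores

    stage("iaa")(_iaa)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def make_split_ids(reports, labels, task, spec):
    from .experiment import make_split

    return make_split([r.report_id for r in reports], labels, task, spec)
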