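"""Binary feature extraction from reports and their annotations.

Every report becomes a set of named binary features (presence encoding):

* ``tok:<word>`` / ``big:<w1>_<w2>`` — lowercased text unigrams and
  bigrams;
* ``con:<Type>:<surface>`` — a concept mention (surface normalized);
* ``mod:<Modality>:<Type>:<surface>`` — a modality-qualified concept,
  so an asserted and a negated mention of the same condition yield
  different features;
* ``rel:<RelType>:<Type1>:<Type2>`` — a relation, encoded by argument
  concept types (surfaces optional).

Feature names may additionally be prefixed by the section the feature
was extracted from (``sec:RESULTS|...``), or extraction may be
restricted to the critical sections (results + conclusion) that carry
the diagnostic statements.

The feature index is built on the training corpus and frozen: features
seen only at test time are dropped.  The stopword filter removes text
n-grams whose training document frequency is above an upper bound
(frequent, non-discriminating) or below a lower bound (hapax noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .model import AnnotationSet, Report, SectionType
from .preprocess import fold, tokenize

CRITICAL_SECTIONS = frozenset({SectionType.RESULTS, SectionType.CONCLUSION})


@dataclass(frozen=True)
class FeatureConfig:
    use_text: bool = True
    ngram_order: Literal[1, 2] = 1
    stopword_filter: bool = False
    max_df: float = 0.8  # fraction of training documents
    min_df: int = 2      # absolute document count
    use_annotations: bool = False
    section_typing: bool = False
    section_restriction: Literal[None, "critical"] = None
    relation_surfaces: bool = False

    def __post_init__(self) -> None:
        if not (self.use_text or self.use_annotations):
            raise ValueError(
                "at least one of use_text / use_annotations must be enabled"
            )
        if self.ngram_order not in (1, 2):
            raise ValueError("ngram_order must be 1 or 2")
        if self.section_typing and self.section_restriction is not None:
            raise ValueError(
                "section_typing and section_restriction are mutually "
                "exclusive"
            )
        if self.section_restriction not in (None, "critical"):
            raise ValueError("section_restriction must be None or 'critical'")


def _norm_surface(surface: str) -> str:
    return fold(surface).replace(" ", "_")


def _sec_prefix(report: Report, offset: int) -> str:
    sec = report.section_at(offset)
    name = sec.section_type.value if sec is not None else "NONE"
    return f"sec:{name}|"


def _offset_allowed(report: Report, offset: int, config: FeatureConfig) -> bool:
    if config.section_restriction != "critical":
        return True
    sec = report.section_at(offset)
    return sec is not None and sec.section_type in CRITICAL_SECTIONS


def text_features(report: Report, config: FeatureConfig) -> set[str]:
    """Unigram (and optionally bigram) presence features, unfiltered."""
    feats: set[str] = set()
    tokens = [
        t for t in tokenize(report.text)
        if _offset_allowed(report, t.start, config)
    ]
    for t in tokens:
        name = f"tok:{t.lower}"
        if config.section_typing:
            name = _sec_prefix(report, t.start) + name
        feats.add(name)
    if config.ngram_order >= 2:
        for a, b in zip(tokens, tokens[1:]):
            # bigrams do not straddle section boundaries
            if report.section_at(a.start) is not report.section_at(b.start):
                continue
            name = f"big:{a.lower}_{b.lower}"
            if config.section_typing:
                name = _sec_prefix(report, a.start) + name
            feats.add(name)
    return feats


def annotation_features(
    report: Report, annset: AnnotationSet, config: FeatureConfig
) -> set[str]:
    """Concept / modality / relation presence features."""
    feats: set[str] = set()
    by_id = annset.concept_by_id()

    def emit(name: str, anchor: int) -> None:
        if not _offset_allowed(report, anchor, config):
            return
        if config.section_typing:
            name = _sec_prefix(report, anchor) + name
        feats.add(name)

    for c in annset.concepts:
        emit(f"con:{c.concept_type.value}:{_norm_surface(c.surface)}", c.start)
    for m in annset.modalities:
        c = by_id[m.target]
        emit(
            f"mod:{m.modality.value}:{c.concept_type.value}:"
            f"{_norm_surface(c.surface)}",
            c.start,
        )
    for r in annset.relations:
        a1, a2 = by_id[r.arg1], by_id[r.arg2]
        if config.relation_surfaces:
            name = (f"rel:{r.relation_type.value}:"
                    f"{a1.concept_type.value}:{_norm_surface(a1.surface)}:"
                    f"{a2.concept_type.value}:{_norm_surface(a2.surface)}")
        else:
            name = (f"rel:{r.relation_type.value}:"
                    f"{a1.concept_type.value}:{a2.concept_type.value}")
        emit(name, a1.start)
    return feats


def report_features(
    report: Report,
    annset: AnnotationSet | None,
    config: FeatureConfig,
) -> set[str]:
    feats: set[str] = set()
    if config.use_text:
        feats |= text_features(report, config)
    if config.use_annotations and annset is not None:
        feats |= annotation_features(report, annset, config)
    return feats


def _is_text_feature(name: str) -> bool:
    core = name.split("|", 1)[-1]
    return core.startswith(("tok:", "big:"))


@dataclass
class FeatureSpace:
    """Frozen, sorted feature-name index fitted on a training corpus."""

    config: FeatureConfig
    names: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def fit(
        self,
        reports: Iterable[Report],
        annsets: dict[str, AnnotationSet] | None,
    ) -> "FeatureSpace":
        reports = list(reports)
        df: dict[str, int] = {}
        for r in reports:
            annset = (annsets or {}).get(r.report_id)
            for name in report_features(r, annset, self.config):
                df[name] = df.get(name, 0) + 1
        kept = set(df)
        if self.config.stopword_filter:
            n_docs = len(reports)
            hi = self.config.max_df * n_docs
            lo = self.config.min_df
            kept = {
                name for name, d in df.items()
                if not _is_text_feature(name) or lo <= d <= hi
            }
        self.names = sorted(kept)
        self.index = {name: i for i, name in enumerate(self.names)}
        return self

    def transform(
        self,
        reports: Iterable[Report],
        annsets: dict[str, AnnotationSet] | None,
    ) -> dict[str, frozenset[int]]:
        """Binary vectors as index sets; unindexed (unseen) features drop."""
        out: dict[str, frozenset[int]] = {}
        for r in reports:
            annset = (annsets or {}).get(r.report_id)
            feats = report_features(r, annset, self.config)
            out[r.report_id] = frozenset(
                self.index[name] for name in feats if name in self.index
            )
        return out

    @property
    def n_features(self) -> int:
        return len(self.names)


def build_matrix(
    reports: list[Report],
    annsets: dict[str, AnnotationSet] | None,
    config: FeatureConfig,
) -> tuple[FeatureSpace, dict[str, frozenset[int]]]:
    """Fit a feature space on these reports and vectorize them."""
    space = FeatureSpace(config).fit(reports, annsets)
    return space, space.transform(reports, annsets)


# ---------------------------------------------------------------------------
# serialization

def write_matrix(
    path, space: FeatureSpace, vectors: dict[str, frozenset[int]],
    header_comment: str | None = None,
) -> None:
    """Sparse text format: feature table then one line per report."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for i, name in enumerate(space.names):
            fh.write(f"@feature\t{i}\t{name}\n")
        for report_id in sorted(vectors):
            ids = " ".join(str(i) for i in sorted(vectors[report_id]))
            fh.write(f"{report_id}\t{ids}\n")


def read_matrix(path) -> tuple[list[str], dict[str, frozenset[int]]]:
    names: list[str] = []
    vectors: dict[str, frozenset[int]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("@feature\t"):
                _, idx, name = line.split("\t", 2)
                assert int(idx) == len(names)
                names.append(name)
            else:
                report_id, _, ids = line.partition("\t")
                vectors[report_id] = frozenset(
                    int(i) for i in ids.split() if i
                )
    return names, vectors


def to_arff(
    relation: str,
    space: FeatureSpace,
    vectors: dict[str, frozenset[int]],
    labels: dict[str, int],
) -> str:
    """Attribute-relation file format export for external toolkits."""
    def q(name: str) -> str:
        return "'" + name.replace("\\", "\\\\").replace("'", "\\'") + "'"

    lines = [f"@RELATION {relation}", ""]
    for name in space.names:
        lines.append(f"@ATTRIBUTE {q(name)} {{0,1}}")
    lines.append("@ATTRIBUTE 'class' {0,1}")
    lines.extend(["", "@DATA"])
    for report_id in sorted(vectors):
        present = vectors[report_id]
        row = ["1" if i in present else "0" for i in range(space.n_features)]
        row.append(str(labels[report_id]))
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"
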