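"""Corpus directory and gold-label table I/O.

A corpus directory holds one ``<report_id>.txt`` per report, optionally
paired with ``<report_id>.ann`` standoff annotations.  Gold labels live
in a tab-separated table with columns report_id / pe / dvt /
incidentaloma.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .brat import read_brat, write_brat
from .model import AnnotationSet, GoldLabels, Report
from .preprocess import split_sections


def read_corpus(
    corpus_dir: str | os.PathLike,
    sectionize: bool = True,
) -> tuple[list[Report], dict[str, AnnotationSet]]:
    """Load all ``.txt`` reports (sorted by id) and any ``.ann`` partners."""
    corpus_dir = Path(corpus_dir)
    reports: list[Report] = []
    annsets: dict[str, AnnotationSet] = {}
    for txt_path in sorted(corpus_dir.glob("*.txt")):
        report_id = txt_path.stem
        text = txt_path.read_text(encoding="utf-8")
        sections = split_sections(text) if sectionize else []
        reports.append(Report(report_id, text, sections))
        ann_path = txt_path.with_suffix(".ann")
        if ann_path.exists():
            annsets[report_id] = read_brat(
                text, ann_path.read_text(encoding="utf-8")
            )
    return reports, annsets


def write_corpus(
    corpus_dir: str | os.PathLike,
    reports: list[Report],
    annsets: dict[str, AnnotationSet] | None = None,
) -> None:
    corpus_dir = Path(corpus_dir)
    corpus_dir.mkdir(parents=True, exist_ok=True)
    for report in reports:
        (corpus_dir / f"{report.report_id}.txt").write_text(
            report.text, encoding="utf-8"
        )
        if annsets and report.report_id in annsets:
            (corpus_dir / f"{report.report_id}.ann").write_text(
                write_brat(annsets[report.report_id]), encoding="utf-8"
            )


def read_labels(path: str | os.PathLike) -> dict[str, GoldLabels]:
    df = pd.read_csv(path, sep="\t", dtype={"report_id": str}, comment="#")
    expected = {"report_id", "pe", "dvt", "incidentaloma"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"labels file missing columns: {sorted(missing)}")
    return {
        row.report_id: GoldLabels(
            row.report_id, int(row.pe), int(row.dvt), int(row.incidentaloma)
        )
        for row in df.itertuples(index=False)
    }


def write_labels(
    path: str | os.PathLike,
    labels: dict[str, GoldLabels] | list[GoldLabels],
    header_comment: str | None = None,
) -> None:
    if isinstance(labels, dict):
        labels = list(labels.values())
    df = pd.DataFrame(
        [(l.report_id, l.pe, l.dvt, l.incidentaloma) for l in labels],
        columns=["report_id", "pe", "dvt", "incidentaloma"],
    )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
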