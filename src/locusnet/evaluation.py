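"""Exon- and gene-level precision, recall and F1 against a reference.

An exon counts as a true positive iff its (sequence_id, start, end, strand)
match a reference CDS exon exactly; exons are deduplicated within each set
before counting.  A gene counts as a true positive iff its full ordered set
of CDS intervals and its strand match a reference gene exactly, so a single
wrong exon boundary fails the whole gene.  Recall = TP/(TP+FN),
Precision = TP/(TP+FP), F1 their harmonic mean, with 0/0 → 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .genes import GeneModel, Transcript
from .io_formats import AnnotationSet

__all__ = ["MetricsRow", "MetricsReport", "exon_level_metrics", "gene_level_metrics", "evaluate"]


@dataclass
class MetricsRow:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


@dataclass
class MetricsReport:
    exon: MetricsRow
    gene: MetricsRow

    def as_dict(self) -> Dict[str, Dict[str, float]]:
        return {"exon": self.exon.as_dict(), "gene": self.gene.as_dict()}


def _transcripts(x) -> List[Transcript]:
    if isinstance(x, AnnotationSet):
        return list(x.transcripts)
    return [g.to_transcript() if isinstance(g, GeneModel) else g for g in x]


def _exon_set(trs: Iterable[Transcript]) -> Set[Tuple[str, int, int, str]]:
    out = set()
    for tr in trs:
        for a, b in tr.cds:
            out.add((tr.sequence_id, a, b, tr.strand))
    return out


def _gene_set(trs: Iterable[Transcript]) -> Set[Tuple[str, str, Tuple[Tuple[int, int], ...]]]:
    return {(tr.sequence_id, tr.strand, tuple(tr.cds)) for tr in trs}


def _row(pred: set, ref: set) -> MetricsRow:
    tp = len(pred & ref)
    return MetricsRow(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def exon_level_metrics(pred, ref) -> MetricsRow:
    """Exact-coordinate exon matching (deduplicated within each set)."""
    return _row(_exon_set(_transcripts(pred)), _exon_set(_transcripts(ref)))


def gene_level_metrics(pred, ref) -> MetricsRow:
    """Whole-structure gene matching: every CDS interval must agree."""
    return _row(_gene_set(_transcripts(pred)), _gene_set(_transcripts(ref)))


def evaluate(pred, ref) -> MetricsReport:
    return MetricsReport(
        exon=exon_level_metrics(pred, ref), gene=gene_level_metrics(pred, ref)
    )
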