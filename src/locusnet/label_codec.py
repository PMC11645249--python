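"""Convert annotations to per-base 15-class labels and back.

``encode_reference_labels`` turns a one-transcript-per-gene annotation into a
label sequence on one strand; ``decode_state_path`` inverts it, mapping a
grammatical state path back to gene models in forward genome coordinates.
``validate_grammar`` checks a path against the 23-edge transition graph.

Conventions (shared with :mod:`locusnet.alphabet`): the frame index of a
coding state is the codon position (0-based) of the base carrying it; START
marks the first base of the start codon and STOP the last base of the stop
codon; the stop codon is part of the CDS (its bases are labeled E0, E1,
STOP); intron states carry the codon position of the next coding base.
Reverse-strand genes are encoded on the reverse-complement coordinate
system, where position p maps to genome position L-1-p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from . import alphabet as ab
from .alphabet import ALPHABET, StateAlphabet
from .genes import GeneModel, Transcript, transcript_to_gene, STOP_CODONS
from .io_formats import AnnotationSet, GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSequence",
    "GrammarViolation",
    "longest_cds_filter",
    "encode_reference_labels",
    "decode_state_path",
    "validate_grammar",
]

MIN_EXON_LENGTH = 3  # an exon must host whole border codons / both border states


@dataclass
class LabelSequence:
    """A per-base vector of state indices on one strand of one sequence."""

    labels: np.ndarray
    strand: str
    sequence_id: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= ab.N_STATES):
            raise ValueError("label values must lie in [0, 15)")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class GrammarViolation:
    position: int
    message: str


def longest_cds_filter(annotation: AnnotationSet) -> AnnotationSet:
    """Keep one transcript per gene: maximal summed CDS length, ties by
    lexicographically smallest transcript id."""
    chosen: List[Transcript] = []
    for gene_id, txs in sorted(annotation.by_gene().items()):
        best = min(txs, key=lambda t: (-t.cds_length, t.transcript_id))
        chosen.append(best)
    chosen.sort(key=lambda t: (t.sequence_id, t.start, t.gene_id))
    return AnnotationSet(transcripts=chosen, source_path=annotation.source_path)


def _strand_intervals(tr: Transcript, length: int) -> List[Tuple[int, int]]:
    """CDS intervals in the coordinate system of the transcript's strand,
    ordered 5'→3'."""
    if tr.strand == "+":
        return list(tr.cds)
    return [(length - b, length - a) for a, b in reversed(tr.cds)]


def _label_one_transcript(
    labels: np.ndarray, exons: List[Tuple[int, int]], seq: str, name: str
) -> bool:
    """Write labels for one transcript (strand coordinates); False if skipped."""
    total = sum(b - a for a, b in exons)
    if total % 3 != 0:
        logger.warning("%s: CDS length %d not divisible by 3; skipped", name, total)
        return False
    if total < 6:
        logger.warning("%s: CDS shorter than two codons; skipped", name)
        return False
    if any(b - a < MIN_EXON_LENGTH for a, b in exons):
        logger.warning("%s: exon shorter than %d bases; skipped", name, MIN_EXON_LENGTH)
        return False
    cds = "".join(seq[a:b] for a, b in exons)
    if not cds.startswith("ATG") or cds[-3:] not in STOP_CODONS:
        logger.warning("%s: missing canonical start or stop codon; skipped", name)
        return False
    for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
        intron = seq[b1:a2]
        if len(intron) < 4 or not (intron.startswith("GT") and intron.endswith("AG")):
            logger.warning("%s: non-canonical intron [%d,%d); skipped", name, b1, a2)
            return False

    frame = 0
    n_ex = len(exons)
    for j, (a, b) in enumerate(exons):
        for p in range(a, b):
            first, last = p == a, p == b - 1
            if j == 0 and first:
                state = ab.START
            elif j == n_ex - 1 and last and frame == 2:
                state = ab.STOP
            elif first and j > 0:
                state = ab.acceptor_state_for_frame(frame)
            elif last and j < n_ex - 1:
                state = ab.donor_state_for_frame(frame)
            else:
                state = ab.exon_state_for_frame(frame)
            labels[p] = state
            frame = (frame + 1) % 3
        if j < n_ex - 1:
            labels[b : exons[j + 1][0]] = ab.intron_state_for_frame(frame)
    return True


def encode_reference_labels(
    annotation: AnnotationSet, record: GenomeRecord, strand: str = "+"
) -> LabelSequence:
    """Per-base labels for one strand of one record.

    The annotation should already be reduced to one transcript per gene;
    transcripts that are frame-inconsistent or lack canonical signals are
    skipped with a warning, as is the later-starting one of two same-strand
    overlapping genes (one label per base).
    """
    strand = "+" if strand in ("+", "forward") else "-"
    L = record.length
    seq = record.sequence if strand == "+" else record.reverse_complement().sequence
    labels = np.full(L, ab.IR, dtype=np.int8)

    txs = annotation.on(record.sequence_id, strand)
    items = sorted(
        ((_strand_intervals(tr, L), tr) for tr in txs), key=lambda it: it[0][0][0] if it[0] else 0
    )
    covered_until = -1
    for exons, tr in items:
        span = (exons[0][0], exons[-1][1])
        if span[0] <= covered_until:
            logger.warning(
                "%s overlaps an earlier same-strand gene; dropped from labels", tr.transcript_id
            )
            continue
        if _label_one_transcript(labels, exons, seq, tr.transcript_id):
            covered_until = span[1] - 1
    return LabelSequence(labels=labels, strand=strand, sequence_id=record.sequence_id)


def validate_grammar(
    path: LabelSequence | np.ndarray, require_ir_boundaries: bool = True
) -> Tuple[bool, Optional[GrammarViolation]]:
    """True iff every adjacent label pair is one of the 23 allowed edges.

    With ``require_ir_boundaries`` (the default for whole-record paths) the
    path must also start and end in a non-coding state that closes no open
    gene, i.e. IR; tile-internal paths can disable it.
    """
    labels = path.labels if isinstance(path, LabelSequence) else np.asarray(path)
    if labels.size == 0:
        return True, None
    adj = ALPHABET.adjacency()
    if require_ir_boundaries:
        if labels[0] != ab.IR:
            return False, GrammarViolation(0, f"path starts in {ab.STATE_NAMES[labels[0]]}, not IR")
        if labels[-1] != ab.IR:
            return False, GrammarViolation(
                len(labels) - 1, f"path ends in {ab.STATE_NAMES[labels[-1]]}, not IR"
            )
    ok = adj[labels[:-1], labels[1:]]
    if ok.all():
        return True, None
    pos = int(np.argmin(ok)) + 1
    return False, GrammarViolation(
        pos,
        f"forbidden transition {ab.STATE_NAMES[labels[pos - 1]]} -> {ab.STATE_NAMES[labels[pos]]}",
    )


class StructuralError(ValueError):
    def __init__(self, position: int, message: str):
        super().__init__(f"position {position}: {message}")
        self.position = position


_EXON_OPEN = {ab.START, ab.ASS0, ab.ASS1, ab.ASS2}
_EXON_CLOSE = {ab.STOP, ab.DSS0, ab.DSS1, ab.DSS2}


def decode_state_path(
    path: LabelSequence,
    record: GenomeRecord,
    strict: bool = True,
    gene_id_prefix: str = "g",
) -> List[GeneModel]:
    """Invert :func:`encode_reference_labels`.

    Maximal runs between START and STOP become single-transcript genes;
    DSS/ASS pairs delimit introns.  Reverse-strand paths are mapped back to
    forward genome coordinates.  With ``strict`` the path must validate under
    the grammar; otherwise malformed gene fragments (e.g. truncated at a tile
    edge) are skipped with a warning.
    """
    labels = path.labels
    L = record.length
    if strict:
        ok, violation = validate_grammar(path, require_ir_boundaries=True)
        if not ok:
            raise StructuralError(violation.position, violation.message)

    genes: List[GeneModel] = []
    adj = ALPHABET.adjacency()
    exons: List[Tuple[int, int]] = []
    exon_start: Optional[int] = None
    in_gene = False
    broken = False
    prev = ab.IR
    for p, s in enumerate(labels):
        s = int(s)
        if in_gene and not adj[prev, s]:
            broken = True
        if s == ab.START:
            if in_gene:
                broken = True
            in_gene, broken, exons, exon_start = True, False, [], p
        elif in_gene:
            if s in _EXON_CLOSE and exon_start is not None:
                exons.append((exon_start, p + 1))
                exon_start = None
                if s == ab.STOP:
                    if broken:
                        logger.warning("skipping malformed gene fragment ending at %d", p)
                    else:
                        genes.append(_make_gene(exons, path, record, len(genes), gene_id_prefix))
                    in_gene = False
            elif s in _EXON_OPEN and exon_start is None:
                exon_start = p
            elif s == ab.IR:
                # gene never closed (possible only in lenient mode)
                logger.warning("skipping unterminated gene fragment at %d", p)
                in_gene = False
        prev = s
    if in_gene:
        logger.warning("skipping gene fragment running off the path end")
    genes.sort(key=lambda g: g.start)
    for i, g in enumerate(genes):
        g.gene_id = f"{gene_id_prefix}{i + 1}"
    return genes


def _make_gene(
    exons: List[Tuple[int, int]],
    path: LabelSequence,
    record: GenomeRecord,
    index: int,
    prefix: str,
) -> GeneModel:
    L = record.length
    if path.strand == "+":
        cds = list(exons)
    else:
        cds = [(L - b, L - a) for a, b in reversed(exons)]
    return GeneModel(
        gene_id=f"{prefix}{index + 1}",
        sequence_id=path.sequence_id,
        strand=path.strand,
        cds=cds,
    )


def labels_to_tsv(path: LabelSequence, out_path: str) -> None:
    """Dump a label sequence as a BED-like TSV of maximal runs (debugging)."""
    labels = path.labels
    with open(out_path, "w") as fh:
        fh.write("#sequence_id\tstart\tend\tstate\tstrand\n")
        if labels.size == 0:
            return
        breaks = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [labels.size]])
        for a, b in zip(starts, ends):
            fh.write(
                f"{path.sequence_id}\t{a}\t{b}\t{ab.STATE_NAMES[labels[a]]}\t{path.strand}\n"
            )
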