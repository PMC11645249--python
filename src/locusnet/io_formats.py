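"""Reading and writing the standard formats: softmasked FASTA and GTF/GFF3.

A genome arrives as (possibly softmasked) FASTA.  Lowercase letters mark
repeats; they are recorded in a per-base binary ``repeat_track`` and the
sequence itself is uppercased.  Letters outside {A, C, G, T, N} (IUPAC
ambiguity codes) are mapped to N with a logged count.  The numeric model
input stacks a 5-column one-hot encoding (N has its own column) with the
repeat track, giving a T×6 matrix per strand; the reverse-strand encoding is
the reverse complement with a reversed repeat track.

Annotations are read from GTF or GFF3 (CDS features, grouped per
transcript) through :mod:`gffutils` and written as GTF2.2 with
``gene``/``transcript``/``CDS`` rows.  Internally everything is 0-based
half-open; the 1-based inclusive convention exists only at the GTF border.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
from Bio import SeqIO

from .genes import GeneModel, Transcript, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "InputEncoding",
    "AnnotationSet",
    "read_genome",
    "encode_input",
    "read_annotation",
    "write_annotation",
    "FormatError",
]

_VALID = set("ACGTN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class FormatError(ValueError):
    """A malformed input file (FASTA or annotation)."""


@dataclass
class GenomeRecord:
    """One sequence with its softmask-derived repeat track."""

    sequence_id: str
    sequence: str
    repeat_track: np.ndarray  # uint8, 1 where the FASTA letter was lowercase

    def __post_init__(self) -> None:
        self.repeat_track = np.asarray(self.repeat_track, dtype=np.uint8)
        if len(self.sequence) != len(self.repeat_track):
            raise ValueError(
                f"{self.sequence_id}: sequence length {len(self.sequence)} != "
                f"repeat track length {len(self.repeat_track)}"
            )
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.sequence_id}: invalid letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(
            sequence_id=self.sequence_id,
            sequence=reverse_complement(self.sequence),
            repeat_track=self.repeat_track[::-1].copy(),
        )


@dataclass
class InputEncoding:
    """T×6 network input: 5 one-hot nucleotide columns + repeat flag."""

    matrix: np.ndarray
    strand: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 6:
            raise ValueError(f"encoding must be T x 6, got {self.matrix.shape}")


@dataclass
class AnnotationSet:
    """A bag of transcripts, as read from a GTF/GFF3 file."""

    transcripts: List[Transcript] = field(default_factory=list)
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_gene(self) -> Dict[str, List[Transcript]]:
        out: Dict[str, List[Transcript]] = {}
        for tr in self.transcripts:
            out.setdefault(tr.gene_id, []).append(tr)
        return out

    def on(self, sequence_id: str, strand: str | None = None) -> List[Transcript]:
        return [
            tr
            for tr in self.transcripts
            if tr.sequence_id == sequence_id and (strand is None or tr.strand == strand)
        ]


def normalize_sequence(raw: str, name: str = "?") -> tuple[str, np.ndarray]:
    """Uppercase, map non-ACGTN to N, derive the repeat track from case."""
    arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
    repeat = ((arr >= ord("a")) & (arr <= ord("z"))).astype(np.uint8)
    upper = np.where(repeat, arr - 32, arr).astype(np.uint8)
    seq = upper.tobytes().decode("ascii")
    bad = [c for c in set(seq) if c not in _VALID]
    if bad:
        n_mapped = sum(seq.count(c) for c in bad)
        logger.info("%s: mapped %d ambiguous letters %s to N", name, n_mapped, sorted(bad))
        table = str.maketrans({c: "N" for c in bad})
        seq = seq.translate(table)
    return seq, repeat


def read_genome(path: str | os.PathLike) -> List[GenomeRecord]:
    """Read a (softmasked, possibly multi-record) FASTA file."""
    records: List[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read FASTA {path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in parsed:
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        seq, repeat = normalize_sequence(raw, rec.id)
        records.append(GenomeRecord(rec.id, seq, repeat))
    return records


def encode_input(record: GenomeRecord, strand: str = "+") -> InputEncoding:
    """One-hot encode a record for one strand.

    Forward: row i one-hot of ``sequence[i]`` plus the repeat flag.
    Reverse: rows encode the reverse complement; the repeat track is
    reversed so row i still describes the same physical base.
    """
    if strand not in ("+", "-", "forward", "reverse"):
        raise ValueError(f"unknown strand {strand!r}")
    strand = "+" if strand in ("+", "forward") else "-"
    rec = record if strand == "+" else record.reverse_complement()
    idx = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for base, j in _BASE_INDEX.items():
        lut[ord(base)] = j
    cols = lut[idx]
    mat = np.zeros((rec.length, 6), dtype=np.float32)
    mat[np.arange(rec.length), cols] = 1.0
    mat[:, 5] = rec.repeat_track
    return InputEncoding(matrix=mat, strand=strand)


# ---------------------------------------------------------------------------
# annotation reading


def _read_features(path: str):
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various types on bad input
        raise FormatError(f"cannot parse annotation {path}: {exc}") from exc
    return db


def _first_attr(feature, *names) -> str | None:
    for name in names:
        vals = feature.attributes.get(name)
        if vals:
            return vals[0]
    return None


def read_annotation(path: str | os.PathLike) -> AnnotationSet:
    """Read CDS features from GTF or GFF3 into an :class:`AnnotationSet`.

    GTF carries ``gene_id``/``transcript_id`` attributes directly; GFF3 links
    CDS → mRNA via ``Parent`` and mRNA → gene via its own ``Parent``.  An
    empty file yields an empty set.
    """
    path = str(path)
    if os.path.getsize(path) == 0 or _only_comments(path):
        return AnnotationSet(transcripts=[], source_path=path)
    db = _read_features(path)
    tx_gene: Dict[str, str] = {}
    tx_meta: Dict[str, tuple[str, str]] = {}
    cds_by_tx: Dict[str, List[tuple[int, int]]] = {}

    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype in ("transcript", "mRNA"):
            tid = _first_attr(feat, "transcript_id", "ID")
            gid = _first_attr(feat, "gene_id", "Parent") or (tid or "") + "_gene"
            if tid:
                tx_gene[tid] = gid
        elif ftype == "CDS":
            tid = _first_attr(feat, "transcript_id", "Parent")
            if tid is None:
                raise FormatError(
                    f"{path}: CDS at {feat.seqid}:{feat.start}-{feat.end} has no "
                    "transcript_id/Parent"
                )
            gid = _first_attr(feat, "gene_id")
            if gid:
                tx_gene.setdefault(tid, gid)
            tx_meta.setdefault(tid, (feat.seqid, feat.strand))
            # GTF/GFF3 are 1-based inclusive; internal is 0-based half-open
            cds_by_tx.setdefault(tid, []).append((feat.start - 1, feat.end))

    transcripts: List[Transcript] = []
    for tid in sorted(cds_by_tx):
        seqid, strand = tx_meta[tid]
        gid = tx_gene.get(tid, f"{tid}_gene")
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=gid,
                sequence_id=seqid,
                strand=strand,
                cds=sorted(cds_by_tx[tid]),
            )
        )
    return AnnotationSet(transcripts=transcripts, source_path=path)


def _only_comments(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return False
    return True


# ---------------------------------------------------------------------------
# GTF writing


def write_annotation(
    genes: Sequence[GeneModel | Transcript],
    path: str | os.PathLike,
    source: str = "locusnet",
) -> None:
    """Write gene models as GTF2.2 (gene/transcript/CDS rows).

    Stop codons are included in the CDS intervals, which is recorded in the
    header.  Rows are ordered by (sequence_id, start, gene_id); overlapping
    same-strand genes are written with a warning.
    """
    items: List[Transcript] = []
    for g in genes:
        items.append(g.to_transcript() if isinstance(g, GeneModel) else g)
    items.sort(key=lambda t: (t.sequence_id, t.start, t.gene_id))

    _warn_same_strand_overlaps(items)

    lines: List[str] = [
        "##gtf (locusnet) coordinates 1-based inclusive; stop codon included in CDS"
    ]
    for tr in items:
        attrs = f'gene_id "{tr.gene_id}"; transcript_id "{tr.transcript_id}";'
        common = (tr.sequence_id, source)
        start1, end1 = tr.start + 1, tr.end
        lines.append(
            "\t".join(
                [*common, "gene", str(start1), str(end1), ".", tr.strand, ".", f'gene_id "{tr.gene_id}";']
            )
        )
        lines.append(
            "\t".join([*common, "transcript", str(start1), str(end1), ".", tr.strand, ".", attrs])
        )
        for (a, b), phase in zip(tr.cds, tr.phases()):
            lines.append(
                "\t".join(
                    [*common, "CDS", str(a + 1), str(b), ".", tr.strand, str(phase), attrs]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _warn_same_strand_overlaps(items: List[Transcript]) -> None:
    by_key: Dict[tuple[str, str], List[Transcript]] = {}
    for tr in items:
        by_key.setdefault((tr.sequence_id, tr.strand), []).append(tr)
    for (seqid, strand), trs in by_key.items():
        trs = sorted(trs, key=lambda t: t.start)
        for a, b in zip(trs, trs[1:]):
            if b.start < a.end:
                logger.warning(
                    "overlapping same-strand genes %s and %s on %s%s",
                    a.gene_id,
                    b.gene_id,
                    seqid,
                    strand,
                )
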