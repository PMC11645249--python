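"""Gene-structure containers shared by the I/O layer, codec and pipeline.

Coordinates are 0-based half-open on the forward genome strand throughout the
package; GTF conversion happens only in :mod:`locusnet.io_formats`.  A
transcript's CDS intervals are stored sorted by genomic start regardless of
strand; transcript (5'→3') order is derived from the strand when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_intervals(cds: Iterable[Interval]) -> List[Interval]:
    ivs = sorted((int(a), int(b)) for a, b in cds)
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted CDS interval [{a}, {b})")
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise ValueError(f"overlapping CDS intervals [{a1},{b1}) and [{a2},{b2})")
    return ivs


@dataclass
class Transcript:
    """One transcript's coding structure (CDS intervals only)."""

    transcript_id: str
    gene_id: str
    sequence_id: str
    strand: str  # "+" or "-"
    cds: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = _normalize_intervals(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def exons_in_transcript_order(self) -> List[Interval]:
        """CDS intervals ordered 5'→3' along the transcript."""
        return list(self.cds) if self.strand == "+" else list(reversed(self.cds))

    def phases(self) -> List[int]:
        """GTF frame value per exon, in genomic-start order.

        The frame of an exon is the number of bases until the next codon
        boundary at the exon's 5' end: ``(3 - cumulative_length % 3) % 3``.
        """
        out = {}
        cum = 0
        for iv in self.exons_in_transcript_order():
            out[iv] = (3 - cum % 3) % 3
            cum += iv[1] - iv[0]
        return [out[iv] for iv in self.cds]


@dataclass
class GeneModel:
    """A predicted or reference protein-coding gene (single transcript).

    Invariants (checked by :func:`validate_gene_model` against the sequence):
    total CDS length is a multiple of 3, the CDS starts with ATG and ends
    with a stop codon on its strand, and every intron starts GT and ends AG.
    """

    gene_id: str
    sequence_id: str
    strand: str
    cds: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = _normalize_intervals(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def to_transcript(self, transcript_id: str | None = None) -> Transcript:
        return Transcript(
            transcript_id=transcript_id or f"{self.gene_id}.t1",
            gene_id=self.gene_id,
            sequence_id=self.sequence_id,
            strand=self.strand,
            cds=list(self.cds),
        )

    def spliced_cds(self, sequence: str) -> str:
        """The spliced coding sequence, 5'→3' on the gene's strand."""
        parts = [sequence[a:b] for a, b in self.cds]
        joined = "".join(parts)
        return joined if self.strand == "+" else reverse_complement(joined)


def transcript_to_gene(tr: Transcript) -> GeneModel:
    return GeneModel(
        gene_id=tr.gene_id, sequence_id=tr.sequence_id, strand=tr.strand, cds=list(tr.cds)
    )


def validate_gene_model(gene: GeneModel, sequence: str) -> List[str]:
    """Check a gene against the sequence; return a list of violations.

    Checks: CDS length divisible by 3, ATG start, stop-codon end, GT..AG
    introns, and no internal in-frame stop codon in the spliced CDS.
    """
    problems: List[str] = []
    cds = gene.spliced_cds(sequence)
    if len(cds) % 3 != 0:
        problems.append(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) < 6:
        problems.append(f"CDS length {len(cds)} shorter than two codons")
        return problems
    if not cds.startswith("ATG"):
        problems.append(f"CDS does not start with ATG (got {cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        problems.append(f"CDS does not end with a stop codon (got {cds[-3:]})")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            problems.append(f"internal in-frame stop codon at CDS offset {i}")
            break
    # introns in genomic orientation of the gene's strand
    if gene.strand == "+":
        pairs = zip(gene.cds, gene.cds[1:])
        for (a1, b1), (a2, b2) in pairs:
            intron = sequence[b1:a2]
            if len(intron) < 4 or not (intron.startswith("GT") and intron.endswith("AG")):
                problems.append(f"intron [{b1},{a2}) is not canonical GT..AG")
    else:
        for (a1, b1), (a2, b2) in zip(gene.cds, gene.cds[1:]):
            intron = reverse_complement(sequence[b1:a2])
            if len(intron) < 4 or not (intron.startswith("GT") and intron.endswith("AG")):
                problems.append(f"intron [{b1},{a2}) is not canonical GT..AG (reverse)")
    return problems
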