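"""Synthetic genomes with planted, grammar-valid gene structures.

The generator emulates the composition of a mammalian genome at desk scale:
by default ~1% of bases are coding exon, ~16% intron and ~83% intergenic.
Genes are planted with canonical signals — an ATG start codon, a
TAA/TAG/TGA stop, GT..AG introns, frame-consistent multi-exon structure —
and contain no in-frame stop codon, spliced or not, because the coding
sequence is drawn codon-by-codon from a human-like codon usage table (which
also gives coding regions the periodicity and composition bias a classifier
can learn).  Region lengths are geometric around configurable means;
repeats are random softmasked intervals confined to non-coding sequence.

Labels are produced through :func:`locusnet.label_codec.encode_reference_labels`,
so every simulated label sequence is grammatical by construction and the
whole simulate → encode → decode loop is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import alphabet as ab
from .genes import Transcript, reverse_complement, STOP_CODONS
from .hmm import ClassProbMatrix
from .io_formats import AnnotationSet, GenomeRecord, encode_input
from .label_codec import LabelSequence, encode_reference_labels

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_class_probabilities",
    "make_training_set",
    "write_genome_fasta",
]

# human codon usage, frequencies per thousand (sense codons only)
_CODON_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "CAT": 10.9, "CAC": 15.1,
    "CAA": 12.3, "CAG": 34.2, "AAT": 17.0, "AAC": 19.1,
    "AAA": 24.4, "AAG": 31.9, "GAT": 21.8, "GAC": 25.1,
    "GAA": 29.0, "GAG": 39.6, "TGT": 10.6, "TGC": 12.6,
    "TGG": 13.2, "CGT": 4.5, "CGC": 10.4, "CGA": 6.2,
    "CGG": 11.4, "AGT": 12.1, "AGC": 19.5, "AGA": 12.2,
    "AGG": 12.0, "GGT": 10.8, "GGC": 22.2, "GGA": 16.5,
    "GGG": 16.5,
}
_SENSE_CODONS = list(_CODON_USAGE)
_SENSE_P = np.array([_CODON_USAGE[c] for c in _SENSE_CODONS])
_SENSE_P = _SENSE_P / _SENSE_P.sum()

MIN_INTRON_LENGTH = 30
MIN_EXON_LENGTH = 30  # spliceosomal minimum; vertebrate micro-exons below this are rare oddities


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic genome.

    Mean intron and intergenic lengths are derived from the composition
    targets (coding / intron fractions) unless given explicitly, so the
    default genome approaches the 1% / 16% / 83% coding / intron /
    intergenic composition of a mammalian genome.
    """

    genome_length: int = 1_000_000
    mean_exon_length: float = 150.0
    mean_exons_per_gene: float = 5.0
    coding_fraction: float = 0.01
    intron_fraction: float = 0.16
    mean_intron_length: Optional[float] = None
    mean_intergenic_length: Optional[float] = None
    gc_content: float = 0.41
    repeat_fraction: float = 0.10
    mean_repeat_length: float = 500.0
    flip_prob: float = 0.0
    uniform_weight: float = 0.0
    sequence_id: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coding_fraction < 1.0) or not (0.0 <= self.intron_fraction < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        if self.coding_fraction + self.intron_fraction >= 1.0:
            raise ValueError("coding + intron fraction must be < 1")
        if min(self.mean_exon_length, self.mean_exons_per_gene) <= 0:
            raise ValueError("means must be positive")
        if self.mean_exon_length <= MIN_EXON_LENGTH + 1:
            raise ValueError(
                f"mean exon length must exceed the {MIN_EXON_LENGTH}-base minimum"
            )

    @property
    def mean_lengths(self) -> Dict[str, float]:
        """Mean region lengths implied by the composition targets."""
        n_ex = self.mean_exons_per_gene
        coding_per_gene = n_ex * self.mean_exon_length
        genome_per_gene = coding_per_gene / self.coding_fraction
        if self.mean_intron_length is not None:
            intron = self.mean_intron_length
        elif n_ex > 1:
            intron = self.intron_fraction * genome_per_gene / (n_ex - 1)
        else:
            intron = float(MIN_INTRON_LENGTH)
        if self.mean_intergenic_length is not None:
            intergenic = self.mean_intergenic_length
        else:
            intron_total = intron * max(n_ex - 1, 0)
            intergenic = genome_per_gene - coding_per_gene - intron_total
        if intergenic <= 1 or intron < MIN_INTRON_LENGTH:
            raise ValueError(
                f"infeasible composition: intergenic mean {intergenic:.1f}, "
                f"intron mean {intron:.1f}"
            )
        return {
            "intergenic": float(intergenic),
            "intron": float(intron),
            "coding_exon": float(self.mean_exon_length),
            "coding_length": float(coding_per_gene),
        }


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _sample_gene(
    rng: np.random.Generator, ml: Dict[str, float], config: SimulationConfig
) -> Tuple[str, List[Tuple[int, int]]]:
    """One gene in transcript orientation: (sequence, exon intervals)."""
    n_ex = 1 + rng.poisson(max(config.mean_exons_per_gene - 1.0, 0.0))
    mean_ex = ml["coding_exon"]
    # shifted geometric: minimum MIN_EXON_LENGTH, mean mean_ex
    p_exit = 1.0 / (mean_ex - MIN_EXON_LENGTH + 1.0)
    exon_lens = [
        MIN_EXON_LENGTH + int(rng.geometric(p_exit)) - 1 for _ in range(n_ex)
    ]
    total = sum(exon_lens)
    pad = (3 - total % 3) % 3
    exon_lens[-1] += pad
    total += pad
    if total < 6:
        exon_lens[-1] += 6 - total
        total = 6
    n_codons = total // 3 - 2
    codons = [_SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=n_codons, p=_SENSE_P)]
    stop = STOP_CODONS[rng.choice(3, p=np.array([0.30, 0.24, 0.46]))]
    cds = "ATG" + "".join(codons) + stop
    assert len(cds) == total

    pieces: List[str] = []
    exons: List[Tuple[int, int]] = []
    pos = 0
    off = 0
    for j, elen in enumerate(exon_lens):
        pieces.append(cds[off : off + elen])
        exons.append((pos, pos + elen))
        pos += elen
        off += elen
        if j < n_ex - 1:
            ilen = max(MIN_INTRON_LENGTH, int(rng.geometric(1.0 / ml["intron"])))
            interior = _random_background(rng, ilen - 4, config.gc_content)
            pieces.append("GT" + interior + "AG")
            pos += ilen
    return "".join(pieces), exons


def simulate_genome(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[GenomeRecord, AnnotationSet, Dict[str, LabelSequence]]:
    """Sample one genome, its annotation, and per-strand label sequences."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ml = config.mean_lengths
    L = config.genome_length

    chunks: List[str] = []
    transcripts: List[Transcript] = []
    pos = 0
    gene_no = 0
    while True:
        gap = int(rng.geometric(1.0 / ml["intergenic"]))
        gene_seq, exons = _sample_gene(rng, ml, config)
        start = pos + gap
        if start + len(gene_seq) + 1 >= L:
            break
        chunks.append(_random_background(rng, gap, config.gc_content))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_no += 1
        if strand == "+":
            chunks.append(gene_seq)
            cds = [(start + a, start + b) for a, b in exons]
        else:
            chunks.append(reverse_complement(gene_seq))
            M = len(gene_seq)
            cds = sorted((start + M - b, start + M - a) for a, b in exons)
        transcripts.append(
            Transcript(
                transcript_id=f"g{gene_no}.t1",
                gene_id=f"g{gene_no}",
                sequence_id=config.sequence_id,
                strand=strand,
                cds=cds,
            )
        )
        pos = start + len(gene_seq)
    chunks.append(_random_background(rng, L - pos, config.gc_content))
    sequence = "".join(chunks)
    assert len(sequence) == L

    if not transcripts and config.genome_length > 10 * ml["coding_length"]:
        raise RuntimeError("no gene fitted the genome; configuration infeasible")

    repeat = _repeat_track(rng, L, transcripts, config)
    record = GenomeRecord(config.sequence_id, sequence, repeat)
    annotation = AnnotationSet(transcripts=transcripts, source_path="<simulated>")
    labels = {
        "+": encode_reference_labels(annotation, record, "+"),
        "-": encode_reference_labels(annotation, record, "-"),
    }
    return record, annotation, labels


def _repeat_track(
    rng: np.random.Generator,
    L: int,
    transcripts: List[Transcript],
    config: SimulationConfig,
) -> np.ndarray:
    track = np.zeros(L, dtype=np.uint8)
    if config.repeat_fraction <= 0:
        return track
    genic = np.zeros(L, dtype=bool)
    for tr in transcripts:
        genic[tr.start : tr.end] = True
    target = int(config.repeat_fraction * L)
    placed = 0
    for _ in range(20 * max(1, target // int(config.mean_repeat_length))):
        if placed >= target:
            break
        start = int(rng.integers(0, L))
        length = int(rng.geometric(1.0 / config.mean_repeat_length))
        end = min(L, start + length)
        if genic[start:end].any():
            continue
        placed += int(end - start) - int(track[start:end].sum())
        track[start:end] = 1
    return track


def simulate_class_probabilities(
    labels: LabelSequence,
    flip_prob: float = 0.0,
    uniform_weight: float = 0.0,
    seed: int = 0,
) -> ClassProbMatrix:
    """Stand-in network output: one-hot at the true labels, optionally
    corrupted by flipping a fraction of rows to a wrong class and blending
    every row with the uniform distribution."""
    rng = np.random.default_rng(seed)
    T = len(labels)
    lab = labels.labels.astype(int).copy()
    if flip_prob > 0:
        flip = rng.random(T) < flip_prob
        offsets = rng.integers(1, ab.N_STATES, size=T)
        lab[flip] = (lab[flip] + offsets[flip]) % ab.N_STATES
    P = np.zeros((T, ab.N_STATES))
    P[np.arange(T), lab] = 1.0
    if uniform_weight > 0:
        P = (1.0 - uniform_weight) * P + uniform_weight / ab.N_STATES
    return ClassProbMatrix(P)


def windows_from_genome(
    record: GenomeRecord,
    labels: Dict[str, LabelSequence],
    window_length: int,
    strands: str = "+-",
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Seamless non-overlapping (encoding, labels) windows for each strand.

    A trailing remainder shorter than one window is dropped.
    """
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for strand in strands:
        enc = encode_input(record, strand).matrix
        lab = labels[strand].labels
        for start in range(0, record.length - window_length + 1, window_length):
            out.append(
                (enc[start : start + window_length], lab[start : start + window_length])
            )
    return out


def make_training_set(
    config: SimulationConfig, window_length: int = 9999
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Simulate one genome and cut it into seamless training windows
    (both strands)."""
    record, _, labels = simulate_genome(config)
    return windows_from_genome(record, labels, window_length)


def write_genome_fasta(record: GenomeRecord, path: str, line_width: int = 60) -> None:
    """Write a record as softmasked FASTA (repeat bases lowercase)."""
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    low = np.where(record.repeat_track.astype(bool), seq + 32, seq)
    text = low.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{record.sequence_id}\n")
        for i in range(0, len(text), line_width):
            fh.write(text[i : i + line_width] + "\n")
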