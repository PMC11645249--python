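"""Whole-genome prediction: tiling, two-pass boundary resolution, two-strand
decoding, gene assembly, the spliced-stop post-filter and GTF emission.

Each strand of each record is cut into tiles (~500 kb by default) that are
decoded independently with the segment-parallel Viterbi.  Every tile is
decoded to complete gene structures (intergenic at both ends), so a gene
straddling a tile boundary is necessarily broken in the first pass; a
boundary where the network's class probabilities indicate gene context
triggers a second pass over the ~1 Mb window formed by the two
neighbouring tiles, and the central half of the re-predicted window
replaces the first-pass labels there.  Assembled
genes whose spliced CDS still contains an in-frame stop codon — possible
only when the stop is spliced across an intron, which the per-position
constraint mask cannot forbid — are removed by a post-filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import alphabet as ab
from .genes import GeneModel, validate_gene_model
from .hmm import (
    ConstraintMask,
    HMMParameters,
    emission_likelihoods,
    sequence_constraint_masks,
)
from .io_formats import AnnotationSet, GenomeRecord, encode_input, write_annotation
from .label_codec import LabelSequence, decode_state_path
from .viterbi import viterbi_parallel

logger = logging.getLogger(__name__)

__all__ = [
    "TilePlan",
    "plan_tiles",
    "resolve_boundaries",
    "assemble_genes",
    "filter_spliced_stops",
    "run_genome_prediction",
]

DEFAULT_TILE_LENGTH = 500_004
DEFAULT_SEGMENT_LENGTH = 50_000


@dataclass
class TilePlan:
    """Deterministic tiling of every strand of every record."""

    tiles: List[Tuple[str, int, int, str]]  # (sequence_id, start, end, strand)
    tile_length: int

    def on(self, sequence_id: str, strand: str) -> List[Tuple[str, int, int, str]]:
        return [t for t in self.tiles if t[0] == sequence_id and t[3] == strand]


def plan_tiles(
    records: Sequence[GenomeRecord], tile_length: int = DEFAULT_TILE_LENGTH
) -> TilePlan:
    """Tile both strands of each record; the last tile may be short.

    Coordinates are in the strand's own system (reverse-strand tiles index
    into the reverse complement), covering each strand exactly once.
    """
    if tile_length < 2:
        raise ValueError("tile length must be at least 2")
    tiles = []
    for rec in records:
        for strand in "+-":
            for start in range(0, rec.length, tile_length):
                tiles.append((rec.sequence_id, start, min(start + tile_length, rec.length), strand))
    return TilePlan(tiles=tiles, tile_length=tile_length)


def _decode_window(
    likelihoods: np.ndarray,
    params: HMMParameters,
    segment_length: int,
    left_end: bool,
    right_end: bool,
) -> np.ndarray:
    boundary = ("ir" if left_end else "free", "ir" if right_end else "free")
    path = viterbi_parallel(
        likelihoods, params, segment_length=min(segment_length, max(2, likelihoods.shape[0])),
        boundary=boundary,
    )
    return path.labels


def resolve_boundaries(
    tile_labels: List[np.ndarray],
    tile_bounds: List[Tuple[int, int]],
    repredict: Callable[[int, int, bool, bool], np.ndarray],
    total_length: int,
    genic_boundary: Optional[Sequence[bool]] = None,
) -> Tuple[np.ndarray, int]:
    """Stitch first-pass tile paths, re-deciding genic boundaries.

    A boundary "appears to be in a gene" when ``genic_boundary`` says so
    (the pipeline derives this from the network's class probabilities at
    the boundary, since first-pass tiles are decoded to complete genes and
    their paths are intergenic at every tile end by construction); without
    that information the stitched labels' flanks are used.  For each genic
    boundary the two neighbouring tiles are re-predicted as one window and
    the central half of that window replaces the stitched labels.  Returns
    the merged labels and the number of boundaries re-decided.  Boundaries
    are visited once (no cascading iteration).
    """
    merged = np.concatenate(tile_labels)
    n_second = 0
    for i in range(len(tile_labels) - 1):
        b = tile_bounds[i][1]
        if genic_boundary is not None:
            if not genic_boundary[i]:
                continue
        elif merged[b - 1] == ab.IR and merged[b] == ab.IR:
            continue
        wstart, wend = tile_bounds[i][0], tile_bounds[i + 1][1]
        relabeled = repredict(wstart, wend, wstart == 0, wend == total_length)
        # replace from the midpoint of each flanking tile — the central
        # half of the merged window when tiles are equal, and still centred
        # on the boundary when the last tile is short
        lo, hi = (wstart + b) // 2, (b + wend) // 2
        merged[lo:hi] = relabeled[lo - wstart : hi - wstart]
        n_second += 1
    return merged, n_second


def predict_strand_labels(
    record: GenomeRecord,
    strand: str,
    model,
    params: HMMParameters,
    tile_length: int = DEFAULT_TILE_LENGTH,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    second_pass: bool = True,
    network_chunk: Optional[int] = None,
) -> Tuple[LabelSequence, int]:
    """First-pass tiled decoding plus optional boundary second pass for one
    strand; labels are in the strand's coordinate system.

    ``network_chunk`` evaluates the network in strand-aligned chunks of
    that length instead of whole tiles (the HMM still decodes whole tiles).
    Small desk-scale models are best evaluated at the context length they
    were trained with; large models can take the whole tile.
    """
    from .nn.network import predict_class_probabilities

    enc = encode_input(record, strand).matrix
    seq = record.sequence if strand == "+" else record.reverse_complement().sequence
    masks = sequence_constraint_masks(seq).mask
    L = record.length
    eps = params.emission_smoothing

    def network_probs(start: int, end: int) -> np.ndarray:
        if network_chunk is None:
            return predict_class_probabilities(model, enc[start:end]).probabilities
        out = np.empty((end - start, ab.N_STATES))
        first = (start // network_chunk) * network_chunk
        for c in range(first, end, network_chunk):
            a, b = max(c, start), min(c + network_chunk, end)
            P = predict_class_probabilities(model, np.ascontiguousarray(enc[c:b]))
            out[a - start : b - start] = P.probabilities[a - c :]
        return out

    boundary_genic: Dict[int, bool] = {}

    def window_labels(start: int, end: int, left_end: bool, right_end: bool) -> np.ndarray:
        X = network_probs(start, end)
        # record whether the network sees gene context at the tile edges;
        # first-pass tiles are decoded to complete genes (IR at both ends),
        # so the trigger for the boundary second pass must come from the
        # class probabilities, not the decoded path
        boundary_genic[start] = bool(X[0].argmax() != ab.IR)
        boundary_genic[end - 1] = bool(X[-1].argmax() != ab.IR)
        lik = emission_likelihoods(X, masks[start:end], eps)
        # every window decodes to complete gene structures (IR at both
        # ends); a straddling gene is recovered by the second pass, whose
        # merged window contains it whole
        return _decode_window(lik, params, segment_length, True, True)

    bounds = [(s, min(s + tile_length, L)) for s in range(0, L, tile_length)]
    tile_labels = [window_labels(s, e, True, True) for s, e in bounds]
    if second_pass and len(tile_labels) > 1:
        genic = [
            boundary_genic[bounds[i][1] - 1] or boundary_genic[bounds[i + 1][0]]
            for i in range(len(bounds) - 1)
        ]
        merged, n_second = resolve_boundaries(
            tile_labels, bounds, window_labels, L, genic_boundary=genic
        )
    else:
        merged, n_second = np.concatenate(tile_labels), 0
    return LabelSequence(labels=merged, strand=strand, sequence_id=record.sequence_id), n_second


def assemble_genes(
    forward: LabelSequence, reverse: LabelSequence, record: GenomeRecord
) -> List[GeneModel]:
    """Decode both strand paths and merge to forward-coordinate gene models.

    Genes on opposite strands may overlap or nest; same-strand conflicts are
    impossible under the grammar.  Decoding is lenient: fragments truncated
    at stitching artefacts are dropped with a warning rather than failing
    the whole record.
    """
    genes = decode_state_path(forward, record, strict=False)
    genes += decode_state_path(reverse, record, strict=False)
    genes.sort(key=lambda g: (g.start, g.strand))
    for i, g in enumerate(genes):
        g.gene_id = f"{record.sequence_id}_g{i + 1}"
    return genes


def filter_spliced_stops(
    genes: Sequence[GeneModel], record: GenomeRecord
) -> Tuple[List[GeneModel], int]:
    """Drop genes whose spliced CDS contains an internal in-frame stop.

    The constraint mask prevents stops lying wholly inside an exon, so any
    survivor here has its stop split across an intron.
    """
    kept: List[GeneModel] = []
    removed = 0
    for g in genes:
        cds = g.spliced_cds(record.sequence)
        internal = any(
            cds[i : i + 3] in ("TAA", "TAG", "TGA") for i in range(0, len(cds) - 3, 3)
        )
        if internal:
            removed += 1
            logger.info("removed gene %s: spliced in-frame stop codon", g.gene_id)
        else:
            kept.append(g)
    return kept, removed


def run_genome_prediction(
    records: Sequence[GenomeRecord],
    model,
    params: HMMParameters,
    output_path: Optional[str] = None,
    tile_length: int = DEFAULT_TILE_LENGTH,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    second_pass: bool = True,
    network_chunk: Optional[int] = None,
    min_cds_length: int = 60,
) -> Tuple[List[GeneModel], Dict[str, int]]:
    """Predict genes on both strands of every record and (optionally) write GTF.

    Orchestrates encode → network → constraint masks → parallel Viterbi →
    boundary resolution → strand assembly → spliced-stop filter → GTF.
    Deterministic given the model weights.  Predictions whose CDS is
    shorter than ``min_cds_length`` (default 20 codons) are discarded as
    noise, the usual minimum-protein-length filter of gene finders.
    """
    all_genes: List[GeneModel] = []
    report = {
        "n_genes": 0,
        "n_second_pass": 0,
        "n_spliced_stop_removed": 0,
        "n_invalid_removed": 0,
        "n_short_removed": 0,
    }
    for rec in records:
        fwd, n2f = predict_strand_labels(
            rec, "+", model, params, tile_length, segment_length, second_pass,
            network_chunk,
        )
        rev, n2r = predict_strand_labels(
            rec, "-", model, params, tile_length, segment_length, second_pass,
            network_chunk,
        )
        genes = assemble_genes(fwd, rev, rec)
        n_before = len(genes)
        genes = [g for g in genes if g.cds_length >= min_cds_length]
        report["n_short_removed"] += n_before - len(genes)
        genes, removed = filter_spliced_stops(genes, rec)
        valid: List[GeneModel] = []
        for g in genes:
            problems = validate_gene_model(g, rec.sequence)
            if problems:
                # per-position masks cannot see across a splice: a 1-base
                # intron can fake both GT and AG locally; drop such genes
                logger.info("removed gene %s: %s", g.gene_id, problems)
                report["n_invalid_removed"] += 1
            else:
                valid.append(g)
        report["n_second_pass"] += n2f + n2r
        report["n_spliced_stop_removed"] += removed
        all_genes.extend(valid)
    report["n_genes"] = len(all_genes)
    if output_path is not None:
        write_annotation(all_genes, output_path)
    return all_genes, report
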