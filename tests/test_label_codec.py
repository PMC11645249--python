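"""The 15-class label codec: encoding, decoding, grammar validation."""

import numpy as np
import pytest

import locusnet.alphabet as ab
from locusnet.alphabet import ALPHABET
from locusnet.genes import Transcript
from locusnet.io_formats import AnnotationSet, GenomeRecord
from locusnet.label_codec import (
    LabelSequence,
    StructuralError,
    decode_state_path,
    encode_reference_labels,
    longest_cds_filter,
    validate_grammar,
)
from locusnet.simulate import SimulationConfig, simulate_genome

from oracles import adjacency_valid


def _record(seq):
    return GenomeRecord("chr", seq, np.zeros(len(seq)))


def _annot(*transcripts):
    return AnnotationSet(transcripts=list(transcripts))


class TestAlphabet:
    def test_state_counts(self):
        assert ALPHABET.n_states == 15
        assert len(ALPHABET.exon_class_indices) == 11
        assert len(ALPHABET.noncoding_indices) == 4
        assert len(ALPHABET.edges) == 23

    def test_partition(self):
        both = set(ALPHABET.exon_class_indices) | set(ALPHABET.noncoding_indices)
        assert both == set(range(15))


class TestLongestCdsFilter:
    def test_keeps_longest_isoform(self):
        a = Transcript("t1", "g", "chr", "+", [(0, 300)])
        b = Transcript("t2", "g", "chr", "+", [(0, 150), (200, 500)])  # 450
        out = longest_cds_filter(_annot(a, b))
        assert [t.transcript_id for t in out.transcripts] == ["t2"]

    def test_tie_breaks_to_smallest_id(self):
        a = Transcript("tB", "g", "chr", "+", [(0, 300)])
        b = Transcript("tA", "g", "chr", "+", [(400, 700)])
        out = longest_cds_filter(_annot(a, b))
        assert [t.transcript_id for t in out.transcripts] == ["tA"]

    def test_single_isoform_unchanged(self):
        a = Transcript("t1", "g", "chr", "+", [(0, 30)])
        assert longest_cds_filter(_annot(a)).transcripts == [a]


class TestEncodeLabels:
    def test_single_exon_gene_labels(self):
        #            0123456789...
        seq = "CC" + "ATGAAATAA" + "CC"
        tr = Transcript("t", "g", "chr", "+", [(2, 11)])
        labels = encode_reference_labels(_annot(tr), _record(seq), "+")
        expect = (
            [ab.IR, ab.IR]
            + [ab.START, ab.E1, ab.E2, ab.E0, ab.E1, ab.E2, ab.E0, ab.E1, ab.STOP]
            + [ab.IR, ab.IR]
        )
        assert labels.labels.tolist() == expect

    def test_two_exon_gene_with_intron_frame(self):
        # exon1 ATGA | intron GT..AG | exon2 AATAA
        intron = "GT" + "C" * 26 + "AG"
        seq = "C" + "ATGA" + intron + "AATAA" + "C"
        tr = Transcript("t", "g", "chr", "+", [(1, 5), (35, 40)])
        labels = encode_reference_labels(_annot(tr), _record(seq), "+")
        got = labels.labels
        assert got[1:5].tolist() == [ab.START, ab.E1, ab.E2, ab.DSS0]
        assert set(got[5:35].tolist()) == {ab.I1}
        assert got[35:40].tolist() == [ab.ASS1, ab.E2, ab.E0, ab.E1, ab.STOP]

    def test_no_genes_all_ir(self):
        labels = encode_reference_labels(_annot(), _record("ACGT" * 10), "+")
        assert (labels.labels == ab.IR).all()

    def test_frame_inconsistent_transcript_skipped(self):
        seq = "C" + "ATGAAAA" + "C" * 5  # CDS length 7, not divisible by 3
        tr = Transcript("t", "g", "chr", "+", [(1, 8)])
        labels = encode_reference_labels(_annot(tr), _record(seq), "+")
        assert (labels.labels == ab.IR).all()

    def test_reverse_strand_round_trips(self, small_sim):
        _, record, annotation, labels = small_sim
        genes = decode_state_path(labels["-"], record)
        minus = [t for t in annotation.transcripts if t.strand == "-"]
        assert sorted(tuple(g.cds) for g in genes) == sorted(tuple(t.cds) for t in minus)


class TestValidateGrammar:
    def test_encoded_labels_are_grammatical(self, small_sim):
        _, record, annotation, labels = small_sim
        for strand in "+-":
            ok, violation = validate_grammar(labels[strand])
            assert ok, violation

    def test_forbidden_adjacency_reported(self):
        ok, violation = validate_grammar(np.array([ab.IR, ab.E0, ab.IR]), False)
        assert not ok
        assert violation.position == 1

    def test_matches_bruteforce_edge_checker(self, rng):
        for _ in range(300):
            labels = rng.integers(0, 15, size=50)
            ok, _ = validate_grammar(labels, require_ir_boundaries=False)
            assert ok == adjacency_valid(labels)

    def test_ir_boundary_requirement(self):
        ok, violation = validate_grammar(np.array([ab.I0, ab.I0]))
        assert not ok and violation.position == 0


class TestDecode:
    def test_decode_inverts_encode(self, small_sim):
        _, record, annotation, labels = small_sim
        got = []
        for strand in "+-":
            got += decode_state_path(labels[strand], record)
        ref = {(tuple(t.cds), t.strand) for t in annotation.transcripts}
        assert {(tuple(g.cds), g.strand) for g in got} == ref

    def test_all_ir_gives_no_genes(self):
        rec = _record("ACGT" * 5)
        path = LabelSequence(np.full(20, ab.IR), "+", "chr")
        assert decode_state_path(path, rec) == []

    def test_ungrammatical_strict_raises(self):
        rec = _record("ACGT" * 5)
        bad = np.full(20, ab.IR)
        bad[10] = ab.E0
        with pytest.raises(StructuralError):
            decode_state_path(LabelSequence(bad, "+", "chr"), rec, strict=True)

    def test_frame_periodicity_within_cds(self, small_sim):
        """Codon-position labels advance 0,1,2 cyclically along each CDS."""
        _, record, annotation, labels = small_sim
        lab = labels["+"].labels
        coding = [
            (i, ALPHABET.codon_position(int(s)))
            for i, s in enumerate(lab)
            if int(s) in ALPHABET.exon_class_indices
        ]
        # within each gene, consecutive coding bases advance frame mod 3
        for (i1, f1), (i2, f2) in zip(coding, coding[1:]):
            if i2 - i1 == 1:  # adjacent coding bases
                assert f2 == (f1 + 1) % 3


class TestEncodeDecodeFuzz:
    def test_roundtrip_many_simulated_annotations(self):
        n_checked = 0
        for seed in range(40):
            cfg = SimulationConfig(
                genome_length=20_000,
                mean_exon_length=60,
                mean_exons_per_gene=3,
                coding_fraction=0.06,
                intron_fraction=0.2,
                seed=seed,
            )
            record, annotation, labels = simulate_genome(cfg)
            got = []
            for strand in "+-":
                got += decode_state_path(labels[strand], record)
            ref = {(tuple(t.cds), t.strand) for t in annotation.transcripts}
            assert {(tuple(g.cds), g.strand) for g in got} == ref
            n_checked += len(annotation)
        assert n_checked > 50
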