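"""The synthetic genome generator and its guarantees."""

import numpy as np
import pytest

import locusnet.alphabet as ab
from locusnet.genes import validate_gene_model, transcript_to_gene
from locusnet.label_codec import validate_grammar
from locusnet.pipeline import filter_spliced_stops
from locusnet.simulate import (
    SimulationConfig,
    make_training_set,
    simulate_class_probabilities,
    simulate_genome,
    windows_from_genome,
    write_genome_fasta,
)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(genome_length=30_000, coding_fraction=0.05,
                               intron_fraction=0.2, seed=11)
        r1, a1, l1 = simulate_genome(cfg)
        r2, a2, l2 = simulate_genome(cfg)
        assert r1.sequence == r2.sequence
        assert [t.cds for t in a1.transcripts] == [t.cds for t in a2.transcripts]
        assert np.array_equal(l1["+"].labels, l2["+"].labels)

    def test_every_gene_valid(self, small_sim):
        _, record, annotation, _ = small_sim
        for tr in annotation.transcripts:
            problems = validate_gene_model(transcript_to_gene(tr), record.sequence)
            assert problems == [], (tr.transcript_id, problems)

    def test_labels_grammatical_both_strands(self, small_sim):
        _, _, _, labels = small_sim
        for strand in "+-":
            ok, violation = validate_grammar(labels[strand])
            assert ok, violation

    def test_no_spliced_stops_by_construction(self, small_sim):
        _, record, annotation, _ = small_sim
        genes = [transcript_to_gene(t) for t in annotation.transcripts]
        kept, removed = filter_spliced_stops(genes, record)
        assert removed == 0
        assert len(kept) == len(genes)

    def test_composition_approaches_mammalian_defaults(self):
        """Coding/intron/intergenic fractions approach 1%/16%/83% on a
        large genome under the default configuration (±30% relative)."""
        cfg = SimulationConfig(genome_length=5_000_000, seed=5)
        record, annotation, labels = simulate_genome(cfg)
        lab = labels["+"].labels
        minus = labels["-"].labels[::-1]
        # a base is coding/intronic if either strand's track says so
        coding_idx = np.array(ab.ALPHABET.exon_class_indices)
        coding = np.isin(lab, coding_idx) | np.isin(minus, coding_idx)
        intron = np.isin(lab, [ab.I0, ab.I1, ab.I2]) | np.isin(minus, [ab.I0, ab.I1, ab.I2])
        c = coding.mean()
        i = intron.mean()
        assert 0.007 <= c <= 0.013
        assert 0.112 <= i <= 0.208
        assert 1 - c - i >= 0.58  # intergenic dominates

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(coding_fraction=0.9, intron_fraction=0.05).mean_lengths

    def test_repeat_track_avoids_genes(self, small_sim):
        _, record, annotation, _ = small_sim
        for tr in annotation.transcripts:
            assert record.repeat_track[tr.start : tr.end].sum() == 0


class TestClassProbabilities:
    def test_zero_noise_exact_onehot(self, small_sim):
        _, _, _, labels = small_sim
        X = simulate_class_probabilities(labels["+"])
        lab = labels["+"].labels
        assert (X.probabilities.argmax(axis=1) == lab).all()
        assert np.allclose(X.probabilities.max(axis=1), 1.0)

    def test_full_uniform_limit(self, small_sim):
        _, _, _, labels = small_sim
        X = simulate_class_probabilities(labels["+"], flip_prob=1.0, uniform_weight=1.0)
        assert np.allclose(X.probabilities, 1 / 15)

    def test_rows_stay_on_simplex(self, small_sim):
        _, _, _, labels = small_sim
        X = simulate_class_probabilities(labels["+"], flip_prob=0.2, uniform_weight=0.3, seed=4)
        assert np.allclose(X.probabilities.sum(axis=1), 1.0)
        assert (X.probabilities >= 0).all()

    def test_flip_changes_requested_fraction(self, small_sim):
        _, _, _, labels = small_sim
        X = simulate_class_probabilities(labels["+"], flip_prob=0.1, seed=9)
        frac = (X.probabilities.argmax(axis=1) != labels["+"].labels).mean()
        assert 0.05 < frac < 0.15


class TestTrainingWindows:
    def test_window_count_and_concatenation(self, small_sim):
        _, record, _, labels = small_sim
        wins = windows_from_genome(record, labels, 2997, strands="+")
        assert len(wins) == record.length // 2997
        joined = np.concatenate([w[1] for w in wins])
        assert np.array_equal(joined, labels["+"].labels[: len(joined)])

    def test_both_strands_cover_genome(self, small_sim):
        _, record, _, labels = small_sim
        wins = windows_from_genome(record, labels, 2997)
        assert len(wins) == 2 * (record.length // 2997)

    def test_class_frequencies_preserved(self, small_sim):
        _, record, _, labels = small_sim
        wins = windows_from_genome(record, labels, 2997, strands="+")
        pooled = np.concatenate([w[1] for w in wins])
        n = len(pooled)
        genome_freq = np.bincount(labels["+"].labels[:n], minlength=15) / n
        window_freq = np.bincount(pooled, minlength=15) / n
        assert np.allclose(genome_freq, window_freq)

    def test_make_training_set_from_config(self):
        cfg = SimulationConfig(genome_length=29_970, coding_fraction=0.05,
                               intron_fraction=0.2, seed=2)
        wins = make_training_set(cfg, window_length=2997)
        assert len(wins) == 20  # 10 per strand
        assert wins[0][0].shape == (2997, 6)


class TestFastaOutput:
    def test_softmask_roundtrip(self, tmp_path, small_sim):
        from locusnet.io_formats import read_genome

        _, record, _, _ = small_sim
        path = str(tmp_path / "sim.fa")
        write_genome_fasta(record, path)
        back = read_genome(path)[0]
        assert back.sequence == record.sequence
        assert np.array_equal(back.repeat_track, record.repeat_track)
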