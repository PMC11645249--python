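"""Sequential Viterbi, segment-parallel Viterbi and max-plus summaries."""

import numpy as np
import pytest

import locusnet.alphabet as ab
from locusnet.hmm import DecodingError, build_transitions
from locusnet.label_codec import validate_grammar
from locusnet.viterbi import (
    SegmentSummary,
    identity_summary,
    maxplus_combine,
    segment_summaries,
    viterbi_parallel,
    viterbi_sequential,
)

from oracles import enumerate_paths, path_score, random_masked_emissions


class TestSequential:
    def test_t1_argmax_of_init_times_emission(self, toy_params):
        E = np.zeros((1, 15))
        E[0, ab.IR] = 0.4
        path = viterbi_sequential(E, toy_params)
        assert path.labels.tolist() == [ab.IR]

    def test_score_matches_bruteforce(self, rng, toy_params):
        A = toy_params.transition_matrix
        init = toy_params.initial_distribution
        final = np.zeros(15, bool)
        final[ab.IR] = True
        for _ in range(60):
            T = int(rng.integers(2, 8))
            E = random_masked_emissions(rng, T)
            best_ref, path_ref, _, _ = enumerate_paths(E, A, init, final)
            path = viterbi_sequential(E, toy_params)
            score = path_score(path.labels, E, A, init)
            assert score == pytest.approx(best_ref, abs=1e-9)
            assert path.labels.tolist() == path_ref

    def test_clean_onehot_recovers_planted_path(self, small_sim):
        from locusnet.simulate import simulate_class_probabilities

        cfg, record, annotation, labels = small_sim
        params = build_transitions(cfg.mean_lengths)
        X = simulate_class_probabilities(labels["-"])
        path = viterbi_sequential(X.probabilities, params, strand="-")
        assert np.array_equal(path.labels, labels["-"].labels)

    def test_no_valid_path_raises(self, toy_params):
        E = np.ones((4, 15))
        E[2] = 0.0
        with pytest.raises(DecodingError):
            viterbi_sequential(E, toy_params)


class TestParallel:
    @pytest.mark.parametrize("segment_length", [7, 50, 128, 400])
    def test_identical_to_sequential(self, rng, toy_params, segment_length):
        for _ in range(25):
            T = int(rng.integers(10, 300))
            E = random_masked_emissions(rng, T)
            seq_path = viterbi_sequential(E, toy_params)
            par_path = viterbi_parallel(E, toy_params, segment_length)
            assert np.array_equal(par_path.labels, seq_path.labels)

    def test_single_segment_trivially_equal(self, rng, toy_params):
        E = random_masked_emissions(rng, 40)
        a = viterbi_sequential(E, toy_params)
        b = viterbi_parallel(E, toy_params, segment_length=1000)
        assert np.array_equal(a.labels, b.labels)

    def test_paths_are_grammatical(self, rng, toy_params):
        for _ in range(20):
            E = random_masked_emissions(rng, int(rng.integers(20, 200)))
            path = viterbi_parallel(E, toy_params, 31)
            ok, violation = validate_grammar(path)
            assert ok, violation

    def test_path_score_self_consistency(self, rng, toy_params):
        """Backtracked path rescored by summing emissions + transitions."""
        E = random_masked_emissions(rng, 200)
        seq = viterbi_sequential(E, toy_params)
        par = viterbi_parallel(E, toy_params, 61)
        s1 = path_score(seq.labels, E, toy_params.transition_matrix,
                        toy_params.initial_distribution)
        s2 = path_score(par.labels, E, toy_params.transition_matrix,
                        toy_params.initial_distribution)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_free_boundary_mode(self, rng, toy_params):
        E = random_masked_emissions(rng, 80)
        a = viterbi_sequential(E, toy_params, boundary="free")
        b = viterbi_parallel(E, toy_params, 17, boundary="free")
        assert np.array_equal(a.labels, b.labels)


class TestMaxPlusCombine:
    def test_identity_is_neutral(self, rng, toy_params):
        E = random_masked_emissions(rng, 12)
        s = segment_summaries(E, toy_params, 12)[0]
        e = identity_summary()
        left = maxplus_combine(s, e)
        assert np.array_equal(left.scores, s.scores)

    def test_associativity(self, rng):
        mats = [SegmentSummary(rng.random((15, 15))) for _ in range(3)]
        a, b, c = mats
        lhs = maxplus_combine(maxplus_combine(a, b), c)
        rhs = maxplus_combine(a, maxplus_combine(b, c))
        assert np.allclose(lhs.scores, rhs.scores)

    def test_neg_inf_propagates(self, rng):
        dead = SegmentSummary(np.full((15, 15), -np.inf))
        b = SegmentSummary(rng.random((15, 15)))
        out = maxplus_combine(dead, b)
        assert np.isneginf(out.scores).all()

    def test_combine_equals_naive_enumeration(self, rng, toy_params):
        """Two short adjacent segments: combined summary equals brute-force
        max over entry/exit-conditioned paths of the concatenation."""
        T1, T2 = 4, 3
        E = random_masked_emissions(rng, T1 + T2)
        s1, s2 = segment_summaries(E, toy_params, T1)
        combined = maxplus_combine(s1, s2)
        full = segment_summaries(E, toy_params, T1 + T2)[0]
        assert np.allclose(
            np.where(np.isneginf(combined.scores), -1e30, combined.scores),
            np.where(np.isneginf(full.scores), -1e30, full.scores),
        )


class TestFuzzEquivalence:
    def test_thousand_instances(self, rng, toy_params):
        """The central correctness property: parallel == sequential paths
        over a large fuzz of lengths, masks and segment lengths."""
        segment_lengths = [7, 50, 128, 1000]
        n = 0
        for trial in range(250):
            T = int(rng.integers(5, 300))
            E = random_masked_emissions(rng, T)
            seq = viterbi_sequential(E, toy_params)
            for seg in segment_lengths:
                par = viterbi_parallel(E, toy_params, seg)
                assert np.array_equal(par.labels, seq.labels), (trial, seg)
                n += 1
        assert n == 1000
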