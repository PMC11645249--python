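"""HMM construction, constraint masks, emissions and forward-backward."""

import numpy as np
import pytest

import locusnet.alphabet as ab
from locusnet.alphabet import ALPHABET, EDGES
from locusnet.hmm import (
    ClassProbMatrix,
    DecodingError,
    HMMParameters,
    build_transitions,
    emission_likelihoods,
    forward_backward,
    forward_log_likelihood,
    sequence_constraint_masks,
)
from locusnet._kernels import sample_state_durations

from oracles import enumerate_paths, random_masked_emissions


class TestBuildTransitions:
    def test_edge_support_and_parameter_count(self, toy_params):
        A = toy_params.transition_matrix
        assert toy_params.n_edges == 23
        assert toy_params.n_free_parameters == 24
        adj = ALPHABET.adjacency()
        assert (A[~adj] == 0).all()
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_geometric_mean_identity(self):
        p = build_transitions({"intergenic": 1000, "intron": 200, "coding_exon": 50})
        A = p.transition_matrix
        assert A[ab.IR, ab.IR] == pytest.approx(0.999)
        assert A[ab.IR, ab.START] == pytest.approx(0.001)
        assert A[ab.I0, ab.I0] == pytest.approx(1 - 1 / 200)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            build_transitions({"intergenic": 0, "intron": 40, "coding_exon": 30})

    def test_duration_sampling_matches_means(self):
        """Monte-Carlo run lengths of IR and intron states reproduce the
        configured geometric means within 2%."""
        means = {"intergenic": 1000.0, "intron": 300.0, "coding_exon": 100.0}
        p = build_transitions(means)
        for state, expect in [(ab.IR, 1000.0), (ab.I1, 300.0)]:
            durations = sample_state_durations(p.transition_matrix, state, 100_000, 42)
            assert abs(durations.mean() / expect - 1.0) < 0.02

    def test_json_roundtrip(self, toy_params, tmp_path):
        path = str(tmp_path / "hmm.json")
        toy_params.to_json(path)
        back = HMMParameters.from_json(path)
        assert np.array_equal(back.transition_matrix, toy_params.transition_matrix)
        assert back.emission_smoothing == toy_params.emission_smoothing


class TestConstraintMasks:
    def test_start_only_at_atg(self):
        mask = sequence_constraint_masks("CATGC").mask
        assert mask[:, ab.START].tolist() == [0, 1, 0, 0, 0]

    def test_donor_requires_gt_after(self):
        mask = sequence_constraint_masks("AAGTA").mask
        assert mask[:, ab.DSS0].tolist() == [0, 1, 0, 0, 0]

    def test_acceptor_requires_ag_before(self):
        mask = sequence_constraint_masks("AAGTA").mask
        # AG at positions 1..2 -> acceptor allowed at 3
        assert mask[:, ab.ASS1].tolist() == [0, 0, 0, 1, 0]

    def test_stop_and_e2_exclusion(self):
        mask = sequence_constraint_masks("CTAAC").mask
        assert mask[:, ab.STOP].tolist() == [0, 0, 0, 1, 0]
        assert mask[3, ab.E2] == 0 and mask[3, ab.DSS2] == 0
        assert mask[2, ab.E2] == 1

    def test_n_disables_signals_not_noncoding(self):
        mask = sequence_constraint_masks("NNNNN").mask
        for s in (ab.START, ab.STOP, ab.ASS0, ab.DSS2):
            assert (mask[:, s] == 0).all()
        for s in ALPHABET.noncoding_indices:
            assert (mask[:, s] == 1).all()

    def test_noncoding_never_masked_random(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=400))
        mask = sequence_constraint_masks(seq).mask
        assert (mask[:, list(ALPHABET.noncoding_indices)] == 1).all()


class TestEmissions:
    def test_zero_smoothing_is_identity(self, rng):
        X = rng.dirichlet(np.ones(15), size=20)
        lik = emission_likelihoods(ClassProbMatrix(X), None, 0.0)
        assert np.allclose(lik, X)

    def test_masked_entries_exactly_zero(self, rng):
        X = rng.dirichlet(np.ones(15), size=20)
        mask = (rng.random((20, 15)) < 0.5).astype(np.uint8)
        lik = emission_likelihoods(X, mask, 0.3)
        assert (lik[mask == 0] == 0).all()
        assert np.allclose(lik[mask == 1], (0.7 * X + 0.3 / 15)[mask == 1])

    def test_invalid_epsilon(self, rng):
        with pytest.raises(ValueError):
            emission_likelihoods(np.ones((3, 15)) / 15, None, 1.0)


class TestForwardBackward:
    def test_t1_posterior_is_normalised_emission(self, toy_params):
        E = np.zeros((1, 15))
        E[0, ab.IR] = 0.7
        post = forward_backward(E, toy_params).probabilities
        assert post[0, ab.IR] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng, toy_params):
        """Posteriors and total likelihood equal brute-force path sums on
        short instances with random masks."""
        A = toy_params.transition_matrix
        init = toy_params.initial_distribution
        final = np.zeros(15, bool)
        final[ab.IR] = True
        for _ in range(60):
            T = int(rng.integers(2, 8))
            E = random_masked_emissions(rng, T)
            _, _, post_ref, ll_ref = enumerate_paths(E, A, init, final)
            post = forward_backward(E, toy_params).probabilities
            assert np.abs(post - post_ref).max() < 1e-9
            assert forward_log_likelihood(E, toy_params) == pytest.approx(ll_ref, abs=1e-9)

    def test_rows_sum_to_one_and_respect_mask(self, rng, toy_params):
        T = 60
        E = random_masked_emissions(rng, T)
        post = forward_backward(E, toy_params).probabilities
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-6)
        assert (post[E == 0.0] == 0).all()

    def test_scaling_invariance_of_log_likelihood(self, rng, toy_params):
        """Multiplying position t's emissions by c shifts log L by log c."""
        E = random_masked_emissions(rng, 30)
        base = forward_log_likelihood(E, toy_params)
        scales = rng.uniform(0.5, 2.0, size=30)
        scaled = E * scales[:, None]
        assert forward_log_likelihood(scaled, toy_params) == pytest.approx(
            base + np.log(scales).sum(), abs=1e-9
        )

    def test_clean_onehot_recovers_planted_labels(self, small_sim, toy_params):
        from locusnet.simulate import simulate_class_probabilities

        cfg, record, annotation, labels = small_sim
        X = simulate_class_probabilities(labels["+"])
        params = build_transitions(cfg.mean_lengths)
        post = forward_backward(X.probabilities, params).probabilities
        assert (post.argmax(axis=1) == labels["+"].labels).all()

    def test_overmasking_raises_with_position(self, toy_params):
        E = np.ones((5, 15))
        E[3, :] = 0.0
        with pytest.raises(DecodingError) as err:
            forward_backward(E, toy_params)
        assert err.value.position == 3
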