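"""Forbidden-transition-aware generator: matrices, emission, amplitudes."""

import numpy as np
import pytest

from ordpat import (
    InvalidSequenceError,
    TRIPLE_TARGET_ORDER,
    build_matrix_from_triple,
    emit_state_sequence,
    generate_dataset,
    generate_series,
    ordinal_sequence,
    relative_frequencies,
    stationary_distribution,
    synthesize_amplitudes,
)
from ordpat.hmm import ReducibleChainWarning, validate_matrix

UNBIASED = (1 / 3, 1 / 3, 1 / 3)

# amplitude negation swaps motif q0<->q4, q1<->q3, q2<->q5
MIRROR = (4, 3, 5, 1, 0, 2)


class TestBuildMatrix:
    def test_triple_assignment_convention(self):
        A = build_matrix_from_triple((0.1, 0.2, 0.7))
        # ascending-overlap states list successors (q0, q1, q5)
        assert A[0, 0] == 0.1 and A[0, 1] == 0.2 and A[0, 5] == 0.7
        assert A[2, 0] == 0.1 and A[2, 1] == 0.2 and A[2, 5] == 0.7
        # descending-overlap states list successors (q3, q4, q2)
        assert A[1, 3] == 0.1 and A[1, 4] == 0.2 and A[1, 2] == 0.7
        assert A[4, 3] == 0.1 and A[4, 4] == 0.2 and A[4, 2] == 0.7

    def test_forbidden_entries_zero_rows_stochastic(self):
        A = build_matrix_from_triple((0.3, 0.3, 0.4))
        validate_matrix(A)
        assert np.count_nonzero(A) == 18
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_unbiased_matrix_doubly_stochastic(self):
        A = build_matrix_from_triple(UNBIASED)
        assert np.allclose(A.sum(axis=0), 1.0)
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_mirror_equivariance(self):
        # negating amplitudes maps the chain of (a1,a2,a3) onto that of (a2,a1,a3)
        A = build_matrix_from_triple((0.5, 0.2, 0.3))
        B = build_matrix_from_triple((0.2, 0.5, 0.3))
        perm = np.array(MIRROR)
        assert np.allclose(A[np.ix_(perm, perm)], B)

    def test_deterministic_triple_self_loop(self):
        A = build_matrix_from_triple((1, 0, 0))
        assert A[0, 0] == 1.0

    def test_invalid_triple_rejected(self):
        with pytest.raises(ValueError):
            build_matrix_from_triple((0.5, 0.5, 0.5))


class TestStationaryDistribution:
    def test_unbiased_chain_uniform(self):
        pi = stationary_distribution(build_matrix_from_triple(UNBIASED))
        assert np.allclose(pi, 1 / 6, atol=1e-10)

    def test_deterministic_chain_point_mass(self):
        with pytest.warns(ReducibleChainWarning):
            pi = stationary_distribution(build_matrix_from_triple((1, 0, 0)))
        assert pi[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("triple", [(0.1, 0.2, 0.7), (0.3, 0.3, 0.4), (0.05, 0.9, 0.05)])
    def test_residual_below_tolerance(self, triple):
        A = build_matrix_from_triple(triple)
        pi = stationary_distribution(A)
        assert np.linalg.norm(pi @ A - pi) < 1e-8
        assert pi.sum() == pytest.approx(1.0)

    def test_compensated_pair_laws_are_permutations(self):
        # the central phenomenon: mirrored triples give histograms with the
        # same bin amplitudes at different motifs, hence identical entropy
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ReducibleChainWarning)
            pa = stationary_distribution(build_matrix_from_triple((0.5, 0.0, 0.5)))
            pb = stationary_distribution(build_matrix_from_triple((0.0, 0.5, 0.5)))
        assert np.allclose(np.sort(pa), np.sort(pb), atol=1e-10)
        assert not np.allclose(pa, pb)


class TestEmitStateSequence:
    def test_single_state(self):
        A = build_matrix_from_triple(UNBIASED)
        s = emit_state_sequence(A, 1, np.random.default_rng(0))
        assert s.shape == (1,) and 0 <= s[0] < 6

    def test_deterministic_chain_stays_at_q0(self):
        A = build_matrix_from_triple((1, 0, 0))
        s = emit_state_sequence(A, 50, np.random.default_rng(0), initial_state=0)
        assert np.all(s == 0)

    def test_unbiased_frequencies_within_sampling_error(self):
        A = build_matrix_from_triple(UNBIASED)
        s = emit_state_sequence(A, 100_000, np.random.default_rng(42))
        freqs = np.bincount(s, minlength=6) / s.size
        se = np.sqrt((1 / 6) * (5 / 6) / s.size)
        assert np.all(np.abs(freqs - 1 / 6) < 5 * se)

    def test_forbidden_transitions_never_emitted(self):
        from ordpat.ordinal import admissible_pair_matrix
        A = build_matrix_from_triple((0.2, 0.3, 0.5))
        s = emit_state_sequence(A, 5000, np.random.default_rng(7))
        adm = admissible_pair_matrix(3)
        assert adm[s[:-1], s[1:]].all()


class TestSynthesizeAmplitudes:
    def test_chained_ascending_motifs_are_monotone(self):
        x = synthesize_amplitudes([0, 0], 3, np.random.default_rng(0))
        assert x.size == 4
        assert np.all(np.diff(x) > 0)

    def test_descent_region_below_carried_samples(self):
        # after an ascending window, state q5 = (2,0,1) forces the new
        # sample below both carried-over values
        x = synthesize_amplitudes([0, 5], 3, np.random.default_rng(1))
        assert x[3] < x[1] and x[3] < x[2]

    def test_inadmissible_sequence_names_offending_index(self):
        with pytest.raises(InvalidSequenceError, match="index 1"):
            synthesize_amplitudes([0, 3], 3, np.random.default_rng(0))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("triple", [UNBIASED, (0.1, 0.1, 0.8), (0.5, 0.0, 0.5)])
    def test_motif_round_trip_identity(self, seed, triple):
        rng = np.random.default_rng(seed)
        A = build_matrix_from_triple(triple)
        states = emit_state_sequence(A, 998, rng)
        x = synthesize_amplitudes(states, 3, rng)
        assert np.array_equal(ordinal_sequence(x, 3), states)
        assert np.unique(x).size == x.size  # tie-free

    def test_round_trip_independent_of_extension_width(self):
        A = build_matrix_from_triple((0.1, 0.1, 0.8))
        states = emit_state_sequence(A, 300, np.random.default_rng(3))
        for delta in (0.01, 1.0, 50.0):
            x = synthesize_amplitudes(states, 3, np.random.default_rng(4), delta=delta)
            assert np.array_equal(ordinal_sequence(x, 3), states)


class TestGenerateDataset:
    def test_shapes_labels_counts(self):
        rng = np.random.default_rng(0)
        ds = generate_dataset(UNBIASED, (0.1, 0.1, 0.8), 5, 100, rng)
        assert len(ds) == 10
        assert sum(s.label == "A" for s in ds) == 5
        assert all(s.amplitudes.size == 100 for s in ds)
        assert all(s.states.size == 98 for s in ds)

    def test_minimal_boundary(self):
        ds = generate_dataset(UNBIASED, UNBIASED, 1, 3, np.random.default_rng(0))
        assert len(ds) == 2 and all(s.states.size == 1 for s in ds)

    def test_seed_reproducibility(self):
        d1 = generate_dataset(UNBIASED, (0.1, 0.1, 0.8), 3, 50, np.random.default_rng(11))
        d2 = generate_dataset(UNBIASED, (0.1, 0.1, 0.8), 3, 50, np.random.default_rng(11))
        for a, b in zip(d1, d2):
            assert np.array_equal(a.amplitudes, b.amplitudes)
            assert np.array_equal(a.states, b.states)

    def test_biased_histogram_matches_stationary_law(self):
        A = build_matrix_from_triple((0.1, 0.1, 0.8))
        pi = stationary_distribution(A)
        s = generate_series(A, 20_000, np.random.default_rng(21))
        freqs = relative_frequencies(s.amplitudes).p
        assert np.max(np.abs(freqs - pi)) < 0.02
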