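"""The ordinal speed HMM: transition kernel, emissions, Viterbi."""

import numpy as np
import pytest

from conftest import brute_force_viterbi, random_hmm_instance, score_path
from emgspeed import speedhmm
from emgspeed.reference import REFERENCE_OFFLINE_CONFUSION
from emgspeed.speedhmm import (
    SPEEDS,
    HmmModel,
    emission_from_confusion,
    gaussian_transition_matrix,
    uniform_initial,
    viterbi,
)

# Distinct entries of the 7-state unit-sd kernel as printed in the
# benchmark table, indexed by |i - j|, with one unit of the last printed
# digit as tolerance (the 0.39 entry truncates phi(0) = 0.3989).
PRINTED_KERNEL = {
    0: (3.9e-1, 1e-2), 1: (2.4e-1, 1e-2), 2: (5.4e-2, 1e-3),
    3: (4.43e-3, 1e-5), 4: (1.34e-4, 1e-6), 5: (1.49e-6, 1e-8),
    6: (6.08e-9, 1e-11),
}


class TestUniformInitial:
    def test_seven_states(self):
        np.testing.assert_allclose(uniform_initial(7), 1.0 / 7.0)

    def test_single_state(self):
        np.testing.assert_array_equal(uniform_initial(1), [1.0])

    @pytest.mark.parametrize("m", [1, 2, 7, 20])
    def test_sums_to_one(self, m):
        assert uniform_initial(m).sum() == pytest.approx(1.0)

    def test_zero_states_rejected(self):
        with pytest.raises(ValueError):
            uniform_initial(0)


class TestGaussianTransition:
    def test_reproduces_printed_values_to_3_significant_figures(self):
        A = gaussian_transition_matrix(7, sd=1.0)
        for i in range(7):
            for j in range(7):
                expected, ulp = PRINTED_KERNEL[abs(i - j)]
                assert A[i, j] == pytest.approx(expected, abs=ulp)

    def test_symmetric_with_diagonal_row_maxima(self):
        A = gaussian_transition_matrix(7)
        np.testing.assert_allclose(A, A.T)
        assert np.all(np.argmax(A, axis=1) == np.arange(7))

    def test_normalized_rows_sum_to_one(self):
        A = gaussian_transition_matrix(7, normalize=True)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_unnormalized_edge_rows_are_densities(self):
        # edge rows of the raw kernel sum to ~0.69, interior to ~1.0
        A = gaussian_transition_matrix(7)
        assert A[0].sum() == pytest.approx(0.6995, abs=5e-3)
        assert A[3].sum() == pytest.approx(1.0, abs=5e-3)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_transition_matrix(7, sd=0.0)


class TestEmissionFromConfusion:
    def test_benchmark_matrix_preserved_up_to_flooring(self):
        B = emission_from_confusion(REFERENCE_OFFLINE_CONFUSION)
        C = REFERENCE_OFFLINE_CONFUSION
        for i in range(7):
            row_sum = C[i].sum()  # printed rows carry rounding slack
            nz = C[i] > 0
            np.testing.assert_allclose(B[i, nz], C[i, nz] / row_sum, rtol=1e-4)
            assert np.all(B[i, ~nz] > 0)
            assert np.all(B[i, ~nz] < 2e-6)

    def test_identity_gets_off_diagonal_floor(self):
        B = emission_from_confusion(np.eye(7), floor=1e-6)
        assert np.all(np.diag(B) > 0.99999)
        off = B[~np.eye(7, dtype=bool)]
        assert np.all((off > 0) & (off < 1.1e-6))

    def test_rows_sum_to_one(self):
        B = emission_from_confusion(REFERENCE_OFFLINE_CONFUSION)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_rejected(self):
        C = np.eye(7).copy()
        C[2] = 0.0
        with pytest.raises(ValueError, match="zero"):
            emission_from_confusion(C)


class TestViterbi:
    def test_single_observation_is_emission_argmax(self, reference_hmm):
        """T=1 with uniform pi: the decoded state maximizes B[:, obs];
        for the benchmark matrix and label 8 km/h that is 8 km/h (0.9118
        dominates its column)."""
        path = viterbi([8], reference_hmm)
        assert path.states.tolist() == [8]

    def test_identity_emissions_echo_observations(self):
        model = HmmModel(
            pi=uniform_initial(7),
            A=gaussian_transition_matrix(7),
            B=emission_from_confusion(np.eye(7)),
        )
        obs = [3, 3, 4, 5, 5, 9, 9, 8]
        np.testing.assert_array_equal(viterbi(obs, model).states, obs)

    def test_empty_sequence_rejected(self, reference_hmm):
        with pytest.raises(ValueError, match="nonempty"):
            viterbi([], reference_hmm)

    def test_unknown_label_rejected(self, reference_hmm):
        with pytest.raises(ValueError, match="alphabet"):
            viterbi([3, 11], reference_hmm)

    def test_matches_brute_force_enumeration(self):
        """>= 200 random instances with N <= 4 states and T <= 6 steps:
        the decoded path must attain the exhaustive-search maximum (the
        path itself may differ only on floating-point near-ties, so the
        check is on independently re-scored probabilities)."""
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(2, 5))
            t_len = int(rng.integers(1, 7))
            pi, A, B, obs_idx = random_hmm_instance(rng, n, t_len)
            states = tuple(range(n))
            model = HmmModel(pi=pi, A=A, B=B, states=states)
            got = viterbi(obs_idx, model)
            want_path, want_logp = brute_force_viterbi(obs_idx, pi, A, B)
            assert got.log_prob == pytest.approx(want_logp, rel=1e-9)
            assert score_path(got.states, obs_idx, pi, A, B) == pytest.approx(
                want_logp, rel=1e-9
            )

    def test_path_invariant_to_scaling_one_emission_column(self):
        """Multiplying the emissions of a single time step by c > 0 shifts
        the path log-probability by log c and leaves the path unchanged —
        the log-domain recursion is correct up to per-column constants."""
        rng = np.random.default_rng(7)
        pi, A, B, _ = random_hmm_instance(rng, 4, 5)
        obs_idx = np.array([0, 1, 2, 3, 1])
        base = viterbi(obs_idx, HmmModel(pi=pi, A=A, B=B, states=(0, 1, 2, 3)))
        c = 37.5
        B2 = B.copy()
        B2[:, 2] *= c  # label 2 occurs exactly once in obs
        # bypass __post_init__: a column-scaled B is deliberately unnormalized
        model2 = HmmModel.__new__(HmmModel)
        model2.pi, model2.A, model2.B = pi, A, B2
        model2.states = (0, 1, 2, 3)
        scaled = viterbi(obs_idx, model2)
        np.testing.assert_array_equal(scaled.states, base.states)
        assert scaled.log_prob == pytest.approx(base.log_prob + np.log(c))

    def test_trellis_retained_on_request(self, reference_hmm):
        path = viterbi([5, 5, 6], reference_hmm, keep_trellis=True)
        assert path.delta.shape == (3, 7)
        assert path.psi.shape == (3, 7)

    def test_agrees_with_hmmlearn(self):
        """Cross-check against an independent HMM library on a proper
        (row-stochastic) model."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(13)
        pi, A, B, _ = random_hmm_instance(rng, 5, 1)
        obs_idx = rng.integers(0, 5, size=40)
        ref = hmmlearn.CategoricalHMM(n_components=5)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, A, B
        _, ref_path = ref.decode(obs_idx.reshape(-1, 1), algorithm="viterbi")
        got = viterbi(obs_idx, HmmModel(pi=pi, A=A, B=B, states=(0, 1, 2, 3, 4)))
        np.testing.assert_array_equal(got.states, ref_path)


class TestNormalizedVsRawTransitions:
    def test_paths_nearly_identical_on_standard_fixture(self, standard_fixture):
        """Row-normalizing A rescales each row by a constant; on the
        140-window benchmark fixture the two decodings agree on >= 95 %
        of windows (observed: at most one differing window)."""
        true, obs = standard_fixture
        raw = HmmModel.standard(REFERENCE_OFFLINE_CONFUSION, normalize=False)
        nrm = HmmModel.standard(REFERENCE_OFFLINE_CONFUSION, normalize=True)
        p_raw = viterbi(obs, raw).states
        p_nrm = viterbi(obs, nrm).states
        assert np.mean(p_raw == p_nrm) >= 0.95


class TestHmmModelValidation:
    def test_bad_pi_rejected(self):
        with pytest.raises(ValueError, match="pi"):
            HmmModel(
                pi=np.full(7, 0.2),
                A=gaussian_transition_matrix(7),
                B=emission_from_confusion(np.eye(7)),
            )

    def test_unnormalized_B_rejected(self):
        with pytest.raises(ValueError, match="B rows"):
            HmmModel(
                pi=uniform_initial(7),
                A=gaussian_transition_matrix(7),
                B=np.eye(7) * 0.9,
            )

    def test_json_roundtrip(self, tmp_path, reference_hmm):
        path = tmp_path / "hmm.json"
        speedhmm.save_model(reference_hmm, path)
        clone = speedhmm.load_model(path)
        assert clone.states == reference_hmm.states
        np.testing.assert_allclose(clone.pi, reference_hmm.pi)
        np.testing.assert_allclose(clone.A, reference_hmm.A)
        np.testing.assert_allclose(clone.B, reference_hmm.B)


class TestOnlineDecoding:
    def test_output_length_matches_input(self, reference_hmm):
        rng = np.random.default_rng(3)
        obs = rng.choice(SPEEDS, size=30)
        out = speedhmm.decode_online(obs, reference_hmm, history=9)
        assert out.shape == obs.shape
        assert set(np.unique(out)) <= set(SPEEDS)

    def test_history_one_is_memoryless(self, reference_hmm):
        obs = [3, 9, 4, 8]
        out = speedhmm.decode_online(obs, reference_hmm, history=1)
        want = [viterbi([o], reference_hmm).states[0] for o in obs]
        np.testing.assert_array_equal(out, want)
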