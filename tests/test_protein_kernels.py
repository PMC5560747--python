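import numpy as np
import pytest

from helpers import gs_kernel_oracle, sw_score_oracle
from kronaff.compound_kernels import SimilarityMatrix, linear_kernel_from_similarity
from kronaff.io_formats import STANDARD_AMINO_ACIDS, SequenceSet
from kronaff.kronrls_core import fit, predict_matrix
from kronaff.protein_kernels import (
    AlignmentParams,
    GSKernelParams,
    blosum_descriptor_table,
    gs_kernel,
    gs_kernel_matrix,
    identity_protein_kernel,
    kernel_from_precomputed_similarity,
    normalize_by_self_scores,
    normalized_sw_similarity,
    smith_waterman_score,
    sw_kernel,
    sw_plus_profiles,
    sw_similarity_matrix,
)


def _random_seq(rng, lo=5, hi=40):
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=rng.integers(lo, hi)))


class TestSmithWaterman:
    def test_ungapped_self_alignment_sums_diagonal(self, align_params, blosum50):
        # BLOSUM50 A/A = 5, optimum is the ungapped diagonal
        assert smith_waterman_score("AAA", "AAA", align_params) == 15.0

    def test_matches_affine_gap_dp_oracle(self, align_params, blosum50, rng):
        for _ in range(12):
            s1, s2 = _random_seq(rng, 3, 25), _random_seq(rng, 3, 25)
            expected = sw_score_oracle(
                s1, s2, blosum50, align_params.gap_open, align_params.gap_extend
            )
            assert smith_waterman_score(s1, s2, align_params) == pytest.approx(expected)

    def test_symmetry(self, align_params, rng):
        s1, s2 = _random_seq(rng), _random_seq(rng)
        assert smith_waterman_score(s1, s2, align_params) == pytest.approx(
            smith_waterman_score(s2, s1, align_params)
        )

    def test_empty_sequence_rejected(self, align_params):
        with pytest.raises(ValueError):
            smith_waterman_score("", "AAA", align_params)

    def test_gap_extend_must_not_exceed_open(self, blosum50):
        with pytest.raises(ValueError):
            AlignmentParams(substitution=blosum50, gap_open=1.0, gap_extend=2.0)


class TestNormalizedSW:
    def test_self_similarity_is_exactly_one(self, align_params, rng):
        s = _random_seq(rng)
        assert normalized_sw_similarity(s, s, align_params) == 1.0

    def test_bounded_by_one_on_random_pairs(self, align_params, rng):
        for _ in range(15):
            s1, s2 = _random_seq(rng), _random_seq(rng)
            assert normalized_sw_similarity(s1, s2, align_params) <= 1.0 + 1e-12

    def test_matrix_symmetric_with_unit_diagonal(self, align_params, rng):
        seqs = SequenceSet([f"p{i}" for i in range(4)], [_random_seq(rng) for _ in range(4)])
        S = sw_similarity_matrix(seqs, align_params)
        assert np.allclose(S.values, S.values.T)
        assert np.allclose(np.diag(S.values), 1.0)


class TestSWPlus:
    def test_reference_equal_to_targets_has_unit_self_column(self, align_params, rng):
        seqs = SequenceSet([f"p{i}" for i in range(3)], [_random_seq(rng) for _ in range(3)])
        prof = sw_plus_profiles(seqs, seqs, align_params)
        assert prof.values.shape == (3, 3)
        assert np.allclose(np.diag(prof.values), 1.0)

    def test_profile_shape_is_targets_by_reference(self, align_params, rng):
        targets = SequenceSet(["t0", "t1", "t2"], [_random_seq(rng) for _ in range(3)])
        ref = SequenceSet([f"h{i}" for i in range(5)], [_random_seq(rng) for _ in range(5)])
        prof = sw_plus_profiles(targets, ref, align_params)
        assert prof.values.shape == (3, 5)

    def test_entries_match_pairwise_normalized_sw(self, align_params, rng):
        targets = SequenceSet(["t0", "t1", "t2"], [_random_seq(rng, 5, 20) for _ in range(3)])
        ref = SequenceSet([f"h{i}" for i in range(5)], [_random_seq(rng, 5, 20) for _ in range(5)])
        prof = sw_plus_profiles(targets, ref, align_params)
        for i, ts in enumerate(targets.sequences):
            for l, rs in enumerate(ref.sequences):
                assert prof.values[i, l] == pytest.approx(
                    normalized_sw_similarity(ts, rs, align_params)
                )


class TestGSKernel:
    def test_single_residue_identity(self):
        assert gs_kernel("A", "A", GSKernelParams(L=1)) == pytest.approx(1.0)

    def test_two_residue_hand_expansion(self):
        params = GSKernelParams(L=1, sigma_p=1.7, sigma_c=9.0)
        table = blosum_descriptor_table()
        psi = table.encode("AC")
        d2 = float(((psi[0] - psi[1]) ** 2).sum())
        expected = 2 + 2 * np.exp(-1 / (2 * params.sigma_p**2)) * np.exp(
            -d2 / (2 * params.sigma_c**2)
        )
        assert gs_kernel("AC", "AC", params) == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self, rng):
        table = blosum_descriptor_table()
        for _ in range(8):
            s = _random_seq(rng, 1, 9)
            t = _random_seq(rng, 1, 9)
            params = GSKernelParams(
                L=int(rng.integers(1, 4)),
                sigma_p=float(rng.uniform(0.5, 3.0)),
                sigma_c=float(rng.uniform(4.0, 25.0)),
            )
            expected = gs_kernel_oracle(
                s, t, params.L, params.sigma_p, params.sigma_c, table
            )
            assert gs_kernel(s, t, params, table) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_in_arguments(self, rng):
        params = GSKernelParams(L=3, sigma_p=1.0, sigma_c=10.0)
        s, t = _random_seq(rng, 4, 12), _random_seq(rng, 4, 12)
        assert gs_kernel(s, t, params) == pytest.approx(gs_kernel(t, s, params))

    def test_monotone_nondecreasing_in_L(self, rng):
        s, t = _random_seq(rng, 6, 12), _random_seq(rng, 6, 12)
        values = [
            gs_kernel(s, t, GSKernelParams(L=L, sigma_p=1.0, sigma_c=10.0))
            for L in range(1, 5)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_L_exceeding_sequence_length_allowed(self):
        params = GSKernelParams(L=10, sigma_p=1.0, sigma_c=5.0)
        assert gs_kernel("AC", "A", params) > 0.0

    def test_matrix_is_normalized_psd(self, rng):
        seqs = SequenceSet(
            [f"p{i}" for i in range(5)], [_random_seq(rng, 8, 20) for _ in range(5)]
        )
        K = gs_kernel_matrix(seqs, GSKernelParams(L=2, sigma_p=1.0, sigma_c=10.0))
        assert K.normalized
        K.check()


class TestIdentityKernel:
    def test_exact_identity(self):
        K = identity_protein_kernel(["a", "b", "c"])
        assert np.array_equal(K.values, np.eye(3))

    def test_kronrls_reduces_to_per_protein_drug_ridge(self, rng):
        """With K_P = I the Kronecker model decouples into one drug-side
        kernel ridge regression per protein column."""
        n_D, n_P, lam = 6, 4, 0.8
        A = rng.normal(size=(n_D, n_D + 2))
        K_D = A @ A.T
        Y = rng.normal(7, 1, size=(n_D, n_P))
        model = fit(K_D, np.eye(n_P), Y, lam)
        preds = predict_matrix(model, K_D, np.eye(n_P))
        for j in range(n_P):
            alpha_j = np.linalg.solve(K_D + lam * np.eye(n_D), Y[:, j])
            assert np.allclose(preds[:, j], K_D @ alpha_j, atol=1e-8)


class TestPrecomputedSimilarity:
    def test_self_score_normalization(self):
        S = SimilarityMatrix(
            list("ab"), list("ab"), np.array([[4.0, 2.0], [2.0, 9.0]])
        )
        N = normalize_by_self_scores(S)
        assert np.allclose(np.diag(N.values), 1.0)
        assert N.values[0, 1] == pytest.approx(2.0 / 6.0)

    def test_kernel_from_raw_scores_is_valid(self, rng):
        B = rng.normal(size=(4, 4))
        raw = B @ B.T + 5 * np.eye(4)
        S = SimilarityMatrix(list("abcd"), list("abcd"), raw)
        K = kernel_from_precomputed_similarity(S)
        assert K.normalized
        K.check()


def test_sw_kernel_valid(align_params, rng):
    seqs = SequenceSet([f"p{i}" for i in range(5)], [_random_seq(rng) for _ in range(5)])
    K = sw_kernel(seqs, align_params)
    assert K.normalized
    K.check()
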