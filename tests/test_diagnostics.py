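"""MIP, ERC, SNR, lambda_min and the noisy-recovery guarantee."""

import numpy as np
import pytest

from usdl.diagnostics import erc, guarantee_check, lambda_min, mip, snr


def erc_pinv_oracle(Psi, S):
    """Dense pseudo-inverse evaluation of the exact recovery coefficient."""
    Psi_bar = Psi / np.linalg.norm(Psi, axis=0)
    S = sorted(S)
    off = [q for q in range(Psi.shape[1]) if q not in S]
    if not off:
        return 1.0
    M = np.linalg.pinv(Psi_bar[:, S]) @ Psi_bar[:, off]
    return 1.0 - np.abs(M).sum(axis=0).max()


class TestMip:
    def test_orthogonal_design_is_zero(self):
        assert mip(np.eye(5)) == 0.0

    def test_duplicated_column_is_one(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((6, 4))
        M[:, 2] = 2.5 * M[:, 0]  # collinear pair
        assert mip(M) == 1.0

    def test_cosine_of_45_degrees(self):
        M = np.array([[1.0, 1 / np.sqrt(2)], [0.0, 1 / np.sqrt(2)]])
        assert mip(M) == pytest.approx(1 / np.sqrt(2))

    def test_scale_and_permutation_invariance(self):
        rng = np.random.default_rng(7)
        M = rng.standard_normal((10, 5))
        scaled = M * rng.uniform(0.1, 10.0, size=5)
        perm = rng.permutation(5)
        assert mip(scaled) == pytest.approx(mip(M), rel=1e-12)
        assert mip(M[:, perm]) == pytest.approx(mip(M), rel=1e-12)

    def test_zero_column_rejected_by_name(self):
        M = np.eye(3)
        M[:, 1] = 0.0
        with pytest.raises(ValueError, match="column 1"):
            mip(M)


class TestErc:
    def test_orthogonal_design_gives_one(self):
        assert erc(np.eye(4), [0, 1]) == pytest.approx(1.0)

    def test_duplicated_column_gives_zero(self):
        M = np.column_stack([np.array([1.0, 0.0]), np.array([1.0, 0.0])])
        assert erc(M, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_full_support_returns_one_by_convention(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((5, 3))
        assert erc(M, [0, 1, 2]) == 1.0

    def test_small_matrix_against_direct_solve(self):
        M = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5],
                      [0.0, 0.0, 1 / np.sqrt(2)], [0.0, 0.0, 0.0]])
        S = [0, 1]
        assert erc(M, S) == pytest.approx(erc_pinv_oracle(M, S), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_normal_equations_match_pinv_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Psi = rng.standard_normal((10, 6))
        S = sorted(rng.choice(6, size=3, replace=False).tolist())
        assert erc(Psi, S) == pytest.approx(erc_pinv_oracle(Psi, S), abs=1e-10)

    def test_rank_deficient_support_raises(self):
        M = np.column_stack([np.ones(4), np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            erc(M, [0, 1])

    def test_weakly_decreases_with_coherent_off_support_column(self):
        rng = np.random.default_rng(5)
        Psi = rng.standard_normal((12, 4))
        S = [0, 1]
        base = erc(Psi, S)
        coherent = np.column_stack([Psi, Psi[:, 0] + 1e-3 * Psi[:, 2]])
        assert erc(coherent, S) <= base + 1e-12


class TestSnr:
    def test_unit_columns_noise_two(self):
        assert np.allclose(snr(np.eye(3), np.array([0.0, 2.0, 0.0])), 0.5)

    def test_homogeneity_in_noise(self):
        rng = np.random.default_rng(1)
        Psi = rng.standard_normal((8, 4))
        e = rng.standard_normal(8)
        assert np.allclose(snr(Psi, 10 * e), snr(Psi, e) / 10)

    def test_zero_noise_gives_infinite_sentinel(self):
        assert np.all(np.isinf(snr(np.eye(2), np.zeros(2))))

    def test_matches_norm_computation(self, rng):
        Psi = rng.standard_normal((9, 5))
        e = rng.standard_normal(9)
        expected = np.linalg.norm(Psi, axis=0) / np.linalg.norm(e)
        assert np.allclose(snr(Psi, e), expected)


class TestLambdaMin:
    def test_orthonormal_support_gives_one(self):
        assert lambda_min(np.eye(5), [0, 2, 4]) == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", [0.2, 0.7, 1.3])
    def test_two_columns_at_angle(self, theta):
        M = np.array([[1.0, np.cos(theta)], [0.0, np.sin(theta)]])
        assert lambda_min(M, [0, 1]) == pytest.approx(1 - np.cos(theta))

    def test_duplicated_column_gives_zero(self):
        M = np.column_stack([np.ones(3), np.ones(3)])
        assert lambda_min(M, [0, 1]) == pytest.approx(0.0, abs=1e-12)


class TestGuarantee:
    def test_noiseless_limit_vacuously_passes(self):
        Psi = np.eye(4)
        a = np.array([0.5, 0.0, -2.0, 0.0])
        rep = guarantee_check(a, Psi, [0, 2], np.zeros(4))
        assert rep.available and rep.all_passed
        assert np.allclose(rep.thresholds, 0.0)

    def test_zero_erc_reports_unavailable(self):
        M = np.column_stack([np.ones(3), np.ones(3), np.eye(3)[:, 0]])
        rep = guarantee_check(np.array([1.0, 0, 0]), M, [0], np.ones(3))
        assert not rep.available and not rep.all_passed

    def test_threshold_formula_audit(self):
        # orthogonal design: ERC = 1, lambda_min = 1, threshold = 2/SNR
        Psi = 2 * np.eye(3)
        e = np.array([1.0, 0.0, 0.0])
        a = np.array([3.0, 0.0, 0.0])
        rep = guarantee_check(a, Psi, [0], e)
        assert rep.thresholds[0] == pytest.approx(2 / 2.0)
        assert rep.all_passed

    def test_passing_check_predicts_omp_recovery(self):
        # seeded noisy instances: whenever the condition passes, OMP finds
        # the true support (consistency of the sufficient condition)
        from usdl.ssr_omp import omp
        from tests.conftest import make_sparse_instance
        checked = 0
        for seed in range(100):
            Psi, a, support, z = make_sparse_instance(seed, noise=0.01)
            e = z - Psi @ a
            rep = guarantee_check(a, Psi, sorted(support), e)
            if not rep.all_passed:
                continue
            checked += 1
            sol = omp(z, Psi, alpha=0.1, kmax=2)
            assert set(sol.support) == support
        assert checked > 50  # the condition holds on most mild-noise draws
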