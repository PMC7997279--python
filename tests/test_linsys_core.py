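"""Unit and property tests for the exact OU-system algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blanketlab as bl
from blanketlab.linsys_core import BlockView, specnorm

from conftest import brute_force_conditional, random_partition, random_potential_system


class TestSolveSolenoidal:
    def test_symmetric_drift_gives_zero(self):
        R = bl.solve_solenoidal(-np.eye(2), np.eye(2)).R
        assert np.array_equal(R, np.zeros((2, 2)))

    def test_rotational_drift(self):
        M = np.array([[-1.0, 1.0], [-1.0, -1.0]])
        R = bl.solve_solenoidal(M, np.eye(2)).R
        assert np.allclose(R, [[0.0, -1.0], [1.0, 0.0]], atol=1e-12)
        # both sides of the defining relation
        assert np.allclose(M @ R + R @ M.T, [[0.0, 2.0], [-2.0, 0.0]], atol=1e-12)

    def test_imaginary_axis_eigenvalues_rejected(self):
        with pytest.raises(bl.SolvabilityError):
            bl.solve_solenoidal(np.array([[0.0, 1.0], [-1.0, 0.0]]), np.eye(2))

    @pytest.mark.parametrize("seed", range(12))
    def test_antisymmetry_of_solutions(self, seed):
        system, _, R_true, _ = random_potential_system(seed)
        sol = bl.solve_solenoidal(system.M, system.Gamma).R
        nrm = specnorm(sol)
        assert nrm == 0.0 or specnorm(sol + sol.T) / nrm < 1e-10
        assert np.allclose(sol, R_true, atol=1e-8 * max(1.0, nrm))


class TestLyapunovCovariance:
    @pytest.mark.parametrize("M, Gamma, C", [
        (-np.eye(3), np.eye(3), np.eye(3)),
        (np.array([[-2.0]]), np.array([[1.0]]), np.array([[0.5]])),
        (np.array([[-1.0, 1.0], [-1.0, -1.0]]), np.eye(2), np.eye(2)),
    ])
    def test_known_solutions(self, M, Gamma, C):
        assert np.allclose(bl.lyapunov_covariance(M, Gamma), C, atol=1e-12)

    def test_non_hurwitz_rejected(self):
        with pytest.raises(bl.NonErgodicError):
            bl.lyapunov_covariance(np.array([[1.0]]), np.array([[1.0]]))


class TestStationaryPrecision:
    def test_decoupled(self):
        st_ = bl.stationary_precision(-np.eye(2), np.eye(2), np.zeros((2, 2)))
        assert np.allclose(st_.U, np.eye(2), atol=1e-12)

    def test_rotational(self):
        M = np.array([[-1.0, 1.0], [-1.0, -1.0]])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        st_ = bl.stationary_precision(M, np.eye(2), R)
        assert np.allclose(st_.U, np.eye(2), atol=1e-10)

    def test_scalar_reciprocal(self):
        st_ = bl.stationary_precision(np.array([[-2.0]]), np.array([[1.0]]), np.zeros((1, 1)))
        assert np.allclose(st_.U, [[2.0]])
        assert np.allclose(st_.C, [[0.5]])

    @pytest.mark.parametrize("seed", range(8))
    def test_precision_equals_inverse_lyapunov(self, seed):
        """The two routes to the stationary density agree, pinning the
        noise convention (autocovariance 2*Gamma)."""
        system, U, _, _ = random_potential_system(seed)
        C = bl.lyapunov_covariance(system.M, system.Gamma)
        rel = specnorm(np.linalg.inv(system.U) - C) / specnorm(C)
        assert rel < 1e-8
        assert specnorm(system.U - U) / specnorm(U) < 1e-8


class TestAssembleFromPotential:
    def test_identity_case(self):
        M = bl.assemble_from_potential(np.eye(2), np.zeros((2, 2)), np.eye(2))
        assert np.allclose(M, -np.eye(2))

    def test_rotational_reverse(self):
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        M = bl.assemble_from_potential(np.eye(2), R, np.eye(2))
        assert np.allclose(M, [[-1.0, 1.0], [-1.0, -1.0]])

    def test_degenerate_precision_rejected(self):
        U = np.array([[1.0, 1.0], [1.0, 1.0]])  # zero eigenvalue
        with pytest.raises(bl.NotSPDError):
            bl.assemble_from_potential(U, np.zeros((2, 2)), np.eye(2))

    def test_non_antisymmetric_rejected(self):
        with pytest.raises(bl.AsymmetryError):
            bl.assemble_from_potential(np.eye(2), np.eye(2), np.eye(2))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_recovers_potential(self, seed):
        """assemble -> solenoidal solve -> stationary density round-trips
        to the input (U, R) within relative 1e-8."""
        system, U, R, _ = random_potential_system(seed, d=6)
        R_hat = system.R
        U_hat = system.U
        assert specnorm(R_hat - R) / max(1.0, specnorm(R)) < 1e-8
        assert specnorm(U_hat - U) / specnorm(U) < 1e-8
        assert bl.SolenoidalMatrix(R_hat).check(system.M, system.Gamma) < 1e-8


class TestConditionalAndMarginal:
    def test_identity_precision(self, part1111):
        cond = bl.conditional_gaussian(np.eye(4), part1111, "psi", ("s", "a", "lambda"))
        assert np.allclose(cond.P, [[1.0]])
        assert np.allclose(cond.K, 0.0)

    def test_two_dimensional_worked_example(self):
        """U = [[2,1],[1,2]]: conditioning the first coordinate on the
        second gives mean -x2/2 and variance 1/2 (precision 2)."""
        part = bl.CoordinatePartition(1, 1, 1, 1)
        U = np.eye(4)
        U[0, 0] = U[1, 1] = 2.0
        U[0, 1] = U[1, 0] = 1.0
        cond = bl.conditional_gaussian(U, part, "psi", ("s", "a", "lambda"))
        assert np.allclose(cond.P[0, 0], 2.0)
        assert np.allclose(cond.K[0, 0], -0.5)
        # brute-force covariance route
        cov, gain = brute_force_conditional(U, np.array([0]), np.array([1, 2, 3]))
        assert np.allclose(cond.covariance, cov, atol=1e-12)
        assert np.allclose(cond.K, gain, atol=1e-12)

    def test_overlapping_blocks_rejected(self, part1111):
        with pytest.raises(bl.BlockError):
            bl.conditional_gaussian(np.eye(4), part1111, ("psi", "s"), ("s",))
        with pytest.raises(bl.BlockError):
            bl.marginal_precision(np.eye(4), part1111, ())

    def test_marginal_identity_and_schur(self, part1111):
        assert np.allclose(
            bl.marginal_precision(np.eye(4), part1111, ("psi", "s", "a", "lambda")),
            np.eye(4))
        # U = [[2,1],[1,2]] embedded in psi,s: marginalise out psi
        U = np.eye(4)
        U[0, 0] = U[1, 1] = 2.0
        U[0, 1] = U[1, 0] = 1.0
        C = np.linalg.inv(U)
        V = bl.marginal_precision(C, part1111, ("s", "a", "lambda"))
        assert np.allclose(V[0, 0], 1.5)  # Schur complement 2 - 1*(1/2)*1

    @pytest.mark.parametrize("seed", range(6))
    def test_schur_equivalence_random(self, seed):
        """Conditional and marginal agree with brute-force full-matrix
        inversion on random 4-8 dimensional precisions."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(4, 9))
        part = random_partition(rng, d)
        X = rng.uniform(-1, 1, (d, d))
        U = (X + X.T) / 2 + d * np.eye(d)
        cond = bl.conditional_gaussian(U, part, "psi", ("s", "a", "lambda"))
        cov, gain = brute_force_conditional(U, part.indices(("psi",)),
                                            part.indices(("s", "a", "lambda")))
        assert np.allclose(cond.covariance, cov, atol=1e-10)
        assert np.allclose(cond.K, gain, atol=1e-10)
        V = bl.marginal_precision(np.linalg.inv(U), part, ("s", "a", "lambda"))
        # Schur complement route on the precision
        bi = part.indices(("s", "a", "lambda"))
        ri = part.indices(("psi",))
        schur = U[np.ix_(bi, bi)] - U[np.ix_(bi, ri)] @ np.linalg.solve(
            U[np.ix_(ri, ri)], U[np.ix_(ri, bi)])
        assert np.allclose(V, schur, atol=1e-10)

    def test_partial_conditioning_marginalises_rest(self):
        """Conditioning psi on s only (a, lambda marginalised out)."""
        rng = np.random.default_rng(3)
        part = bl.CoordinatePartition(1, 1, 1, 1)
        X = rng.uniform(-1, 1, (4, 4))
        U = (X + X.T) / 2 + 4 * np.eye(4)
        cond = bl.conditional_gaussian(U, part, "psi", "s")
        cov, gain = brute_force_conditional(U, np.array([0]), np.array([1]))
        assert np.allclose(cond.covariance, cov, atol=1e-10)
        assert np.allclose(cond.K, gain, atol=1e-10)


class TestBlockView:
    def test_reassembly_exact(self):
        rng = np.random.default_rng(0)
        part = bl.CoordinatePartition(2, 1, 3, 2)
        X = rng.standard_normal((part.d, part.d))
        view = BlockView(X, part)
        rebuilt = np.zeros_like(X)
        out = BlockView(rebuilt, part)
        for r in bl.BLOCKS:
            for c in bl.BLOCKS:
                out[r, c] = view[r, c]
        assert np.array_equal(rebuilt, X)

    def test_unknown_label_rejected(self):
        part = bl.CoordinatePartition(1, 1, 1, 1)
        with pytest.raises(bl.BlockError):
            BlockView(np.eye(4), part)["psi", "bogus"]

    def test_partition_invariants(self):
        with pytest.raises(bl.BlockError):
            bl.CoordinatePartition(0, 1, 1, 1)
        p = bl.CoordinatePartition(2, 3, 1, 4)
        assert p.d == 10
        idx = np.concatenate([p.indices((b,)) for b in bl.BLOCKS])
        assert np.array_equal(idx, np.arange(10))


class TestGibbsEnergy:
    def test_standard_normal_at_origin(self):
        st_ = bl.StationaryGaussian(U=np.eye(3), C=np.eye(3))
        assert np.isclose(st_.gibbs_energy(np.zeros(3)), 1.5 * np.log(2 * np.pi))

    def test_quadratic_growth(self):
        st_ = bl.StationaryGaussian(U=2.0 * np.eye(1), C=0.5 * np.eye(1))
        x = np.array([1.5])
        assert np.isclose(st_.gibbs_energy(x) - st_.gibbs_energy(0 * x), 0.5 * 2.0 * 1.5 ** 2)
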