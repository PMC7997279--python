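"""Tests for the Gaussian free-energy / KL analysis."""

import numpy as np
import pytest

import blanketlab as bl
from blanketlab.lemma_analysis import kl_gradient_maps, kl_profile
from blanketlab.synthetic_systems import ConstraintSpec

from conftest import mc_mutual_information, quadrature_kl_1d, random_potential_system


_ALL_R_PAIRS = (("psi", "s"), ("psi", "a"), ("psi", "lambda"),
                ("s", "a"), ("s", "lambda"), ("a", "lambda"))

_C1_M_ZEROS = (("a", "psi"), ("lambda", "psi"), ("s", "lambda"), ("psi", "lambda"))


def decoupled_psi_system(seed=0):
    """External coordinates independent of everything: the conditional
    is constant, so a matching q exists with identically zero KL."""
    spec = ConstraintSpec(
        partition=bl.CoordinatePartition(1, 1, 1, 1),
        zero_U=(("psi", "s"), ("psi", "a"), ("psi", "lambda"), ("s", "lambda")),
        zero_R=_ALL_R_PAIRS,
        seed=seed,
    )
    return bl.generate_system(spec)


def lambda_tracking_system(seed=0):
    """Conditional mean of psi depends on lambda only, under the blanket
    drift pattern: q with the matching gain reproduces the conditional.

    Realisable only through the active-internal solenoidal coupling
    (so the cross and marginal families apply but the diagonal one does
    not), and only on the solenoidal submanifold r_psi,a =
    r_a,lambda * r_psi,lambda: off it the drift constraints force
    U_psi,psi = 0, and without the coupling they force
    U_lambda,lambda < 0 — no such ergodic gradient-flow system exists.
    Built entry-wise from that analysis (scalars, Gamma = I)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        r_ps = rng.uniform(0.1, 0.4) * rng.choice([-1, 1])
        r_pl = rng.uniform(0.3, 0.8) * rng.choice([-1, 1])
        r_al = rng.uniform(0.9, 1.1) * rng.choice([-1, 1])
        r_pa = r_al * r_pl
        R = np.zeros((4, 4))
        R[0, 1], R[0, 2], R[0, 3], R[2, 3] = r_ps, r_pa, r_pl, r_al
        R -= R.T
        u_pp = 1.0
        u_pl = r_pl * u_pp
        u_sl = r_ps * u_pl
        u_al = -rng.uniform(2.0, 2.5) / r_al   # strong coupling buys u_ll > 0
        u_ll = -(u_pl + r_ps * u_sl + r_pa * u_al) / r_pl
        U = np.array([
            [u_pp, 0.0, 0.0, u_pl],
            [0.0, 3.0, rng.uniform(-0.5, 0.5), u_sl],
            [0.0, 0.0, 6.0, u_al],
            [0.0, 0.0, 0.0, u_ll],
        ])
        U = np.triu(U) + np.triu(U, 1).T
        if np.min(np.linalg.eigvalsh(U)) <= 1e-6:
            continue
        M = -(np.eye(4) + R) @ U
        system = bl.LinearOUSystem(bl.CoordinatePartition(1, 1, 1, 1), M, np.eye(4))
        if bl.check_condition(system, 1).satisfied and abs(U[0, 3]) > 1e-3:
            return system
    raise AssertionError("lambda-tracking witness not found")


class TestGaussianKL:
    def test_zero_iff_equal(self, isotropic_system):
        cond = bl.posterior(isotropic_system)
        q = bl.VariationalGaussian(A=np.zeros((1, 1)), b=np.zeros(1), S=cond.covariance)
        assert bl.gaussian_kl(q, cond, np.zeros(3)) == 0.0

    def test_mean_shift(self):
        """Equal unit covariances, mean difference (2, 0): KL = |d|^2/2 = 2."""
        part = bl.CoordinatePartition(2, 1, 1, 1)
        system = bl.LinearOUSystem(part, -np.eye(5), np.eye(5))
        cond = bl.posterior(system)
        q = bl.VariationalGaussian(A=np.zeros((2, 1)), b=np.array([2.0, 0.0]), S=np.eye(2))
        assert np.isclose(bl.gaussian_kl(q, cond, np.zeros(3)), 2.0)

    def test_variance_mismatch_against_quadrature(self, isotropic_system):
        """Unit conditional variance, q variance 4, equal means:
        KL = (4 - 1 - ln 4)/2, cross-checked by Gauss-Hermite quadrature."""
        cond = bl.posterior(isotropic_system)
        q = bl.VariationalGaussian(A=np.zeros((1, 1)), b=np.zeros(1), S=4.0 * np.eye(1))
        val = bl.gaussian_kl(q, cond, np.zeros(3))
        assert np.isclose(val, 0.5 * (4 - 1 - np.log(4)))
        assert np.isclose(val, quadrature_kl_1d(0.0, 4.0, 0.0, 1.0), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_gibbs_inequality(self, seed):
        """KL >= 0 for arbitrary Gaussian q at arbitrary blanket points."""
        system, *_ = random_potential_system(seed, partition=bl.CoordinatePartition(2, 1, 2, 2))
        cond = bl.posterior(system)
        rng = np.random.default_rng(seed)
        q = bl.VariationalGaussian(A=rng.uniform(-1, 1, (2, 2)), b=rng.uniform(-1, 1, 2),
                                   S=np.eye(2) + 0.5 * np.diag(rng.uniform(0, 1, 2)))
        for _ in range(20):
            y = rng.uniform(-3, 3, 5)
            assert bl.gaussian_kl(q, cond, y) >= 0.0

    def test_profile_matches_pointwise(self):
        system, *_ = random_potential_system(7, partition=bl.CoordinatePartition(1, 1, 1, 1))
        cond = bl.posterior(system)
        rng = np.random.default_rng(7)
        q = bl.VariationalGaussian(A=rng.uniform(-1, 1, (1, 1)), b=rng.uniform(-1, 1, 1),
                                   S=1.3 * np.eye(1))
        prof = kl_profile(system, q)
        for _ in range(20):
            y = rng.uniform(-2, 2, 3)
            assert np.isclose(prof(y), bl.gaussian_kl(q, cond, y), atol=1e-10)


class TestFreeEnergy:
    def test_reduces_to_negative_log_marginal(self, isotropic_system):
        """With q equal to the conditional the KL term vanishes and F is
        exactly -ln p*(s,a,lambda); at the origin of a standard normal
        marginal that is (3/2) ln 2 pi."""
        cond = bl.posterior(isotropic_system)
        q = bl.VariationalGaussian(A=np.zeros((1, 1)), b=np.zeros(1), S=cond.covariance)
        F = bl.free_energy(isotropic_system, q, np.zeros(3))
        assert np.isclose(F, 1.5 * np.log(2 * np.pi))

    @pytest.mark.parametrize("seed", [0, 3])
    def test_kl_is_the_only_q_dependence(self, seed):
        """F - KL equals -ln p*(s,a,lambda) for any q and point."""
        system, *_ = random_potential_system(seed, partition=bl.CoordinatePartition(1, 1, 1, 1))
        cond = bl.posterior(system)
        rng = np.random.default_rng(seed)
        qs = [bl.VariationalGaussian(A=rng.uniform(-1, 1, (1, 1)),
                                     b=rng.uniform(-1, 1, 1), S=np.eye(1) * (1 + i))
              for i in range(3)]
        y = rng.uniform(-1, 1, 3)
        vals = [bl.free_energy(system, q, y) - bl.gaussian_kl(q, cond, y) for q in qs]
        assert np.allclose(vals, vals[0], atol=1e-12)


class TestGradientMaps:
    def test_constant_conditional_gives_zero_maps(self):
        system = decoupled_psi_system()
        cond = bl.posterior(system)
        q = bl.VariationalGaussian(A=np.zeros((1, 1)), b=np.zeros(1), S=cond.covariance)
        maps = kl_gradient_maps(system, q)
        assert maps.both_vanish

    def test_finite_difference_oracle(self):
        """The affine gradient maps agree with central finite differences
        of the pointwise KL."""
        cert = bl.generate_counterexample("obs5", seed=1)
        system = cert.system
        cond = bl.posterior(system)
        rng = np.random.default_rng(0)
        q = bl.VariationalGaussian(A=rng.uniform(-1, 1, (1, 1)), b=rng.uniform(-1, 1, 1),
                                   S=2.0 * np.eye(1))
        maps = kl_gradient_maps(system, q)
        h = 1e-6
        for _ in range(5):
            y = rng.uniform(-2, 2, 3)
            num = np.empty(3)
            for j in range(3):
                e = np.zeros(3); e[j] = h
                num[j] = (bl.gaussian_kl(q, cond, y + e) - bl.gaussian_kl(q, cond, y - e)) / (2 * h)
            assert np.isclose(maps.grad_a(y)[0], num[1], atol=1e-5)
            assert np.isclose(maps.grad_lambda(y)[0], num[2], atol=1e-5)

    def test_zero_gain_kills_a_and_lambda_gradients(self):
        """On the gradient-flow chain system the conditional mean depends
        only on s; with A = 0 the a- and lambda-gradients vanish but the
        s-dependence of the KL remains."""
        cert = bl.generate_counterexample("obs5", seed=0)
        q = bl.VariationalGaussian(A=np.zeros((1, 1)), b=np.zeros(1), S=np.eye(1))
        maps = kl_gradient_maps(cert.system, q)
        assert maps.both_vanish
        prof = kl_profile(cert.system, q)
        assert abs(prof.H[0, 0]) > 1e-3           # s-curvature survives
        assert np.allclose(prof.H[1:, :], 0.0, atol=1e-12)

    def test_nonzero_gain_reintroduces_lambda_gradient(self):
        cert = bl.generate_counterexample("obs5", seed=0)
        cond = bl.posterior(cert.system)
        A = np.array([[0.7]])
        q = bl.VariationalGaussian(A=A, b=np.zeros(1), S=np.eye(1))
        maps = kl_gradient_maps(cert.system, q)
        assert not maps.grad_lambda.vanishes
        # lambda-lambda curvature is A^T Sigma_c^{-1} A
        expected = (A.T @ cond.P @ A).item()
        assert np.isclose(kl_profile(cert.system, q).H[2, 2], expected, atol=1e-12)


class TestLemmaFeasibility:
    def test_decoupled_psi_is_strongest_case(self):
        """With the conditional constant, the stationary psi-marginal is
        a feasible q with identically zero KL."""
        system = decoupled_psi_system()
        rep = bl.lemma_feasibility(system, "diagonal")
        assert rep.status == "ok" and rep.feasible
        cond = bl.posterior(system)
        q = bl.VariationalGaussian(A=rep.A, b=cond.mean(np.zeros(3)), S=cond.covariance)
        prof = kl_profile(system, q)
        rng = np.random.default_rng(0)
        assert all(abs(prof(rng.uniform(-2, 2, 3))) < 1e-12 for _ in range(10))

    def test_chain_system_pins_gain_to_zero(self):
        cert = bl.generate_counterexample("obs5", seed=0)
        rep = cert.feasibility_report
        assert rep.feasible
        assert np.allclose(rep.A, 0.0, atol=1e-12)
        assert rep.solution_nullspace.shape[1] == 0   # A unique
        assert rep.S_unconstrained

    def test_active_coupling_defeats_feasibility(self):
        """When the conditional mean reads the active coordinate, no
        lambda-parameterised Gaussian mean can track it."""
        cert = bl.generate_counterexample("obs4", seed=0)
        rep = cert.feasibility_report
        assert rep.status == "ok"
        assert rep.feasible is False
        assert rep.residual > 1e-2

    def test_not_applicable_when_family_fails(self):
        cert = bl.generate_counterexample("obs2", seed=0)   # diagonal family fails
        rep = bl.lemma_feasibility(cert.system, "diagonal")
        assert rep.status == "not_applicable"

    def test_nullspaces_trivial_for_spd_diffusion(self):
        for seed in range(5):
            system, *_ = random_potential_system(
                seed, partition=bl.CoordinatePartition(1, 1, 2, 2), identity_gamma=True)
            rep = bl.lemma_feasibility(system, "marginal")
            if rep.status == "ok":
                assert rep.nullspace_dim_a == 0
                assert rep.nullspace_dim_lambda == 0

    def test_reverse_implication_constructive(self):
        """If q equals an (s,a)-independent conditional, all gradient maps
        vanish, the KL is identically zero and every applicable rewriting
        family is feasible."""
        system = lambda_tracking_system()
        cond = bl.posterior(system)
        assert np.allclose(cond.K[:, :2], 0.0, atol=1e-10)   # (s,a)-independent
        assert abs(cond.K[0, 2]) > 1e-3                      # genuinely lambda-dependent
        A = cond.K[:, 2:]     # exact lambda-gain of the conditional
        q = bl.VariationalGaussian(A=A, b=np.zeros(1), S=cond.covariance)
        assert kl_gradient_maps(system, q).both_vanish
        prof = kl_profile(system, q)
        rng = np.random.default_rng(0)
        assert all(abs(prof(rng.uniform(-2, 2, 3))) < 1e-10 for _ in range(10))
        idrep = bl.identity_residuals(system)
        applicable = [f for f in ("diagonal", "cross", "marginal") if idrep.holds(f)]
        assert "marginal" in applicable and "cross" in applicable
        for family in applicable:
            rep = bl.lemma_feasibility(system, family)
            assert rep.status == "ok" and rep.feasible
            assert np.allclose(rep.A, A, atol=1e-8)


class TestKLSupremumProbe:
    @pytest.mark.parametrize("c", [0.0, 10.0, 1e3, 1e6])
    def test_unbounded_divergence_with_vanishing_gradients(self, c):
        cert = bl.generate_counterexample("obs5", seed=0)
        rep = cert.feasibility_report
        probe = bl.kl_supremum_probe(cert.system, rep, c)
        assert probe.kl > c
        assert probe.gradients.both_vanish
        assert probe.distinct_from_posterior
        assert probe.gain_mismatch > 1e-3   # conditional mean varies with s, q's does not

    def test_probe_kl_recomputed_from_witness(self):
        cert = bl.generate_counterexample("obs5", seed=0)
        probe = bl.kl_supremum_probe(cert.system, cert.feasibility_report, 10.0)
        cond = bl.posterior(cert.system)
        assert np.isclose(probe.kl, bl.gaussian_kl(probe.q, cond, probe.point), rtol=1e-12)

    def test_infeasible_report_rejected(self):
        cert = bl.generate_counterexample("obs4", seed=0)
        with pytest.raises(bl.InfeasibleError):
            bl.kl_supremum_probe(cert.system, cert.feasibility_report, 1.0)


class TestDPI:
    def test_decoupled_internal_gives_zero_information(self):
        spec = ConstraintSpec(
            partition=bl.CoordinatePartition(1, 1, 1, 1),
            zero_U=(("lambda", "s"), ("lambda", "a"), ("lambda", "psi")),
            seed=0,
        )
        system = bl.generate_system(spec)
        rep = bl.dpi_check(system)
        assert np.isclose(rep.mi_internal_estimate, 0.0, atol=1e-10)
        assert np.isclose(rep.mi_internal_blanket, 0.0, atol=1e-10)
        assert rep.inequality_holds

    @pytest.mark.parametrize("seed", range(5))
    def test_inequality_on_generic_systems(self, seed):
        cert = bl.generate_counterexample("obs1_reverse", seed=seed)
        rep = bl.dpi_check(cert.system)
        assert 0.0 <= rep.mi_internal_estimate <= rep.mi_internal_blanket + 1e-10
        assert rep.inequality_holds

    def test_against_monte_carlo(self):
        """Closed-form Gaussian informations agree with a Monte-Carlo
        estimator within 3 standard errors."""
        cert = bl.generate_counterexample("obs1_reverse", seed=2)
        system = cert.system
        rep = bl.dpi_check(system)
        p = system.partition
        idx = p.indices(("s", "a", "lambda"))
        Csub = system.C[np.ix_(idx, idx)]
        # within the (s, a, lambda) marginal: lambda is last, (s, a) first
        est, se = mc_mutual_information(Csub, [2], [0, 1], n_samples=100_000, seed=11)
        assert abs(est - rep.mi_internal_blanket) < 3 * se
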