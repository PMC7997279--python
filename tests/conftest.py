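"""Shared fixtures and independent numerical oracles.

The oracles here (brute-force Gaussian conditioning, Gauss-Hermite
quadrature of KL integrands, Monte-Carlo mutual information) are kept
deliberately independent of the library code paths they check.
"""

import numpy as np
import pytest

from blanketlab import CoordinatePartition, LinearOUSystem, assemble_from_potential


def random_partition(rng: np.random.Generator, d: int) -> CoordinatePartition:
    """A random 4-block partition of dimension d >= 4."""
    cuts = np.sort(rng.choice(np.arange(1, d), size=3, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [d]]))
    return CoordinatePartition(*map(int, sizes))


def random_spd(rng: np.random.Generator, d: int, inflation: float | None = None) -> np.ndarray:
    X = rng.uniform(-1.0, 1.0, size=(d, d))
    S = (X + X.T) / 2.0
    S[np.diag_indices(d)] = (d if inflation is None else inflation) + rng.uniform(0, 1, d)
    return S


def random_antisymmetric(rng: np.random.Generator, d: int) -> np.ndarray:
    X = rng.uniform(-1.0, 1.0, size=(d, d))
    return (X - X.T) / 2.0


def random_block_diag_spd(rng: np.random.Generator, partition: CoordinatePartition) -> np.ndarray:
    G = np.zeros((partition.d, partition.d))
    for name, sl in partition.slices.items():
        n = sl.stop - sl.start
        A = rng.uniform(-1.0, 1.0, size=(n, n))
        G[sl, sl] = A @ A.T + n * np.eye(n)
    return G


def random_potential_system(seed: int, d: int | None = None,
                            partition: CoordinatePartition | None = None,
                            identity_gamma: bool = False):
    """A generic ergodic system built from random (U, R, Gamma)."""
    rng = np.random.default_rng(seed)
    if partition is None:
        d = d or int(rng.integers(4, 13))
        partition = random_partition(rng, d)
    U = random_spd(rng, partition.d)
    R = random_antisymmetric(rng, partition.d)
    Gamma = np.eye(partition.d) if identity_gamma else random_block_diag_spd(rng, partition)
    system = assemble_from_potential(U, R, Gamma, partition)
    return system, U, R, Gamma


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_conditional(U: np.ndarray, target_idx: np.ndarray, given_idx: np.ndarray):
    """Conditional moments of a zero-mean Gaussian via full covariance
    inversion only: returns (covariance, gain)."""
    C = np.linalg.inv(U)
    Ctt = C[np.ix_(target_idx, target_idx)]
    Ctg = C[np.ix_(target_idx, given_idx)]
    Cgg = C[np.ix_(given_idx, given_idx)]
    gain = Ctg @ np.linalg.inv(Cgg)
    return Ctt - gain @ Ctg.T, gain


def quadrature_kl_1d(mu_q, var_q, mu_p, var_p, n_nodes=80):
    """KL between 1-d Gaussians by Gauss-Hermite quadrature of q ln(q/p)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    x = mu_q + np.sqrt(var_q) * nodes
    log_q = -0.5 * ((x - mu_q) ** 2 / var_q + np.log(2 * np.pi * var_q))
    log_p = -0.5 * ((x - mu_p) ** 2 / var_p + np.log(2 * np.pi * var_p))
    return float(np.sum(weights * (log_q - log_p)) / np.sqrt(2 * np.pi))


def mc_mutual_information(cov: np.ndarray, idx_x, idx_y, n_samples: int, seed: int):
    """Monte-Carlo Gaussian mutual information I(X;Y) = E[ln p(x|y) - ln p(x)],
    with the conditional/marginal densities evaluated in closed form.
    Returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    idx_x, idx_y = np.asarray(idx_x), np.asarray(idx_y)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_samples, cov.shape[0])) @ L.T
    x, y = z[:, idx_x], z[:, idx_y]
    Sxx = cov[np.ix_(idx_x, idx_x)]
    Syy = cov[np.ix_(idx_y, idx_y)]
    Sxy = cov[np.ix_(idx_x, idx_y)]
    gain = Sxy @ np.linalg.pinv(Syy)
    cond_cov = Sxx - gain @ Sxy.T

    def logpdf(v, mean, c):
        d = v.shape[1]
        Lc = np.linalg.cholesky(c + 1e-300 * np.eye(d))
        sol = np.linalg.solve(Lc, (v - mean).T)
        return -0.5 * (d * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(Lc)))
                       + np.sum(sol ** 2, axis=0))

    ratio = logpdf(x, (gain @ y.T).T, cond_cov) - logpdf(x, 0.0 * x, Sxx)
    return float(np.mean(ratio)), float(np.std(ratio, ddof=1) / np.sqrt(n_samples))


@pytest.fixture
def part1111() -> CoordinatePartition:
    return CoordinatePartition(1, 1, 1, 1)


@pytest.fixture
def isotropic_system(part1111) -> LinearOUSystem:
    """The fully decoupled reference system: M = -I, Gamma = I."""
    return LinearOUSystem(part1111, -np.eye(4), np.eye(4))
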