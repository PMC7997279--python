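"""Exact algebra of linear Ornstein-Uhlenbeck (OU) systems.

A linear OU system

    dx/dt = M x + omega,      <omega(t) omega(t')^T> = 2 Gamma delta(t - t')

with Hurwitz drift ``M`` and symmetric positive-definite diffusion
``Gamma`` is ergodic, and its stationary density is a zero-mean Gaussian
with covariance ``C`` solving the Lyapunov equation ``M C + C M^T +
2 Gamma = 0``.  The drift admits the Helmholtz-type decomposition

    M = -(Gamma + R) U,

where ``U = C^{-1}`` is the stationary precision and ``R`` is the unique
antisymmetric *solenoidal* matrix solving the Sylvester equation
``M R + R M^T = M Gamma - Gamma M^T``.  The gradient part ``-Gamma U x``
descends the Gibbs energy ``G(x) = -ln p*(x)`` while ``-R U x``
circulates probability flux along its level sets.

The state is partitioned into four blocks, conventionally called
external (psi), sensory (s), active (a) and internal (lambda)
coordinates; every matrix in the package is addressed through that
block structure.

All residual norms in this package are spectral (2-)norms: they are
invariant under the independent-copies lift used by
:mod:`blanketlab.generalised_coordinates`, so structural verdicts
transfer exactly between a system and its lift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg

from .errors import (
    AsymmetryError,
    BlockError,
    ConsistencyError,
    NonErgodicError,
    NotSPDError,
    SolvabilityError,
)

#: block labels in fixed order: external, sensory, active, internal
BLOCKS = ("psi", "s", "a", "lambda")

#: absolute tolerance for structural-zero assertions (matrices are O(1))
TOL_STRUCTURAL = 1e-10
#: relative tolerance for cross-checks between independent routes
TOL_CROSS = 1e-8
#: a required-zero block is called *violated* only above this norm
VIOLATION_THRESHOLD = 1e-3
#: Hurwitz margin: all eigenvalue real parts must lie below -margin
HURWITZ_MARGIN = 1e-8


def specnorm(x: np.ndarray) -> float:
    """Spectral norm, with the convention ``specnorm(empty) = 0``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.size == 0:
        return 0.0
    return float(np.linalg.norm(x, 2))


def _as_square(x, name: str, d: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise BlockError(f"{name} must be a square matrix, got shape {x.shape}")
    if d is not None and x.shape[0] != d:
        raise BlockError(f"{name} must be {d}x{d}, got {x.shape[0]}x{x.shape[0]}")
    return x


def is_symmetric(x: np.ndarray, tol: float = TOL_STRUCTURAL) -> bool:
    return specnorm(x - x.T) <= tol * max(1.0, specnorm(x))


def is_antisymmetric(x: np.ndarray, tol: float = TOL_STRUCTURAL) -> bool:
    return specnorm(x + x.T) <= tol * max(1.0, specnorm(x))


def is_spd(x: np.ndarray, tol: float = TOL_STRUCTURAL) -> bool:
    if not is_symmetric(x, tol):
        return False
    return bool(np.min(np.linalg.eigvalsh((x + x.T) / 2.0)) > 0.0)


def require_spd(x: np.ndarray, name: str) -> np.ndarray:
    x = _as_square(x, name)
    if not is_symmetric(x):
        raise NotSPDError(f"{name} is not symmetric")
    if np.min(np.linalg.eigvalsh((x + x.T) / 2.0)) <= 0.0:
        raise NotSPDError(f"{name} has a non-positive eigenvalue")
    return x


def is_hurwitz(M: np.ndarray, margin: float = HURWITZ_MARGIN) -> bool:
    return bool(np.max(np.linalg.eigvals(M).real) < -margin)


@dataclass(frozen=True)
class CoordinatePartition:
    """Sizes of the (psi, s, a, lambda) blocks of the state vector.

    The block order is fixed; index ranges are contiguous, disjoint and
    cover ``0..d-1``.
    """

    n_psi: int
    n_s: int
    n_a: int
    n_lambda: int

    def __post_init__(self):
        for name in ("n_psi", "n_s", "n_a", "n_lambda"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise BlockError(f"partition size {name} must be a positive integer, got {v!r}")

    @property
    def d(self) -> int:
        return self.n_psi + self.n_s + self.n_a + self.n_lambda

    @property
    def sizes(self) -> dict[str, int]:
        return {"psi": self.n_psi, "s": self.n_s, "a": self.n_a, "lambda": self.n_lambda}

    @cached_property
    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name in BLOCKS:
            n = self.sizes[name]
            out[name] = slice(start, start + n)
            start += n
        return out

    def indices(self, blocks: Iterable[str]) -> np.ndarray:
        """Concatenated integer indices of the named blocks, in block order."""
        blocks = self._validate_blocks(blocks)
        return np.concatenate([np.arange(self.slices[b].start, self.slices[b].stop) for b in blocks])

    def _validate_blocks(self, blocks: Iterable[str]) -> tuple[str, ...]:
        blocks = tuple(blocks)
        if not blocks:
            raise BlockError("empty block set")
        for b in blocks:
            if b not in BLOCKS:
                raise BlockError(f"unknown block label {b!r}; expected one of {BLOCKS}")
        if len(set(blocks)) != len(blocks):
            raise BlockError(f"repeated block label in {blocks}")
        # keep canonical order
        return tuple(b for b in BLOCKS if b in blocks)

    def to_dict(self) -> dict[str, int]:
        return {"psi": self.n_psi, "s": self.n_s, "a": self.n_a, "lambda": self.n_lambda}

    @classmethod
    def from_dict(cls, data: Mapping[str, int]) -> "CoordinatePartition":
        return cls(int(data["psi"]), int(data["s"]), int(data["a"]), int(data["lambda"]))


class BlockView:
    """Addresses the 16 sub-matrices ``X_ab`` of a d x d matrix by block label.

    ``view["a", "psi"]`` is the sub-matrix coupling psi-gradients to the
    time derivative of the active coordinates, etc.  Assembling all 16
    blocks reproduces the matrix exactly (it is a plain slicing view).
    """

    def __init__(self, matrix: np.ndarray, partition: CoordinatePartition):
        self.matrix = _as_square(matrix, "matrix", partition.d)
        self.partition = partition

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        row, col = key
        sl = self.partition.slices
        if row not in BLOCKS or col not in BLOCKS:
            raise BlockError(f"unknown block pair {key!r}")
        return self.matrix[sl[row], sl[col]]

    def __setitem__(self, key: tuple[str, str], value) -> None:
        row, col = key
        sl = self.partition.slices
        if row not in BLOCKS or col not in BLOCKS:
            raise BlockError(f"unknown block pair {key!r}")
        self.matrix[sl[row], sl[col]] = value

    def rows(self, blocks: Sequence[str]) -> np.ndarray:
        return self.matrix[self.partition.indices(blocks), :]

    def submatrix(self, row_blocks: Sequence[str], col_blocks: Sequence[str]) -> np.ndarray:
        ri = self.partition.indices(row_blocks)
        ci = self.partition.indices(col_blocks)
        return self.matrix[np.ix_(ri, ci)]


def block(matrix: np.ndarray, partition: CoordinatePartition, row: str, col: str) -> np.ndarray:
    """Convenience accessor for a single block of ``matrix``."""
    return BlockView(matrix, partition)[row, col]


def is_block_diagonal(matrix: np.ndarray, partition: CoordinatePartition,
                      tol: float = TOL_STRUCTURAL) -> bool:
    view = BlockView(matrix, partition)
    return all(
        specnorm(view[r, c]) <= tol
        for r in BLOCKS for c in BLOCKS if r != c
    )


@dataclass
class SolenoidalMatrix:
    """Antisymmetric matrix of the flux-circulating part of the drift."""

    R: np.ndarray

    def __post_init__(self):
        self.R = _as_square(self.R, "R")
        if not is_antisymmetric(self.R):
            raise AsymmetryError("R is not antisymmetric")

    def check(self, M: np.ndarray, Gamma: np.ndarray, tol: float = TOL_CROSS) -> float:
        """Residual of the defining Sylvester relation, relative to its scale."""
        lhs = M @ self.R + self.R @ M.T
        rhs = M @ Gamma - Gamma @ M.T
        return specnorm(lhs - rhs) / max(1.0, specnorm(rhs))


@dataclass
class StationaryGaussian:
    """Zero-mean Gaussian stationary density, held as precision U and covariance C."""

    U: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.U = require_spd(self.U, "U")
        self.C = require_spd(self.C, "C")
        d = self.U.shape[0]
        if specnorm(self.U @ self.C - np.eye(d)) > 1e-6 * max(1.0, specnorm(self.U) * specnorm(self.C)):
            raise ConsistencyError("U and C are not inverses of each other")

    @property
    def d(self) -> int:
        return self.U.shape[0]

    def log_normaliser(self) -> float:
        """ln Z such that p*(x) = exp(-x^T U x / 2) / Z."""
        sign, logdet = np.linalg.slogdet(self.U)
        return 0.5 * (self.d * np.log(2.0 * np.pi) - logdet)

    def gibbs_energy(self, x: np.ndarray) -> float:
        """G(x) = -ln p*(x) = x^T U x / 2 + ln Z."""
        x = np.asarray(x, dtype=float).ravel()
        return float(0.5 * x @ self.U @ x + self.log_normaliser())

    def log_density(self, x: np.ndarray) -> float:
        return -self.gibbs_energy(x)


@dataclass
class GaussianConditional:
    """Conditional of a zero-mean Gaussian: target blocks given other blocks.

    The conditional is Gaussian with precision ``P`` and mean
    ``K @ y`` where ``y`` stacks the given coordinates in block order.
    """

    target: tuple[str, ...]
    given: tuple[str, ...]
    P: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        self.P = require_spd(self.P, "conditional precision")

    @cached_property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.P)

    def mean(self, y: np.ndarray) -> np.ndarray:
        return self.K @ np.asarray(y, dtype=float).ravel()


@dataclass
class LinearOUSystem:
    """A linear OU system: partition plus drift M and diffusion Gamma.

    Invariants checked on construction: M Hurwitz, Gamma SPD and
    block-diagonal with respect to the partition.  The solenoidal matrix
    and the stationary density are derived lazily and cached.
    """

    partition: CoordinatePartition
    M: np.ndarray
    Gamma: np.ndarray
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        d = self.partition.d
        self.M = _as_square(self.M, "M", d)
        self.Gamma = _as_square(self.Gamma, "Gamma", d)
        if self._validate:
            if not is_hurwitz(self.M):
                raise NonErgodicError("drift matrix M is not Hurwitz (system not ergodic)")
            require_spd(self.Gamma, "Gamma")
            if not is_block_diagonal(self.Gamma, self.partition):
                raise NotSPDError("Gamma must be block-diagonal over the partition")

    @property
    def d(self) -> int:
        return self.partition.d

    @cached_property
    def R(self) -> np.ndarray:
        return solve_solenoidal(self.M, self.Gamma).R

    @cached_property
    def stationary(self) -> StationaryGaussian:
        return stationary_precision(self.M, self.Gamma, self.R)

    @property
    def U(self) -> np.ndarray:
        return self.stationary.U

    @property
    def C(self) -> np.ndarray:
        return self.stationary.C

    def blocks(self, matrix: np.ndarray) -> BlockView:
        return BlockView(matrix, self.partition)

    def drift(self, x: np.ndarray) -> np.ndarray:
        return self.M @ np.asarray(x, dtype=float).ravel()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def solve_solenoidal(M: np.ndarray, Gamma: np.ndarray) -> SolenoidalMatrix:
    """Solve ``M R + R M^T = M Gamma - Gamma M^T`` for the solenoidal matrix R.

    The right-hand side is antisymmetric and, for Hurwitz ``M``, the
    Sylvester operator is invertible, so the solution exists, is unique
    and is antisymmetric (``-R^T`` solves the same equation).

    Raises
    ------
    SolvabilityError
        If some eigenvalue pair of ``M`` satisfies lambda_i + lambda_j = 0
        (impossible for Hurwitz M, but guarded for arbitrary input).
    """
    M = _as_square(M, "M")
    Gamma = _as_square(Gamma, "Gamma", M.shape[0])
    eig = np.linalg.eigvals(M)
    pair_sums = eig[:, None] + eig[None, :]
    scale = max(1.0, float(np.max(np.abs(eig))))
    if np.min(np.abs(pair_sums)) < 1e-10 * scale:
        raise SolvabilityError(
            "M and -M^T share an eigenvalue (lambda_i + lambda_j = 0); "
            "the solenoidal Sylvester equation is singular"
        )
    rhs = M @ Gamma - Gamma @ M.T
    if specnorm(rhs) == 0.0:
        R = np.zeros_like(M)
    else:
        # A X + X B = Q with A = M, B = M^T
        R = linalg.solve_sylvester(M, M.T, rhs)
        # symmetrise away roundoff: the exact solution is antisymmetric
        R = (R - R.T) / 2.0
    return SolenoidalMatrix(R)


def lyapunov_covariance(M: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """Stationary covariance: the SPD solution of ``M C + C M^T + 2 Gamma = 0``."""
    M = _as_square(M, "M")
    Gamma = _as_square(Gamma, "Gamma", M.shape[0])
    if not is_hurwitz(M):
        raise NonErgodicError("drift matrix M is not Hurwitz; no stationary covariance")
    C = linalg.solve_continuous_lyapunov(M, -2.0 * Gamma)
    C = (C + C.T) / 2.0
    return require_spd(C, "stationary covariance C")


def stationary_precision(M: np.ndarray, Gamma: np.ndarray,
                         R: np.ndarray | SolenoidalMatrix,
                         tol: float = TOL_CROSS) -> StationaryGaussian:
    """Stationary density via ``U = -(Gamma + R)^{-1} M``, cross-checked
    against the inverse of the Lyapunov covariance.

    The agreement of the two routes (within relative tolerance ``tol``)
    pins the noise convention: autocovariance ``2 Gamma delta(t-t')``.
    """
    if isinstance(R, SolenoidalMatrix):
        R = R.R
    M = _as_square(M, "M")
    d = M.shape[0]
    R = _as_square(R, "R", d)
    Gamma = _as_square(Gamma, "Gamma", d)
    U = -np.linalg.solve(Gamma + R, M)
    U = (U + U.T) / 2.0
    if np.min(np.linalg.eigvalsh(U)) <= 0.0:
        raise NotSPDError("stationary precision U has a non-positive eigenvalue")
    C = lyapunov_covariance(M, Gamma)
    rel = specnorm(np.linalg.inv(U) - C) / specnorm(C)
    if rel > tol:
        raise ConsistencyError(
            f"precision route and Lyapunov route disagree (relative error {rel:.3e})"
        )
    return StationaryGaussian(U=U, C=C)


def assemble_from_potential(U: np.ndarray, R: np.ndarray, Gamma: np.ndarray,
                            partition: CoordinatePartition | None = None) -> np.ndarray | LinearOUSystem:
    """Build the drift ``M = -(Gamma + R) U`` from a stationary precision,
    a solenoidal matrix and a diffusion matrix.

    The result is automatically Hurwitz (it is similar to
    ``-U^{1/2}(Gamma+R)U^{1/2}``, whose symmetric part is negative
    definite) and satisfies the solenoidal Sylvester relation and the
    stationary-precision relation by construction.

    Returns the drift matrix, or a full :class:`LinearOUSystem` when a
    partition is supplied.
    """
    U = require_spd(U, "U")
    d = U.shape[0]
    R = _as_square(R, "R", d)
    if not is_antisymmetric(R):
        raise AsymmetryError("R is not antisymmetric")
    Gamma = require_spd(_as_square(Gamma, "Gamma", d), "Gamma")
    M = -(Gamma + R) @ U
    if partition is None:
        return M
    return LinearOUSystem(partition=partition, M=M, Gamma=Gamma)


def conditional_gaussian(U: np.ndarray, partition: CoordinatePartition,
                         target: Sequence[str] | str,
                         given: Sequence[str] | str) -> GaussianConditional:
    """Conditional of the zero-mean Gaussian with precision ``U``.

    For target t and given g covering all blocks the conditional
    precision is the sub-block ``U_tt`` and the mean gain is
    ``-U_tt^{-1} U_tg``; when some blocks are neither target nor given
    they are marginalised out first (covariance route).
    """
    if isinstance(target, str):
        target = (target,)
    if isinstance(given, str):
        given = (given,)
    target = partition._validate_blocks(target)
    given = partition._validate_blocks(given) if given else ()
    if set(target) & set(given):
        raise BlockError(f"target {target} and given {given} overlap")
    U = require_spd(_as_square(U, "U", partition.d), "U")
    ti = partition.indices(target)
    gi = partition.indices(given)
    if len(ti) + len(gi) == partition.d:
        P = U[np.ix_(ti, ti)]
        K = -np.linalg.solve(P, U[np.ix_(ti, gi)])
    else:
        # marginalise out the remaining blocks, then condition
        C = np.linalg.inv(U)
        Ctt = C[np.ix_(ti, ti)]
        Ctg = C[np.ix_(ti, gi)]
        Cgg = C[np.ix_(gi, gi)]
        K = np.linalg.solve(Cgg.T, Ctg.T).T
        Sigma = Ctt - K @ Ctg.T
        P = np.linalg.inv((Sigma + Sigma.T) / 2.0)
    return GaussianConditional(target=target, given=given, P=(P + P.T) / 2.0, K=K)


def marginal_precision(C: np.ndarray, partition: CoordinatePartition,
                       blocks: Sequence[str] | str) -> np.ndarray:
    """Precision of the marginal over ``blocks``: inverse of the
    restricted covariance (equals the Schur complement of the precision)."""
    if isinstance(blocks, str):
        blocks = (blocks,)
    blocks = partition._validate_blocks(blocks)
    C = _as_square(C, "C", partition.d)
    bi = partition.indices(blocks)
    V = np.linalg.inv(C[np.ix_(bi, bi)])
    return (V + V.T) / 2.0
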