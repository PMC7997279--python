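"""Lifting a system to independent copies ("generalised coordinates").

The generalised-coordinate formulation of the criticised argument
replaces the state x by an extended state (x, x', x'', ...).  The
construction implemented here realises the extended state as ``n``
statistically independent copies of the base system, reordered so that
each partition block of the lift stacks the corresponding blocks of all
copies: every matrix lifts block-wise as ``X_ab -> I_n (x) X_ab``
(Kronecker product).

Independence of the copies makes preservation exact: the lifted drift
has the base spectrum with multiplicity n (so ergodicity is preserved),
the lifted solenoidal and precision matrices are the lifts of the base
ones, and every block-zero pattern, flow-identity residual and
feasibility verdict of the base system transfers to the lift unchanged
— residuals are *equal* because the package measures them in the
spectral norm, which is invariant under ``I_n (x) .``.  Counterexamples
to the free-energy lemma therefore transport verbatim into generalised
coordinates.

The construction uses a finite order n; all stated properties are
per-copy, so preservation for every finite n is the computationally
meaningful content of the infinite-copies construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .linsys_core import BLOCKS, BlockView, CoordinatePartition, LinearOUSystem


def lift_partition(partition: CoordinatePartition, n: int) -> CoordinatePartition:
    return CoordinatePartition(n * partition.n_psi, n * partition.n_s,
                               n * partition.n_a, n * partition.n_lambda)


def lift_matrix(X: np.ndarray, partition: CoordinatePartition, n: int) -> np.ndarray:
    """Block-wise Kronecker lift: each partition block X_ab becomes I_n (x) X_ab.

    Equivalent to n diagonal copies of X with coordinates reordered
    partition-major, so block accessors work unchanged on the lift.
    """
    if n < 1:
        raise ValueError(f"order n must be >= 1, got {n}")
    lifted_p = lift_partition(partition, n)
    out = np.zeros((lifted_p.d, lifted_p.d))
    src = BlockView(np.asarray(X, dtype=float), partition)
    dst = BlockView(out, lifted_p)
    eye = np.eye(n)
    for r in BLOCKS:
        for c in BLOCKS:
            dst[r, c] = np.kron(eye, src[r, c])
    return out


@dataclass
class GeneralisedSystem:
    """A base system together with its order-n independent-copies lift."""

    base: LinearOUSystem
    order: int
    system: LinearOUSystem

    @property
    def partition(self) -> CoordinatePartition:
        return self.system.partition

    @cached_property
    def U(self) -> np.ndarray:
        return self.system.U

    @cached_property
    def R(self) -> np.ndarray:
        return self.system.R


def lift_generalised(system: LinearOUSystem, n: int) -> GeneralisedSystem:
    """Lift a system to n independent copies, preserving all structure.

    The lifted drift and diffusion are the block-Kronecker lifts of the
    base ones; the lifted solenoidal matrix and stationary precision
    (computed from scratch on the lift) coincide with the lifts of the
    base R and U by uniqueness of the Sylvester/Lyapunov solutions.
    """
    lifted = LinearOUSystem(
        partition=lift_partition(system.partition, n),
        M=lift_matrix(system.M, system.partition, n),
        Gamma=lift_matrix(system.Gamma, system.partition, n),
    )
    return GeneralisedSystem(base=system, order=n, system=lifted)
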