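"""Markov-blanket conditions as block-zero patterns, and the chain structure.

Three non-equivalent formalisations of "having a Markov blanket"
circulate in the free-energy-principle literature; for linear OU
systems each is exactly a zero pattern on one matrix:

* condition 1 — the drift field has blanket-shaped *dependencies*:
  the psi-rows of f do not read lambda, the (a, lambda)-rows do not
  read psi, and the s-rows do not read lambda, i.e.
  ``M_a,psi = M_lambda,psi = M_s,lambda = M_psi,lambda = 0``;
* condition 2 — the stationary density renders internal and external
  coordinates conditionally independent given the blanket, i.e.
  ``U_psi,lambda = 0`` on the precision matrix (exact for Gaussians);
* condition 3 — the solenoidal matrix does not couple the blanket to
  psi or lambda, nor psi to lambda:
  ``R_psi,s = R_psi,a = R_psi,lambda = R_s,lambda = R_a,lambda = 0``
  (antisymmetric partners implied).

A condition is *satisfied* when every required-zero block has spectral
norm below a strict tolerance, and *violated* only when some block
exceeds a much larger threshold; the wide gap keeps boolean verdicts
robust against floating-point noise, and the generators resample any
draw landing in the ambiguous band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import MissingMatrixError
from .linsys_core import (
    BLOCKS,
    BlockView,
    CoordinatePartition,
    LinearOUSystem,
    TOL_STRUCTURAL,
    VIOLATION_THRESHOLD,
    is_block_diagonal,
    specnorm,
)

#: required-zero block lists per condition: (matrix name, row, col)
CONDITION_BLOCKS: dict[int, tuple[tuple[str, str, str], ...]] = {
    1: (
        ("M", "a", "psi"),
        ("M", "lambda", "psi"),
        ("M", "s", "lambda"),
        ("M", "psi", "lambda"),
    ),
    2: (
        ("U", "psi", "lambda"),
        ("U", "lambda", "psi"),
    ),
    3: (
        ("R", "psi", "s"),
        ("R", "psi", "a"),
        ("R", "psi", "lambda"),
        ("R", "s", "lambda"),
        ("R", "a", "lambda"),
        # antisymmetric partners
        ("R", "s", "psi"),
        ("R", "a", "psi"),
        ("R", "lambda", "psi"),
        ("R", "lambda", "s"),
        ("R", "lambda", "a"),
    ),
}


@dataclass
class ConditionReport:
    """Verdict for one blanket condition, with per-block residual norms."""

    condition_id: int
    satisfied: bool
    residuals: dict[str, float]
    tol: float
    violation_threshold: float = VIOLATION_THRESHOLD

    @property
    def violated(self) -> bool:
        """True when some required-zero block is well above the noise band."""
        return any(r > self.violation_threshold for r in self.residuals.values())

    @property
    def ambiguous(self) -> bool:
        return (not self.satisfied) and (not self.violated)

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values())

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_id,
            "satisfied": bool(self.satisfied),
            "violated": bool(self.violated),
            "residuals": {k: float(v) for k, v in self.residuals.items()},
            "tol": float(self.tol),
            "violation_threshold": float(self.violation_threshold),
        }


def _matrices_of(system) -> tuple[CoordinatePartition, dict[str, np.ndarray]]:
    """Accept a LinearOUSystem or a mapping with 'partition' and matrices."""
    if isinstance(system, LinearOUSystem):
        return system.partition, {"M": system.M, "U": system.U, "R": system.R,
                                  "Gamma": system.Gamma}
    if isinstance(system, Mapping):
        part = system.get("partition")
        if not isinstance(part, CoordinatePartition):
            part = CoordinatePartition.from_dict(part)
        mats = {k: np.asarray(system[k], dtype=float)
                for k in ("M", "U", "R", "Gamma") if system.get(k) is not None}
        return part, mats
    raise TypeError(f"expected LinearOUSystem or mapping, got {type(system)!r}")


def check_condition(system, condition_id: int, tol: float = TOL_STRUCTURAL) -> ConditionReport:
    """Decide one blanket condition from the relevant matrix's block-zero pattern.

    Condition 1 needs the drift M, condition 2 the stationary precision
    U, condition 3 the solenoidal matrix R; a :class:`LinearOUSystem`
    supplies all three, a mapping must carry the needed one.
    """
    if condition_id not in CONDITION_BLOCKS:
        raise ValueError(f"condition_id must be 1, 2 or 3, got {condition_id}")
    partition, mats = _matrices_of(system)
    residuals: dict[str, float] = {}
    for mat_name, row, col in CONDITION_BLOCKS[condition_id]:
        if mat_name not in mats:
            raise MissingMatrixError(
                f"condition {condition_id} needs matrix {mat_name}, not present in input"
            )
        view = BlockView(mats[mat_name], partition)
        residuals[f"{mat_name}[{row},{col}]"] = specnorm(view[row, col])
    satisfied = all(r < tol for r in residuals.values())
    return ConditionReport(condition_id=condition_id, satisfied=satisfied,
                           residuals=residuals, tol=tol)


def drift_transpose_residual(M: np.ndarray, Gamma: np.ndarray, R: np.ndarray
                             ) -> tuple[float, bool]:
    """Relative residual of the transpose identity
    ``M = (Gamma + R) M^T (Gamma - R)^{-1}``.

    The identity is an algebraic consequence of the solenoidal Sylvester
    relation, so it holds for every system assembled from (U, R, Gamma).
    Returns ``(residual, used_pseudoinverse)``; the pseudoinverse branch
    is only reachable when ``Gamma - R`` is singular.
    """
    A = Gamma - R
    used_pinv = False
    try:
        inv = np.linalg.inv(A)
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(A)
        used_pinv = True
    M_rec = (Gamma + R) @ M.T @ inv
    return specnorm(M - M_rec) / max(1.0, specnorm(M)), used_pinv


@dataclass
class ChainReport:
    """Result of the chain-structure check for blanket systems with
    fully block-diagonal solenoidal coupling."""

    status: str                                # "ok" | "not_applicable"
    failing_precondition: str | None = None
    residual_M_lambda_s: float | None = None
    residual_M_psi_a: float | None = None
    transpose_identity_residual: float | None = None
    used_pseudoinverse: bool = False
    chain_pattern_residuals: dict[str, float] = field(default_factory=dict)
    tol: float = 1e-8

    @property
    def chain_holds(self) -> bool:
        if self.status != "ok":
            return False
        return (self.residual_M_lambda_s < self.tol
                and self.residual_M_psi_a < self.tol)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "failing_precondition": self.failing_precondition,
            "residual_M_lambda_s": self.residual_M_lambda_s,
            "residual_M_psi_a": self.residual_M_psi_a,
            "transpose_identity_residual": self.transpose_identity_residual,
            "used_pseudoinverse": self.used_pseudoinverse,
            "chain_pattern_residuals": self.chain_pattern_residuals,
            "chain_holds": self.chain_holds,
            "tol": self.tol,
        }


def verify_chain_implication(system: LinearOUSystem, tol: float = 1e-8) -> ChainReport:
    """Verify that blanket drift dependencies plus block-diagonal
    solenoidal coupling force a chain interaction structure.

    When the drift has the blanket dependency pattern (condition 1) and
    the solenoidal matrix is *fully* block-diagonal — condition 3 plus a
    vanishing sensory-active coupling ``R_s,a`` — the transpose identity
    ``M = (Gamma+R) M^T (Gamma-R)^{-1}`` applies block-by-block and
    forces ``M_lambda,s = M_psi,a = 0``: internal coordinates cannot be
    driven by sensory ones, nor external by active ones, so the four
    blocks interact in a chain psi - s - a - lambda.

    The sensory-active coupling must vanish for the blockwise transpose
    argument to go through (a nonzero ``R_s,a`` re-introduces a
    lambda-to-s drift coupling through the inverse); systems where it
    does not get a ``not_applicable`` verdict naming that precondition.
    """
    cond1 = check_condition(system, 1)
    if not cond1.satisfied:
        return ChainReport(status="not_applicable", failing_precondition="condition_1", tol=tol)
    cond3 = check_condition(system, 3)
    if not cond3.satisfied:
        return ChainReport(status="not_applicable", failing_precondition="condition_3", tol=tol)
    if not is_block_diagonal(system.Gamma, system.partition):
        return ChainReport(status="not_applicable",
                           failing_precondition="Gamma_block_diagonal", tol=tol)
    Rv = system.blocks(system.R)
    if specnorm(Rv["s", "a"]) > TOL_STRUCTURAL:
        return ChainReport(status="not_applicable",
                           failing_precondition="R_sa_zero", tol=tol)

    Mv = system.blocks(system.M)
    res_ls = specnorm(Mv["lambda", "s"])
    res_pa = specnorm(Mv["psi", "a"])
    ident, used_pinv = drift_transpose_residual(system.M, system.Gamma, system.R)
    # full target pattern: f_psi(psi,s), f_s(psi,s,a), f_a(s,a,lambda), f_lambda(a,lambda)
    pattern = {
        "M[psi,a]": res_pa,
        "M[psi,lambda]": specnorm(Mv["psi", "lambda"]),
        "M[s,lambda]": specnorm(Mv["s", "lambda"]),
        "M[a,psi]": specnorm(Mv["a", "psi"]),
        "M[lambda,psi]": specnorm(Mv["lambda", "psi"]),
        "M[lambda,s]": res_ls,
    }
    return ChainReport(status="ok", residual_M_lambda_s=res_ls, residual_M_psi_a=res_pa,
                       transpose_identity_residual=ident, used_pseudoinverse=used_pinv,
                       chain_pattern_residuals=pattern, tol=tol)
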