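"""Which rewritings of the active/internal flow hold, as exact matrix identities.

For a linear OU system the active and internal rows of the drift,
``f_a`` and ``f_lambda``, are linear maps of the state, so every
proposed rewriting of them in terms of (partial) gradients of the
stationary log-density is an equality of *coefficient matrices* of
linear maps.  Checking identities at that level is exact and
basis-independent — no sampling of points is involved.

Four families of rewritings are checked, from most to least general:

* ``full_state`` — f_a, f_lambda written through the gradient of the
  joint log-density with all solenoidal couplings kept; this is a row
  selection of the drift decomposition M = -(Gamma+R)U and holds for
  every system.
* ``marginal`` — the same, but through the gradient of the *marginal*
  log-density over (s, a, lambda).  The psi-gradient term drops because
  the marginal does not depend on psi; the remaining terms survive the
  conditional expectation exactly (a Gaussian identity).  Holds
  whenever the drift has the blanket dependency pattern (condition 1),
  which is what makes f_a, f_lambda functions of (s, a, lambda) only.
* ``cross`` — keeps the diagonal blocks plus the active-internal
  solenoidal cross terms R_a,lambda / R_lambda,a but silently drops the
  sensory couplings R_a,s, R_lambda,s.
* ``diagonal`` — keeps only (Gamma+R)_aa and (Gamma+R)_lambda,lambda.

Because the marginal precision V is invertible, ``diagonal`` holds iff
R_a,s = R_a,lambda = R_lambda,s = R_lambda,a = 0 and ``cross`` holds
iff R_a,s = R_lambda,s = 0; generic solenoidal coupling therefore
defeats both reductions even when conditions 1 and 2 hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotApplicableError
from .blanket_conditions import check_condition
from .linsys_core import (
    BlockView,
    LinearOUSystem,
    TOL_STRUCTURAL,
    VIOLATION_THRESHOLD,
    marginal_precision,
    specnorm,
)

#: identity families, ordered from most general to most restrictive
FAMILIES = ("full_state", "marginal", "cross", "diagonal")

#: families whose right-hand side lives on the marginal over (s, a, lambda)
MARGINAL_FAMILIES = ("marginal", "cross", "diagonal")


def family_weighting(system: LinearOUSystem, family: str) -> np.ndarray:
    """Coefficient matrix W of the gradient weighting of one family.

    W maps the (s, a, lambda) gradient of the marginal log-density to
    (f_a, f_lambda); rows are (a, lambda), columns (s, a, lambda).
    """
    if family not in MARGINAL_FAMILIES:
        raise ValueError(f"no marginal weighting for family {family!r}")
    p = system.partition
    G = BlockView(system.Gamma, p)
    R = BlockView(system.R, p)
    z = np.zeros
    if family == "marginal":
        row_a = [R["a", "s"], G["a", "a"] + R["a", "a"], R["a", "lambda"]]
        row_l = [R["lambda", "s"], R["lambda", "a"], G["lambda", "lambda"] + R["lambda", "lambda"]]
    elif family == "cross":
        row_a = [z((p.n_a, p.n_s)), G["a", "a"] + R["a", "a"], R["a", "lambda"]]
        row_l = [z((p.n_lambda, p.n_s)), R["lambda", "a"], G["lambda", "lambda"] + R["lambda", "lambda"]]
    else:  # diagonal
        row_a = [z((p.n_a, p.n_s)), G["a", "a"] + R["a", "a"], z((p.n_a, p.n_lambda))]
        row_l = [z((p.n_lambda, p.n_s)), z((p.n_lambda, p.n_a)),
                 G["lambda", "lambda"] + R["lambda", "lambda"]]
    return np.block([row_a, row_l])


def flow_coefficients(system: LinearOUSystem, family: str) -> tuple[np.ndarray, np.ndarray]:
    """Left and right coefficient matrices of one rewriting family.

    For ``full_state`` both sides are maps of the full state x; for the
    marginal families they are maps of (s, a, lambda), which requires
    the blanket drift pattern (condition 1) — otherwise f_a, f_lambda
    are not functions of (s, a, lambda) alone and the marginalisation
    step is invalid (NotApplicableError).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    p = system.partition
    Mv = BlockView(system.M, p)
    if family == "full_state":
        left = Mv.rows(("a", "lambda"))
        right = -(np.vstack([
            BlockView(system.Gamma + system.R, p).rows(("a", "lambda"))
        ]) @ system.U)
        return left, right
    cond1 = check_condition(system, 1)
    if not cond1.satisfied:
        raise NotApplicableError(
            "condition_1",
            "marginal-family identities need the blanket drift pattern "
            "(f_a, f_lambda must be functions of (s, a, lambda) only)",
        )
    left = Mv.submatrix(("a", "lambda"), ("s", "a", "lambda"))
    V = marginal_precision(system.C, p, ("s", "a", "lambda"))
    W = family_weighting(system, family)
    right = -W @ V
    return left, right


@dataclass
class FamilyVerdict:
    residual: float | None
    verdict: str  # "holds" | "fails" | "ambiguous" | "not_applicable"

    def to_dict(self) -> dict:
        return {"residual": self.residual, "verdict": self.verdict}


@dataclass
class IdentityResidualReport:
    """Per-family residual norms and verdicts for one system."""

    families: dict[str, FamilyVerdict]
    tol: float
    violation_threshold: float = VIOLATION_THRESHOLD

    def holds(self, family: str) -> bool:
        return self.families[family].verdict == "holds"

    def fails(self, family: str) -> bool:
        return self.families[family].verdict == "fails"

    def to_dict(self) -> dict:
        return {
            "tol": self.tol,
            "violation_threshold": self.violation_threshold,
            "families": {k: v.to_dict() for k, v in self.families.items()},
        }


def identity_residuals(system: LinearOUSystem, tol: float = TOL_STRUCTURAL
                       ) -> IdentityResidualReport:
    """Aggregate residuals of all rewriting families for one system."""
    out: dict[str, FamilyVerdict] = {}
    for family in FAMILIES:
        try:
            left, right = flow_coefficients(system, family)
        except NotApplicableError:
            out[family] = FamilyVerdict(residual=None, verdict="not_applicable")
            continue
        res = specnorm(left - right)
        if res < tol:
            verdict = "holds"
        elif res > VIOLATION_THRESHOLD:
            verdict = "fails"
        else:
            verdict = "ambiguous"
        out[family] = FamilyVerdict(residual=res, verdict=verdict)
    return IdentityResidualReport(families=out, tol=tol)
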