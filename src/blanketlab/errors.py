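"""Exception hierarchy for blanketlab.

Every error raised by the library derives from :class:`BlanketLabError`,
so callers can catch the whole family with one clause.  The leaf classes
mirror the distinct failure modes of the linear-system algebra (solver
degeneracy, lost ergodicity, broken matrix invariants) and of the I/O
layer (schema and dimension mismatches).
"""


class BlanketLabError(Exception):
    """Base class for all blanketlab errors."""


class SolvabilityError(BlanketLabError):
    """The Sylvester equation for the solenoidal matrix is singular
    (some eigenvalue pair of the drift satisfies lambda_i + lambda_j = 0)."""


class NonErgodicError(BlanketLabError):
    """The drift matrix is not Hurwitz, so no stationary density exists."""


class ConsistencyError(BlanketLabError):
    """Two independent routes to the same quantity disagree beyond tolerance."""


class NotSPDError(BlanketLabError):
    """A matrix required to be symmetric positive definite is not."""


class AsymmetryError(BlanketLabError):
    """A matrix required to be antisymmetric is not."""


class BlockError(BlanketLabError):
    """Invalid block selection (unknown label, empty or overlapping sets)."""


class MissingMatrixError(BlanketLabError):
    """A check needs a matrix (M, U or R) that the input does not carry."""


class GenerationError(BlanketLabError):
    """The constrained random-system generator exhausted its attempts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StabilityError(BlanketLabError):
    """The integration step violates the stability guard, or the
    trajectory overflowed."""


class DimensionError(BlanketLabError):
    """Array dimensions are inconsistent with the declared partition."""


class SchemaError(BlanketLabError):
    """A system or report file does not follow the JSON schema."""


class InvariantError(BlanketLabError):
    """A loaded system violates a structural invariant (names the field)."""


class InfeasibleError(BlanketLabError):
    """A witness was requested from an infeasible feasibility report."""


class NotApplicableError(BlanketLabError):
    """A check's precondition fails; carries the name of the failing one."""

    def __init__(self, precondition, message=None):
        super().__init__(message or f"precondition not met: {precondition}")
        self.precondition = precondition
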