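"""Gaussian analysis of the variational free-energy lemma.

The lemma under scrutiny asserts that for a blanket system there is a
variational density q(Psi | lambda) over the external coordinates,
parameterised by the internal coordinates *only*, such that the active
and internal flows descend the free energy

    F(s, a, lambda) = -ln p*(s, a, lambda)
                      + KL[ q(Psi|lambda) || p*(Psi | s, a, lambda) ].

Within the Gaussian-linear family — q(Psi|lambda) normal with mean
``A lambda + b`` and constant SPD covariance ``S``, which is exhaustive
for matching a Gaussian conditional — everything is closed form.  With
``K`` the gain of the conditional mean (mu_c = K y over the blanket
state y = (s, a, lambda)) and ``Delta = K - [0 | 0 | A]``, the KL
divergence is the quadratic profile

    D(y) = 1/2 (Delta y - b)^T U_pp (Delta y - b)
           + 1/2 [ tr(U_pp S) - n_psi - ln det(U_pp S) ],

where ``U_pp`` is the conditional precision of psi.  The free-energy
rewriting of a flow family with gradient weighting W requires
``W grad_y D == 0`` identically; since the Hessian of D is
``Delta^T U_pp Delta`` with U_pp SPD, that is *equivalent* to the
linear constraint ``Delta W^T = 0`` on the mean gain A.  Feasibility of
the lemma in the Gaussian-linear family is therefore a linear
least-squares problem, and three structural facts fall out:

* the covariance S is never constrained — it enters D only through
  point-independent terms — so any feasible q can be made arbitrarily
  far from the conditional (unbounded KL) without disturbing the
  vanishing gradients;
* the offset b is never constrained either (it shifts D by a constant);
* infeasibility is a property of the system alone: it occurs exactly
  when the conditional mean of psi depends on coordinates the
  weighting cannot reach (e.g. on a, for the diagonal family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .errors import InfeasibleError, NotApplicableError, NotSPDError
from .flow_identities import MARGINAL_FAMILIES, family_weighting, identity_residuals
from .linsys_core import (
    CoordinatePartition,
    GaussianConditional,
    LinearOUSystem,
    conditional_gaussian,
    marginal_precision,
    require_spd,
    specnorm,
)

#: every affine coefficient of a gradient map below this means "vanishes identically"
VANISH_TOL = 1e-10
#: scale-normalised least-squares residual above this means "infeasible"
INFEASIBLE_THRESHOLD = 1e-2
#: residual below this means "feasible"
FEASIBLE_TOL = 1e-8


@dataclass
class VariationalGaussian:
    """q(Psi | lambda): Gaussian with mean ``A lambda + b`` and covariance S.

    Structurally independent of (s, a) — the mean reads only the
    internal coordinates, the covariance is constant.
    """

    A: np.ndarray
    b: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.S = require_spd(np.atleast_2d(np.asarray(self.S, dtype=float)), "S")
        n_psi = self.S.shape[0]
        if self.A.shape[0] != n_psi or self.b.shape[0] != n_psi:
            raise NotSPDError(
                f"inconsistent shapes: A {self.A.shape}, b {self.b.shape}, S {self.S.shape}"
            )

    @property
    def n_psi(self) -> int:
        return self.S.shape[0]

    @property
    def n_lambda(self) -> int:
        return self.A.shape[1]

    def mean(self, lam: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(lam, dtype=float).ravel() + self.b


def posterior(system: LinearOUSystem) -> GaussianConditional:
    """The conditional p*(Psi | s, a, lambda) of the stationary density."""
    return conditional_gaussian(system.U, system.partition,
                                target=("psi",), given=("s", "a", "lambda"))


def _lambda_part(y: np.ndarray, n_lambda: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    return y[len(y) - n_lambda:]


def gaussian_kl(q: VariationalGaussian, cond: GaussianConditional,
                point: np.ndarray) -> float:
    """KL[q(Psi|lambda) || p*(Psi | s,a,lambda)] at one blanket point.

    Closed form for Gaussians:
    ``1/2 [tr(Sigma_c^{-1} S) - n + (mu_c-mu_q)^T Sigma_c^{-1} (mu_c-mu_q)
    + ln det Sigma_c - ln det S]``; nonnegative, zero iff the densities
    coincide at that point.
    """
    y = np.asarray(point, dtype=float).ravel()
    mu_c = cond.mean(y)
    mu_q = q.mean(_lambda_part(y, q.n_lambda))
    P = cond.P  # Sigma_c^{-1}
    n = q.n_psi
    diff = mu_c - mu_q
    _, logdet_P = np.linalg.slogdet(P)
    _, logdet_S = np.linalg.slogdet(q.S)
    val = 0.5 * (np.trace(P @ q.S) - n + diff @ P @ diff - logdet_P - logdet_S)
    return float(max(val, 0.0))


def free_energy(system: LinearOUSystem, q: VariationalGaussian,
                point: np.ndarray) -> float:
    """F(s,a,lambda) = -ln p*(s,a,lambda) + KL[q || p*(Psi|s,a,lambda)].

    When q equals the conditional the KL term vanishes and F reduces to
    the negative log marginal density exactly.
    """
    y = np.asarray(point, dtype=float).ravel()
    p = system.partition
    V = marginal_precision(system.C, p, ("s", "a", "lambda"))
    _, logdet_V = np.linalg.slogdet(V)
    n_y = V.shape[0]
    neg_log_marginal = 0.5 * (y @ V @ y - logdet_V + n_y * np.log(2.0 * np.pi))
    return float(neg_log_marginal + gaussian_kl(q, posterior(system), y))


@dataclass
class KLProfile:
    """Exact quadratic representation D(y) = const + g.y + y^T H y / 2."""

    const: float
    g: np.ndarray
    H: np.ndarray

    def __call__(self, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float).ravel()
        return float(self.const + self.g @ y + 0.5 * y @ self.H @ y)


def kl_profile(system: LinearOUSystem, q: VariationalGaussian) -> KLProfile:
    """Exact KL profile of q against the psi-conditional, over y = (s,a,lambda)."""
    cond = posterior(system)
    p = system.partition
    Delta = _gain_mismatch(cond, q, p)
    P = cond.P
    n = q.n_psi
    _, logdet_P = np.linalg.slogdet(P)
    _, logdet_S = np.linalg.slogdet(q.S)
    const = 0.5 * (np.trace(P @ q.S) - n - logdet_P - logdet_S + q.b @ P @ q.b)
    g = -Delta.T @ P @ q.b
    H = Delta.T @ P @ Delta
    return KLProfile(const=float(const), g=g, H=(H + H.T) / 2.0)


def _gain_mismatch(cond: GaussianConditional, q: VariationalGaussian,
                   partition: CoordinatePartition) -> np.ndarray:
    """Delta = K - [0 | 0 | A]: how the conditional mean's dependence on
    (s, a, lambda) exceeds what the variational mean can track."""
    n_s, n_a, n_l = partition.n_s, partition.n_a, partition.n_lambda
    A_ext = np.hstack([np.zeros((q.n_psi, n_s)), np.zeros((q.n_psi, n_a)), q.A])
    if cond.K.shape != A_ext.shape:
        raise NotSPDError(f"dimension mismatch: gain {cond.K.shape} vs q {A_ext.shape}")
    return cond.K - A_ext


@dataclass
class AffineMap:
    """An affine map y -> matrix @ y + offset, with a vanishing verdict."""

    matrix: np.ndarray
    offset: np.ndarray
    tol: float = VANISH_TOL

    @property
    def max_coefficient(self) -> float:
        m = float(np.max(np.abs(self.matrix))) if self.matrix.size else 0.0
        o = float(np.max(np.abs(self.offset))) if self.offset.size else 0.0
        return max(m, o)

    @property
    def vanishes(self) -> bool:
        return self.max_coefficient < self.tol

    def __call__(self, y: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(y, dtype=float).ravel() + self.offset


@dataclass
class GradientMaps:
    grad_a: AffineMap
    grad_lambda: AffineMap

    @property
    def both_vanish(self) -> bool:
        return self.grad_a.vanishes and self.grad_lambda.vanishes


def kl_gradient_maps(system: LinearOUSystem, q: VariationalGaussian) -> GradientMaps:
    """Exact affine representations of grad_a D and grad_lambda D over y.

    grad_y D = H y + g; the a- and lambda-rows are returned separately
    with a per-gradient "vanishes identically" verdict (every affine
    coefficient below tolerance).
    """
    prof = kl_profile(system, q)
    p = system.partition
    a_rows = slice(p.n_s, p.n_s + p.n_a)
    l_rows = slice(p.n_s + p.n_a, p.n_s + p.n_a + p.n_lambda)
    return GradientMaps(
        grad_a=AffineMap(prof.H[a_rows, :], prof.g[a_rows]),
        grad_lambda=AffineMap(prof.H[l_rows, :], prof.g[l_rows]),
    )


@dataclass
class LemmaFeasibilityReport:
    """Feasibility of the free-energy rewriting within the Gaussian-linear family.

    The verdict is explicitly scoped to Gaussian q with mean affine in
    lambda; a non-Gaussian q outside this family is not ruled out by an
    "infeasible" verdict (for a Gaussian conditional the family is
    exhaustive for exact matching, but the constraint analysis itself
    is family-relative).
    """

    family: str
    status: str                       # "ok" | "not_applicable"
    failing_precondition: str | None = None
    nullspace_dim_a: int | None = None
    nullspace_dim_lambda: int | None = None
    residual: float | None = None
    feasible: bool | None = None
    A: np.ndarray | None = None
    solution_nullspace: np.ndarray | None = None   # basis of free directions for rows of A
    witness: VariationalGaussian | None = None
    S_unconstrained: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "status": self.status,
            "failing_precondition": self.failing_precondition,
            "nullspace_dim_a": self.nullspace_dim_a,
            "nullspace_dim_lambda": self.nullspace_dim_lambda,
            "residual": self.residual,
            "feasible": self.feasible,
            "A": None if self.A is None else self.A.tolist(),
            "solution_nullspace_dim": (None if self.solution_nullspace is None
                                       else int(self.solution_nullspace.shape[1])),
            "S_unconstrained": self.S_unconstrained,
            "notes": list(self.notes),
        }


def lemma_feasibility(system: LinearOUSystem, family: str) -> LemmaFeasibilityReport:
    """Decide whether a Gaussian-linear q(Psi|lambda) can realise the
    free-energy rewriting of the named flow family.

    Applicable only when the system actually satisfies that flow family
    (otherwise the rewriting's premise is void).  The constraint on the
    mean gain A is ``Delta W^T = 0`` with W the family's gradient
    weighting; it is solved by least squares, the solution set is
    ``A = A0 + (free directions)``, and b and S remain unconstrained,
    which is what later enables unbounded-KL witnesses.
    """
    if family not in MARGINAL_FAMILIES:
        raise ValueError(f"lemma family must be one of {MARGINAL_FAMILIES}, got {family!r}")
    idres = identity_residuals(system)
    verdict = idres.families[family].verdict
    if verdict == "not_applicable":
        return LemmaFeasibilityReport(family=family, status="not_applicable",
                                      failing_precondition="condition_1")
    if verdict != "holds" and not (idres.families[family].residual or 0) < FEASIBLE_TOL:
        return LemmaFeasibilityReport(family=family, status="not_applicable",
                                      failing_precondition=f"flow_family_{family}")

    p = system.partition
    cond = posterior(system)
    W = family_weighting(system, family)
    GR = system.Gamma + system.R
    v = system.blocks(GR)
    ns_a = null_space(v["a", "a"])
    ns_l = null_space(v["lambda", "lambda"])

    # constraint (K - [0|0|A]) W^T = 0  <=>  A Wl^T = K W^T, Wl = lambda-columns of W
    K = cond.K
    n_s, n_a = p.n_s, p.n_a
    Wl = W[:, n_s + n_a:]
    T = K @ W.T
    # solve B A^T = T^T in the least-squares sense, B = Wl
    At, *_ = np.linalg.lstsq(Wl, T.T, rcond=None)
    A0 = At.T
    residual = specnorm(A0 @ Wl.T - T) / max(1.0, specnorm(T))
    sol_null = null_space(Wl)
    feasible = residual < FEASIBLE_TOL
    report = LemmaFeasibilityReport(
        family=family,
        status="ok",
        nullspace_dim_a=int(ns_a.shape[1]),
        nullspace_dim_lambda=int(ns_l.shape[1]),
        residual=float(residual),
        feasible=bool(feasible) if (residual < FEASIBLE_TOL or residual > INFEASIBLE_THRESHOLD)
        else None,
        A=A0,
        solution_nullspace=sol_null,
        witness=None,
        S_unconstrained=True,
    )
    report.notes.append(
        "S and b enter the KL only through point-independent terms; "
        "they are unconstrained whenever the gain constraint on A is satisfiable."
    )
    if feasible:
        report.witness = VariationalGaussian(A=A0, b=np.zeros(q_dim := cond.P.shape[0]),
                                             S=cond.covariance)
    elif residual > INFEASIBLE_THRESHOLD:
        report.notes.append(
            "no Gaussian q with lambda-affine mean can make the weighted KL "
            "gradients vanish identically; within this family the free-energy "
            "rewriting does not exist."
        )
    return report


@dataclass
class ProbeWitness:
    """A feasible q whose KL to the conditional exceeds a requested bound."""

    q: VariationalGaussian
    point: np.ndarray
    kl: float
    threshold: float
    covariance_scale: float
    gradients: GradientMaps
    gain_mismatch: float  # spectral norm of Delta: >0 means q != posterior

    @property
    def distinct_from_posterior(self) -> bool:
        return self.gain_mismatch > 0.0 or self.covariance_scale != 1.0

    def to_dict(self) -> dict:
        return {
            "kl": self.kl,
            "threshold": self.threshold,
            "covariance_scale": self.covariance_scale,
            "gradients_vanish": self.gradients.both_vanish,
            "gain_mismatch": self.gain_mismatch,
            "distinct_from_posterior": self.distinct_from_posterior,
        }


def kl_supremum_probe(system: LinearOUSystem, report: LemmaFeasibilityReport,
                      c: float) -> ProbeWitness:
    """Construct a feasible q whose pointwise KL exceeds ``c`` while its
    weighted KL gradients still vanish identically.

    The construction scales the conditional covariance, S = t Sigma_c,
    which adds the point-independent term n_psi (t - 1 - ln t)/2 to the
    KL without touching the gradient maps; t is grown deterministically
    until that term strictly exceeds c.  This is the unbounded-KL
    phenomenon: vanishing free-energy gradients bound the divergence by
    nothing.
    """
    if report.status != "ok" or not report.feasible:
        raise InfeasibleError(
            "kl_supremum_probe needs a feasible report; "
            f"got status={report.status!r}, feasible={report.feasible!r}"
        )
    cond = posterior(system)
    n_psi = cond.P.shape[0]
    t = 2.0 * c / n_psi + 2.0
    while 0.5 * n_psi * (t - 1.0 - np.log(t)) <= c:
        t *= 2.0
    q = VariationalGaussian(A=report.A, b=np.zeros(n_psi), S=t * cond.covariance)
    p = system.partition
    point = np.zeros(p.n_s + p.n_a + p.n_lambda)
    kl = gaussian_kl(q, cond, point)
    grads = kl_gradient_maps(system, q)
    Delta = _gain_mismatch(cond, q, p)
    return ProbeWitness(q=q, point=point, kl=kl, threshold=c, covariance_scale=float(t),
                        gradients=grads, gain_mismatch=specnorm(Delta))


# ---------------------------------------------------------------------------
# data-processing inequality for the "most likely internal coordinate"
# ---------------------------------------------------------------------------

def _gaussian_mi(cov: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray) -> float:
    """Mutual information between two (possibly degenerate) jointly
    Gaussian blocks: I = (ln det Sxx - ln det S_{x|y}) / 2, with a
    pseudoinverse regression to handle degenerate Y."""
    Sxx = cov[np.ix_(idx_x, idx_x)]
    Syy = cov[np.ix_(idx_y, idx_y)]
    Sxy = cov[np.ix_(idx_x, idx_y)]
    cond_cov = Sxx - Sxy @ np.linalg.pinv(Syy) @ Sxy.T
    sign_x, logdet_x = np.linalg.slogdet(Sxx)
    sign_c, logdet_c = np.linalg.slogdet((cond_cov + cond_cov.T) / 2.0)
    if sign_x <= 0 or sign_c <= 0:
        return 0.0
    return float(max(0.5 * (logdet_x - logdet_c), 0.0))


@dataclass
class DPIReport:
    """Closed-form Gaussian information audit of the estimator lambda_bar(s, a)."""

    gain: np.ndarray                      # lambda_bar = gain @ (s, a)
    mi_internal_blanket: float            # I(Lambda; (S, A))
    mi_internal_estimate: float           # I(Lambda; Lambda_bar)
    inequality_holds: bool
    margin: float

    def to_dict(self) -> dict:
        return {
            "mi_internal_blanket": self.mi_internal_blanket,
            "mi_internal_estimate": self.mi_internal_estimate,
            "inequality_holds": self.inequality_holds,
            "margin": self.margin,
        }


def dpi_check(system: LinearOUSystem, tol: float = 1e-10) -> DPIReport:
    """Check the data-processing inequality for the most-likely-internal map.

    For a Gaussian stationary density the most likely internal
    coordinate given the blanket, lambda_bar(s, a), is the conditional
    mean — an affine (here linear) function of (s, a).  Since
    Lambda -> (S, A) -> Lambda_bar is a Markov chain, the information
    the estimate carries about the internal coordinates cannot exceed
    what the blanket itself carries: I(Lambda; Lambda_bar) <=
    I(Lambda; (S, A)).  Both sides are closed-form log-determinant
    expressions; degenerate estimates (rank-deficient gain) are handled
    by pseudoinverse regression.
    """
    p = system.partition
    C = system.C
    sl = p.slices
    idx_sa = p.indices(("s", "a"))
    idx_l = p.indices(("lambda",))
    S_sa = C[np.ix_(idx_sa, idx_sa)]
    S_l_sa = C[np.ix_(idx_l, idx_sa)]
    gain = np.linalg.solve(S_sa.T, S_l_sa.T).T      # lambda_bar = gain @ (s,a)

    mi_full = _gaussian_mi(C, idx_l, idx_sa)
    # joint covariance of (lambda, lambda_bar)
    S_ll = C[np.ix_(idx_l, idx_l)]
    cov_bar = gain @ S_sa @ gain.T
    cross = S_l_sa @ gain.T
    n_l = len(idx_l)
    joint = np.block([[S_ll, cross], [cross.T, cov_bar]])
    mi_bar = _gaussian_mi(joint, np.arange(n_l), np.arange(n_l, 2 * n_l))
    margin = mi_full - mi_bar
    return DPIReport(gain=gain, mi_internal_blanket=mi_full,
                     mi_internal_estimate=mi_bar,
                     inequality_holds=bool(margin >= -tol), margin=float(margin))
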