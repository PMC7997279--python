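"""Seeded generators for structured linear OU systems and counterexamples.

The critiqued argument lives or dies on block-zero patterns of three
matrices — the drift M, the stationary precision U and the solenoidal
matrix R — so the generator works directly in those terms.  The
construction route fixes an antisymmetric R honouring its pattern,
then solves the *linear* constraints that the requested zero blocks of
``M = -(Gamma + R) U`` impose on the symmetric matrix U (for fixed R
the bilinear problem is linear in U), projects a diagonally-inflated
random target onto the constraint nullspace, and accepts the draw iff
U is positive definite and every required-nonzero block is well above
the violation threshold.  Acceptance is checked against the same
condition/identity/feasibility reports the analysis modules produce, so
every emitted counterexample carries a machine-checkable certificate.

Counterexample classes (API tokens follow the package's observation
labels):

* ``obs1_forward``  — blanket drift pattern holds, stationary
  conditional independence fails;
* ``obs1_reverse``  — conditional independence holds, drift pattern fails;
* ``obs2``          — both hold, yet the diagonal and cross reductions of
  the blanket flow both fail (generic solenoidal sensory coupling);
* ``obs4``          — both hold and the diagonal flow reduction holds, yet
  no Gaussian-linear variational density can realise the free-energy
  rewriting (the conditional mean of psi depends on a);
* ``obs5``          — gradient-flow chain system (R = 0) where the
  free-energy rewriting is feasible but the feasible set pins only the
  mean gain (A = 0), leaving the KL divergence unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import null_space

from .errors import GenerationError
from .blanket_conditions import ConditionReport, check_condition
from .flow_identities import IdentityResidualReport, identity_residuals
from .lemma_analysis import (
    LemmaFeasibilityReport,
    ProbeWitness,
    kl_supremum_probe,
    lemma_feasibility,
)
from .linsys_core import (
    BLOCKS,
    BlockView,
    CoordinatePartition,
    LinearOUSystem,
    VIOLATION_THRESHOLD,
    is_hurwitz,
    specnorm,
)

OBSERVATIONS = ("obs1_forward", "obs1_reverse", "obs2", "obs4", "obs5")

#: zero-block patterns of the three blanket conditions, reused by specs
CONDITION1_M_ZEROS = (("a", "psi"), ("lambda", "psi"), ("s", "lambda"), ("psi", "lambda"))
CONDITION2_U_ZEROS = (("psi", "lambda"),)
CONDITION3_R_ZEROS = (("psi", "s"), ("psi", "a"), ("psi", "lambda"),
                      ("s", "lambda"), ("a", "lambda"))


@dataclass(frozen=True)
class ConstraintSpec:
    """Declarative recipe for a structured random system.

    ``zero_*`` are block pairs whose sub-matrix must vanish (symmetric /
    antisymmetric partners are implied for U and R); ``nonzero`` maps a
    matrix name to block pairs whose norm must exceed the violation
    threshold.  A block listed as both zero and nonzero for the same
    matrix is inconsistent and rejected before any sampling.
    """

    partition: CoordinatePartition
    zero_M: tuple[tuple[str, str], ...] = ()
    zero_U: tuple[tuple[str, str], ...] = ()
    zero_R: tuple[tuple[str, str], ...] = ()
    nonzero: Mapping[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self):
        for name, zeros in (("M", self.zero_M), ("U", self.zero_U), ("R", self.zero_R)):
            for pair in zeros:
                if pair[0] not in BLOCKS or pair[1] not in BLOCKS:
                    raise GenerationError(f"invalid block pair {pair} in zero_{name}")
        for name, pairs in self.nonzero.items():
            if name not in ("M", "U", "R"):
                raise GenerationError(f"nonzero requirements refer to unknown matrix {name!r}")
            zeros = {"M": set(self.zero_M),
                     "U": _sym_closure(self.zero_U),
                     "R": _sym_closure(self.zero_R)}[name]
            for pair in pairs:
                if pair[0] not in BLOCKS or pair[1] not in BLOCKS:
                    raise GenerationError(f"invalid block pair {pair} in nonzero[{name}]")
                if tuple(pair) in zeros:
                    raise GenerationError(
                        f"inconsistent spec: {name} block {pair} required both zero and nonzero"
                    )


def _sym_closure(pairs: Sequence[tuple[str, str]]) -> set[tuple[str, str]]:
    out = set()
    for r, c in pairs:
        out.add((r, c))
        out.add((c, r))
    return out


def _entry_mask(partition: CoordinatePartition, pairs: Sequence[tuple[str, str]],
                symmetric: bool) -> np.ndarray:
    """Boolean d x d mask of entries forced to zero by block pairs."""
    d = partition.d
    mask = np.zeros((d, d), dtype=bool)
    sl = partition.slices
    use = _sym_closure(pairs) if symmetric else set(map(tuple, pairs))
    for r, c in use:
        mask[sl[r], sl[c]] = True
    return mask


def _sample_antisymmetric(rng: np.random.Generator, partition: CoordinatePartition,
                          zero_pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    d = partition.d
    X = rng.uniform(-1.0, 1.0, size=(d, d))
    R = (X - X.T) / 2.0
    R[_entry_mask(partition, zero_pairs, symmetric=True)] = 0.0
    return (R - R.T) / 2.0


def _sym_target(rng: np.random.Generator, partition: CoordinatePartition,
                zero_mask: np.ndarray, inflation: float | None = None) -> np.ndarray:
    """Random symmetric target with inflated diagonal, honouring the zero mask."""
    d = partition.d
    X = rng.uniform(-1.0, 1.0, size=(d, d))
    T = (X + X.T) / 2.0
    infl = float(d) if inflation is None else inflation
    T[np.diag_indices(d)] = infl + rng.uniform(0.0, 1.0, size=d)
    T[zero_mask] = 0.0
    return (T + T.T) / 2.0


def _solve_structured_U(rng: np.random.Generator, partition: CoordinatePartition,
                        R: np.ndarray, Gamma: np.ndarray,
                        zero_U: Sequence[tuple[str, str]],
                        zero_M: Sequence[tuple[str, str]]) -> np.ndarray | None:
    """One draw of a symmetric U with the given U-pattern such that
    ``-(Gamma+R)U`` has the given M-pattern; None if not SPD."""
    d = partition.d
    u_mask = _entry_mask(partition, zero_U, symmetric=True)
    # free symmetric basis: upper-triangle entries outside the U-zero mask
    free = [(i, j) for i in range(d) for j in range(i, d) if not u_mask[i, j]]
    m_mask = _entry_mask(partition, zero_M, symmetric=False)
    m_entries = [(i, j) for i in range(d) for j in range(d) if m_mask[i, j]]
    GR = Gamma + R

    if m_entries:
        A = np.zeros((len(m_entries), len(free)))
        for k, (i, j) in enumerate(free):
            # basis element E has 1 at (i,j) and (j,i)
            for r, (mi, mj) in enumerate(m_entries):
                val = GR[mi, i] if j == mj else 0.0
                if i != j and i == mj:
                    val += GR[mi, j]
                elif i == j and i == mj:
                    val = GR[mi, i]
                A[r, k] = val
        N = null_space(A)
        if N.shape[1] == 0:
            return None
    else:
        N = np.eye(len(free))

    target = _sym_target(rng, partition, u_mask)
    t = np.array([target[i, j] for (i, j) in free])
    coeffs = N @ (N.T @ t)
    U = np.zeros((d, d))
    for c, (i, j) in zip(coeffs, free):
        U[i, j] = c
        U[j, i] = c
    if np.min(np.linalg.eigvalsh(U)) <= 1e-8:
        return None
    return U


def _requirements_met(system: LinearOUSystem, spec: ConstraintSpec) -> bool:
    mats = {"M": system.M, "U": system.U, "R": system.R}
    for name, pairs in spec.nonzero.items():
        view = BlockView(mats[name], system.partition)
        for r, c in pairs:
            if specnorm(view[r, c]) <= VIOLATION_THRESHOLD:
                return False
    return True


def generate_system(spec: ConstraintSpec, Gamma: np.ndarray | None = None) -> LinearOUSystem:
    """Draw a linear OU system honouring a :class:`ConstraintSpec`.

    Deterministic given ``spec.seed``.  Raises
    :class:`~blanketlab.errors.GenerationError` with rejection
    diagnostics after ``max_attempts`` failed draws.
    """
    p = spec.partition
    d = p.d
    Gamma = np.eye(d) if Gamma is None else np.asarray(Gamma, dtype=float)
    rng = np.random.default_rng(spec.seed)
    diagnostics = {"spd_rejections": 0, "requirement_rejections": 0, "attempts": 0}
    for _ in range(spec.max_attempts):
        diagnostics["attempts"] += 1
        R = _sample_antisymmetric(rng, p, spec.zero_R)
        U = _solve_structured_U(rng, p, R, Gamma, spec.zero_U, spec.zero_M)
        if U is None:
            diagnostics["spd_rejections"] += 1
            continue
        M = -(Gamma + R) @ U
        system = LinearOUSystem(partition=p, M=M, Gamma=Gamma)
        if not _requirements_met(system, spec):
            diagnostics["requirement_rejections"] += 1
            continue
        return system
    raise GenerationError(
        f"no admissible system in {spec.max_attempts} attempts", diagnostics=diagnostics
    )


@dataclass
class CounterexampleCertificate:
    """A generated system bundled with the reports establishing its claims."""

    observation: str
    system: LinearOUSystem
    seed: int
    attempts: int
    condition_reports: dict[int, ConditionReport] = field(default_factory=dict)
    identity_report: IdentityResidualReport | None = None
    feasibility_report: LemmaFeasibilityReport | None = None
    probe: ProbeWitness | None = None

    def to_dict(self) -> dict:
        out = {
            "observation": self.observation,
            "seed": self.seed,
            "attempts": self.attempts,
            "conditions": {str(k): v.to_dict() for k, v in self.condition_reports.items()},
        }
        if self.identity_report is not None:
            out["identities"] = self.identity_report.to_dict()
        if self.feasibility_report is not None:
            out["feasibility"] = self.feasibility_report.to_dict()
        if self.probe is not None:
            out["probe"] = self.probe.to_dict()
        return out


_STRICT = 1e-12  # satisfied-condition residuals in certificates must beat this

#: minimum stationary partial correlation between psi and lambda for the
#: forward class: makes its conditional dependence empirically falsifiable
#: at the package's standard simulation length, not merely analytically nonzero
_MIN_PARTIAL_CORR = 0.25


def _stationary_partial_correlation(system: LinearOUSystem) -> float:
    """Largest |partial correlation| of a psi and a lambda coordinate
    given everything else, read off the stationary precision."""
    U = system.U
    p = system.partition
    ip = p.indices(("psi",))
    il = p.indices(("lambda",))
    denom = np.sqrt(np.outer(np.diag(U)[ip], np.diag(U)[il]))
    return float(np.max(np.abs(-U[np.ix_(ip, il)] / denom)))


def _cert_conditions(system: LinearOUSystem, want: dict[int, bool]) -> dict[int, ConditionReport] | None:
    """Check conditions against wanted verdicts; None if any draw is off
    or lands in the ambiguous band."""
    reports = {}
    for cid, should_hold in want.items():
        rep = check_condition(system, cid, tol=_STRICT)
        if should_hold and not rep.satisfied:
            return None
        if not should_hold and not rep.violated:
            return None
        reports[cid] = rep
    return reports


def _gen_obs1_forward(rng: np.random.Generator, p: CoordinatePartition) -> LinearOUSystem | None:
    """Blanket drift pattern imposed directly on M; conditional
    independence then generically fails."""
    d = p.d
    M = rng.uniform(-1.0, 1.0, size=(d, d))
    M[_entry_mask(p, CONDITION1_M_ZEROS, symmetric=False)] = 0.0
    # shift the whole spectrum left; diagonal shift preserves off-diagonal zeros
    shift = float(np.max(np.linalg.eigvals(M).real)) + 0.5
    M -= shift * np.eye(d)
    if not is_hurwitz(M):
        return None
    return LinearOUSystem(partition=p, M=M, Gamma=np.eye(d))


def _gen_obs4(rng: np.random.Generator, p: CoordinatePartition) -> LinearOUSystem | None:
    """Both blanket conditions and the diagonal flow reduction hold, but
    the conditional mean of psi reads the active coordinate, which no
    lambda-parameterised Gaussian mean can track.

    Construction: U couples psi-s, psi-a and s-a (lambda decoupled, so
    U_psi,lambda = U_s,lambda = U_a,lambda = 0), all four sensory/cross
    solenoidal blocks vanish (diagonal reduction exact), and the drift
    zero M_a,psi is restored by the compensating block
    R_a,psi = -(Gamma_aa + R_aa) U_a,psi U_psi,psi^{-1}.
    """
    d = p.d
    sl = p.slices
    u_mask = _entry_mask(p, (("psi", "lambda"), ("s", "lambda"), ("a", "lambda")),
                         symmetric=True)
    U = _sym_target(rng, p, u_mask)
    if np.min(np.linalg.eigvalsh(U)) <= 1e-8:
        return None
    Gamma = np.eye(d)
    R = np.zeros((d, d))
    view = BlockView(R, p)
    Uv = BlockView(U, p)
    G_aa = Gamma[sl["a"], sl["a"]]
    R_apsi = -G_aa @ Uv["a", "psi"] @ np.linalg.inv(Uv["psi", "psi"])
    view["a", "psi"] = R_apsi
    view["psi", "a"] = -R_apsi.T
    M = -(Gamma + R) @ U
    return LinearOUSystem(partition=p, M=M, Gamma=Gamma)


def generate_counterexample(observation: str, seed: int,
                            partition: CoordinatePartition | None = None,
                            max_attempts: int = 200) -> CounterexampleCertificate:
    """Generate one certified counterexample of the requested class.

    Deterministic given ``seed``; every certificate's reports pass their
    stated verdicts or :class:`GenerationError` is raised with
    attempt diagnostics.
    """
    if observation not in OBSERVATIONS:
        raise ValueError(f"unknown observation {observation!r}; expected one of {OBSERVATIONS}")
    p = partition or CoordinatePartition(1, 1, 1, 1)
    rng = np.random.default_rng(seed)
    fails = {"draw": 0, "verdict": 0}

    for attempt in range(1, max_attempts + 1):
        system = None
        if observation == "obs1_forward":
            system = _gen_obs1_forward(rng, p)
            want = {1: True, 2: False}
        elif observation == "obs1_reverse":
            R = _sample_antisymmetric(rng, p, ())
            U = _sym_target(rng, p, _entry_mask(p, CONDITION2_U_ZEROS, symmetric=True))
            if np.min(np.linalg.eigvalsh(U)) > 1e-8:
                M = -(np.eye(p.d) + R) @ U
                system = LinearOUSystem(partition=p, M=M, Gamma=np.eye(p.d))
            want = {2: True, 1: False}
        elif observation == "obs2":
            U = None
            R = _sample_antisymmetric(rng, p, ())
            U = _solve_structured_U(rng, p, R, np.eye(p.d),
                                    CONDITION2_U_ZEROS, CONDITION1_M_ZEROS)
            if U is not None:
                system = LinearOUSystem(partition=p, M=-(np.eye(p.d) + R) @ U,
                                        Gamma=np.eye(p.d))
            want = {1: True, 2: True}
        elif observation == "obs4":
            system = _gen_obs4(rng, p)
            want = {1: True, 2: True}
        else:  # obs5
            u_mask = _entry_mask(p, (("psi", "a"), ("psi", "lambda"), ("s", "lambda")),
                                 symmetric=True)
            U = _sym_target(rng, p, u_mask)
            if np.min(np.linalg.eigvalsh(U)) > 1e-8:
                system = LinearOUSystem(partition=p, M=-U, Gamma=np.eye(p.d))
            want = {1: True, 2: True}

        if system is None:
            fails["draw"] += 1
            continue

        cert = _certify(observation, system, seed, attempt, want)
        if cert is None:
            fails["verdict"] += 1
            continue
        return cert

    raise GenerationError(
        f"counterexample class {observation!r} not realised in {max_attempts} attempts "
        f"at partition {p.to_dict()}",
        diagnostics=fails,
    )


def _certify(observation: str, system: LinearOUSystem, seed: int, attempts: int,
             want: dict[int, bool]) -> CounterexampleCertificate | None:
    conds = _cert_conditions(system, want)
    if conds is None:
        return None
    cert = CounterexampleCertificate(observation=observation, system=system,
                                     seed=seed, attempts=attempts,
                                     condition_reports=conds)
    if observation == "obs1_forward":
        if _stationary_partial_correlation(system) < _MIN_PARTIAL_CORR:
            return None
        return cert
    if observation == "obs1_reverse":
        return cert

    idrep = identity_residuals(system)
    cert.identity_report = idrep
    if observation == "obs2":
        ok = (idrep.holds("full_state") and idrep.holds("marginal")
              and idrep.fails("diagonal") and idrep.fails("cross"))
        return cert if ok else None

    if observation == "obs4":
        if not (idrep.holds("full_state") and idrep.holds("marginal")
                and idrep.holds("diagonal")):
            return None
        # nonzero psi-a coupling of the stationary precision drives infeasibility
        if specnorm(system.blocks(system.U)["psi", "a"]) <= VIOLATION_THRESHOLD:
            return None
        feas = lemma_feasibility(system, "diagonal")
        cert.feasibility_report = feas
        if feas.status != "ok" or feas.feasible is not False:
            return None
        return cert

    # obs5
    if not all(idrep.holds(f) for f in ("full_state", "marginal", "cross", "diagonal")):
        return None
    # the unbounded-divergence argument needs a genuinely s-dependent conditional
    uview = system.blocks(system.U)
    for pair in (("psi", "s"), ("s", "a"), ("a", "lambda")):
        if specnorm(uview[pair[0], pair[1]]) <= VIOLATION_THRESHOLD:
            return None
    feas = lemma_feasibility(system, "diagonal")
    cert.feasibility_report = feas
    if feas.status != "ok" or feas.feasible is not True:
        return None
    if feas.A is None or specnorm(feas.A) > _STRICT:
        return None  # feasible set must pin the mean gain at zero
    cert.probe = kl_supremum_probe(system, feas, c=1e6)
    if not (cert.probe.kl > 1e6 and cert.probe.gradients.both_vanish
            and cert.probe.gain_mismatch > VIOLATION_THRESHOLD):
        return None
    return cert
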