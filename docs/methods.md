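# Methods

## Model class and conventions

Everything operates on linear (Ornstein–Uhlenbeck) stochastic systems

    dx/dt = M x + ω,     ⟨ω(t) ω(t')ᵀ⟩ = 2 Γ δ(t − t'),

with `x = (ψ, s, a, λ)` partitioned into external, sensory, active and
internal blocks (all sizes ≥ 1, dense algebra, dimensions up to ~50).
`M` must be Hurwitz (spectral abscissa below −10⁻⁸) and `Γ` symmetric
positive definite and block-diagonal over the partition. The restriction
to the linear constant-coefficient class is deliberate: here `Γ` and the
solenoidal matrix `R` are exactly constant, the stationary density is
exactly Gaussian, and every structural claim becomes decidable matrix
algebra. Coordinate-dependent `Γ` or `R` (the nonlinear setting) is out
of scope.

**Noise normalisation.** The noise autocovariance is fixed at `2Γδ`.
This is the unique convention under which the two routes to the
stationary density agree: the Lyapunov route `M C + C Mᵀ + 2Γ = 0` and
the potential route `U = −(Γ+R)⁻¹M` with `R` solving the Sylvester
equation `MR + RMᵀ = MΓ − ΓMᵀ`. `stationary_precision` cross-checks the
two routes at relative 10⁻⁸ on every call, and the simulation layer
verifies the convention empirically (the simulated covariance matches
`U⁻¹`, not `(2U)⁻¹` or `(U/2)⁻¹`). States are column vectors; gradients
are column vectors; the stationary mean is zero throughout.

**Norms.** All residual norms are spectral (2-)norms. This is a
load-bearing choice: the generalised-coordinate lift maps every block
`X_ab` to `I_n ⊗ X_ab`, under which the spectral norm is invariant, so
verdicts and residuals transfer *exactly* (to 10⁻¹²) between a system
and its lift. Frobenius norms would scale by √n and break residual
comparisons.

**Tolerance bands.** A required-zero block is *satisfied* below 10⁻¹⁰
(absolute; all matrices are O(1)) and *violated* only above 10⁻³. The
wide gap makes boolean verdicts robust to floating-point noise; the
generators resample any draw landing in the ambiguous band.
Cross-checks between independent routes use 10⁻⁸ relative.

## Blanket conditions and the chain structure

The three conditions are decided as block-zero patterns: the drift
dependency pattern on `M` (condition 1), stationary conditional
independence as `U_ψλ = 0` on the precision (condition 2 — exact for
Gaussians, so no numerical conditional-independence testing is used),
and the solenoidal decoupling pattern on `R` (condition 3).

`verify_chain_implication` checks that conditions 1 and 3 force the
chain interaction structure ψ–s–a–λ (`M_λs = M_ψa = 0`), via the
transpose identity `M = (Γ+R)Mᵀ(Γ−R)⁻¹` (an algebraic consequence of
the Sylvester relation; a pseudoinverse branch exists for singular
`Γ−R` and attaches a warning — unreachable while `Γ` is SPD). One
precondition beyond the literal block list of condition 3 is required:
the sensory–active solenoidal coupling `R_sa` must also vanish, i.e. `R`
must be *fully* block-diagonal. This is not pedantry: with `R_sa ≠ 0`
the blockwise transpose argument breaks and the chain genuinely fails
(`M_λs(Γ_ss − R_ss) = M_λa R_as` has nonzero right-hand side; the test
suite exhibits a numerical counterexample). The check therefore returns
a `not_applicable` verdict naming `R_sa_zero` rather than a false chain,
and the chain-verification study conditions generate `R` fully
block-diagonal.

## Flow identities as coefficient-matrix equalities

For OU systems `f_a` and `f_λ` are linear maps, so every proposed
rewriting through (partial) gradients of the stationary log-density is
an equality of coefficient matrices — checked exactly, never by
sampling points (a property test confirms pointwise and matrix verdicts
coincide). Four families are checked: the full-state form (a row
selection of `M = −(Γ+R)U`; holds always), the marginal form (gradient
of the marginal over `(s,a,λ)` with all surviving solenoidal couplings;
holds exactly when the drift has the blanket pattern, by the Gaussian
conditional-expectation identity `E[∇_β ln p*(x) | s,a,λ] = ∇_β ln
p*(s,a,λ)`, which the suite verifies by quadrature), and the cross and
diagonal reductions. Because the marginal precision `V` is invertible,
the diagonal reduction holds iff `R_as = R_aλ = R_λs = R_λa = 0` and the
cross form iff `R_as = R_λs = 0` — which is why generic solenoidal
coupling defeats them even under both blanket conditions, and why the
identity classes nest monotonically. The marginal gradient is computed
as `−V·(s,a,λ)` with `V` from the covariance restriction, not by
symbolic differentiation.

## Free-energy lemma within the Gaussian-linear family

The variational family is `q(Ψ|λ) = N(Aλ + b, S)` with constant SPD
`S`: Gaussian with mean affine in λ. The family is exhaustive for
matching a Gaussian conditional exactly, and it is structurally
incapable of depending on `(s, a)` — the "parameterised by λ only"
reading. Infeasibility verdicts are explicitly scoped to this family;
whether some non-Gaussian q could succeed where it fails is noted in
reports, not resolved. (The alternative convention `q(Ψ|s,a,λ)` is
trivially feasible — set q equal to the conditional — and is exposed
only implicitly through that observation.)

With `K` the conditional mean gain (`μ_c = K y`, `y = (s,a,λ)`) and
`Δ = K − [0|0|A]`, the KL divergence is the quadratic profile
`D(y) = ½(Δy − b)ᵀ U_ψψ (Δy − b) + const(S)`. A rewriting family with
gradient weighting `W` requires `W ∇_y D ≡ 0`; since the Hessian is
`ΔᵀU_ψψΔ` with `U_ψψ` SPD, this is *equivalent* to the linear
constraint `Δ Wᵀ = 0` on `A` (from `WΔᵀU_ψψΔWᵀ = 0 ⟹ ΔWᵀ = 0`).
Feasibility is therefore a linear least-squares problem: solved via
`lstsq`, solution set parameterised by the nullspace of the λ-columns
of `W`, normalised residual below 10⁻⁸ means feasible and above 10⁻²
infeasible ("vanishes identically" means every affine coefficient of a
gradient map is below 10⁻¹⁰). Three structural facts follow and are
reported: `S` and `b` are never constrained (they enter `D` only
through point-independent terms), and infeasibility is a property of
the system alone — it occurs exactly when `K` has support the weighting
cannot reach (e.g. a ψ–a precision coupling under the diagonal family).

The unbounded-KL probe scales `S = t·Σ_c`, adding
`½ n_ψ (t − 1 − ln t)` to the divergence everywhere without touching
the gradient maps; `t` starts at `2c/n_ψ + 2` and doubles
deterministically until the closed form strictly exceeds the requested
bound (the starting value alone undershoots by `½ n_ψ ln t` for large
c). The probe re-evaluates the KL at the witness point through the
generic closed form rather than trusting the construction.

A structural finding surfaced by the constructive tests: within this
class, a conditional that is `(s,a)`-independent but genuinely
λ-dependent cannot coexist with the *diagonal* reduction — the drift
constraints force `U_λλ < 0`. Such conditionals exist only through the
active–internal solenoidal coupling (cross/marginal families), and only
on the solenoidal submanifold `R_ψa = R_aλ R_ψλ` (scalar blocks). The
"strongest case" of the feasibility hierarchy (q equal to a constant
conditional, KL ≡ 0) is realised by decoupling ψ entirely.

`dpi_check` computes the most-likely-internal map `λ̄(s,a)` (the
conditional mean — affine, here linear) and closed-form Gaussian mutual
informations `I(Λ;Λ̄) ≤ I(Λ;(S,A))`, with pseudoinverse regression for
degenerate `λ̄`. For jointly Gaussian blocks with a full-rank gain the
two informations coincide (`λ̄` is a sufficient linear statistic), so
the inequality is typically tight; it is strict when the gain is rank
deficient. The newer λ̄-parameterised free-energy construction itself is
deliberately not implemented beyond this check.

## Synthetic systems: what the generators emulate

The generators realise the counterexample classes from their defining
block constraints, not from any fixed numerical instances; class
membership, never numeric equality with external examples, is what a
certificate claims. The construction route fixes an antisymmetric `R`
honouring its zero pattern (free entries uniform on [−1, 1]), then
solves the linear constraints that the requested zero blocks of
`M = −(Γ+R)U` impose on symmetric `U` (the bilinear problem is linear
in `U` for fixed `R`; no alternating optimisation, for determinism),
projects a diagonally-inflated random target (diagonal ≈ d + U(0,1), to
favour positive definiteness without biasing the structural zeros) onto
the constraint nullspace, and accepts iff `U` is SPD and every
required-nonzero block exceeds the violation threshold. `Γ` defaults to
the identity; any SPD block-diagonal `Γ` is accepted. Everything is
deterministic given the seed, and every certificate re-validates from
the serialized system alone.

The forward independence counterexample (blanket drift pattern without
stationary conditional independence) additionally requires the implied
stationary partial correlation `|ρ(ψ, λ | rest)| ≥ 0.25`. This is part
of the class definition: the class's claim is a conditional
*dependence*, and the package's empirical check of that claim (partial
correlations from a 2×10⁵-step trajectory, ~10³ effective samples)
resolves effect sizes of roughly 0.15 upward; a violation of 10⁻³ would
be real but empirically unfalsifiable at these lengths. Minimal
partitions are (1,1,1,1) for all classes; the infeasibility class keeps
λ stationarily decoupled (forced by its constraints at scalar blocks)
while the drift zero `M_aψ` is restored by the compensating solenoidal
block `R_aψ = −(Γ_aa+R_aa) U_aψ U_ψψ⁻¹`.

## Simulation layer

Euler–Maruyama (`x ← x + Mx·dt + √(2Γdt)·ξ`) is the primary integrator
for transparency, with a stability guard `dt < 0.5/max|eig(M)|`, an
overflow bound, and a minimum of 10⁴ post-burn-in steps; exact OU
transition sampling (matrix exponential, no discretisation bias) is the
cross-check mode. Standard errors use autocorrelation-corrected
effective sample sizes (integrated autocorrelation time truncated at
the first non-positive autocorrelation, conservatively paired as the
entrywise minimum); covariance z-tests pass below 4 SE, and stochastic
test assertions sit at 3–4 SE with fixed seeds so they are
deterministic in practice. Euler–Maruyama's stationary covariance
carries an O(dt·‖M‖) bias (~0.5 % for unit-rate systems at dt = 0.01,
but ~2 % for the stiffer generated systems whose eigenvalues sit near
−5); the tight 3 SE covariance-reproduction check therefore runs on the
unit-rate reference system, where the bias is an order of magnitude
below the standard error, while the partial-correlation and
Monte-Carlo-KL checks — insensitive to that bias at the 4 SE scale —
run on generated counterexample systems. Every stochastic operation
takes an explicit seed; there is no hidden global state.

## Problem sizes

The package's standard study conditions, used by the test suite and by
`scripts/acceptance.py`: 200 random systems of dimension 4–12 for the
exact-algebra properties; counterexample searches over seeds 0–9 at the
minimal partition; 100 constrained systems for the chain property; 50
conditional-independence systems for the information inequality; lifts
at orders 1, 2, 3, 5; simulations of 2×10⁵ steps at dt = 0.01; 10⁵
Monte-Carlo samples for KL and mutual-information estimates.

## Known limitations

* Verdicts are exact only for the linear OU class; nothing here speaks
  to coordinate-dependent `Γ`, `R`, non-Gaussian noise, or
  discrete-state formulations.
* Lemma infeasibility is relative to the Gaussian-λ-affine family
  (exhaustive for exact conditional matching, but not for the weaker
  weighted-gradient conditions in principle).
* Whether ergodic blanket systems can have non-trivial nullspaces of
  `(Γ+R)_aa` or `(Γ+R)_λλ` with degenerate diffusion is only reported
  (dimensions are 0 whenever `Γ` is SPD), not resolved.
* The empirical conditional-independence check is approximate by
  nature (finite trajectories, discretisation bias) and is used as a
  cross-check of the exact precision-matrix verdicts, never as the
  decision procedure.
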