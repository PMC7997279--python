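# blanketlab

Exact structural analysis of Markov-blanket arguments for linear
Ornstein–Uhlenbeck (OU) systems — the machinery needed to *check*, rather
than assume, the chain of rewritings behind variational free-energy
accounts of self-organising systems.

## The problem

Consider an ergodic stochastic process

```
dx/dt = f(x) + ω,      ⟨ω(t) ω(t')ᵀ⟩ = 2Γ δ(t − t'),
```

whose state is partitioned into external, sensory, active and internal
coordinates, `x = (ψ, s, a, λ)`. A popular line of argument holds that
when such a system "has a Markov blanket", its internal coordinates
appear to perform Bayesian inference about the external ones: the active
and internal flows supposedly descend a variational free energy

```
F(s, a, λ) = −ln p*(s, a, λ) + KL[ q(Ψ|λ) ‖ p*(Ψ|s, a, λ) ],
```

so that vanishing KL gradients would "render" the variational density
`q(Ψ|λ)` equal to the conditional `p*(Ψ|s,a,λ)`. Each step of that
argument is a concrete mathematical claim, and for linear OU systems —
where the stationary density is Gaussian with precision `U`, the drift
decomposes as `M = −(Γ + R)U` with antisymmetric solenoidal `R`, and
every rewriting is an identity between coefficient matrices — each claim
is *exactly decidable*. This package decides them, and constructs
certified counterexamples where they fail:

* the two circulating notions of "Markov blanket" — a dependency pattern
  of the drift (`M_aψ = M_λψ = M_sλ = M_ψλ = 0`) and conditional
  independence in the stationary density (`U_ψλ = 0`) — are
  **independent**: neither implies the other;
* rewriting the active/internal flows through *partial* gradients of the
  marginal log-density is valid in its general form, but the reduced
  forms that drop the solenoidal sensory couplings **fail** even when
  both blanket conditions hold;
* a variational density parameterised by the internal coordinates alone
  **need not exist** (within the Gaussian family with λ-affine mean,
  which is exhaustive for matching a Gaussian conditional), and when it
  does exist its KL divergence from the conditional is **unbounded**
  while all free-energy gradients vanish — vanishing gradients certify
  nothing about posterior matching;
* all of these verdicts transport verbatim to "generalised coordinates"
  realised as independent copies of the system.

## What the package provides

| Module | Contents |
|---|---|
| `linsys_core` | partitions, block views, solenoidal solve (Sylvester), stationary density (Lyapunov), conditionals/marginals |
| `blanket_conditions` | the three blanket conditions as block-zero verdicts; the chain-structure implication |
| `flow_identities` | the four flow-rewriting families as exact coefficient-matrix identities |
| `lemma_analysis` | Gaussian KL/free energy, gradient maps, lemma feasibility as linear least squares, unbounded-KL probes, the data-processing inequality for λ̄(s,a) |
| `synthetic_systems` | seeded generators of constrained systems and certified counterexamples |
| `generalised_coordinates` | the independent-copies lift |
| `simulate_validate` | Euler–Maruyama / exact OU simulation, covariance z-tests, empirical partial correlations, Monte-Carlo KL |
| `interface_io` | JSON system/report formats, full-analysis pipeline, `blanketlab` CLI |

## Worked example

Generate the gradient-flow counterexample in which the free-energy lemma
is *feasible* yet certifies nothing, and inspect it:

```python
import numpy as np
import blanketlab as bl

cert = bl.generate_counterexample("obs5", seed=0)
system = cert.system            # chain-coupled gradient flow, R = 0, Γ = I

print({c: bl.check_condition(system, c).satisfied for c in (1, 2, 3)})
# {1: True, 2: True, 3: True}       – both blanket conditions (and more) hold

ids = bl.identity_residuals(system)
print({k: v.verdict for k, v in ids.families.items()})
# {'full_state': 'holds', 'marginal': 'holds', 'cross': 'holds', 'diagonal': 'holds'}

feas = bl.lemma_feasibility(system, "diagonal")
print(feas.feasible, feas.A.ravel(), feas.residual)
# True [-0.] 0.0                    – feasible, but the mean gain is pinned to A = 0

probe = bl.kl_supremum_probe(system, feas, c=1e6)
print(f"{probe.kl:.4g}", probe.gradients.both_vanish, f"{probe.gain_mismatch:.4f}")
# 2e+06 True 0.0171
```

The last line is the punchline: a variational density inside the
feasible set whose KL divergence from the conditional exceeds 10⁶ at a
blanket point, while both free-energy gradient maps vanish identically
(every affine coefficient is 0) — and whose mean gain differs from the
conditional's by 0.017 in spectral norm, because the conditional mean
tracks the sensory coordinate and `q(Ψ|λ)` structurally cannot. The KL
is unbounded over the feasible set: gradient conditions place no bound
on the divergence, so they cannot "render" `q` equal to the posterior.

The same analyses are available from the shell:

```
blanketlab generate --observation obs5 --seed 0 --out sys.json --certificate cert.json
blanketlab check --system sys.json
blanketlab lemma --system sys.json --family diagonal --probe-c 1e6
blanketlab analyze --system sys.json --lift-order 3 --out report.json
```

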