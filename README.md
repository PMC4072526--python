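# ergokit

Linear-programming certificates for the long-term behavior of stochastic
chemical reaction networks — ergodicity, robustness over rate intervals,
moment boundedness and convergence, light-tailedness, and optimal
attractive sets for first-order moments — together with a Gillespie
SSA / reaction-rate-equation simulation layer that validates every
certificate empirically.

## Who this is for

Modelers in systems and synthetic biology (and epidemiology/ecology) who
work with continuous-time Markov chain models of reaction networks and
need to answer: *does my stochastic model have a unique stationary
distribution that attracts every initial condition?  Are its moments
bounded, and by how much?  Does this hold for all rate constants, or
only the ones I fitted?*  Solving or simulating the chemical master
equation cannot answer these questions conclusively; drift certificates
can, and for large network classes they reduce to linear programs whose
size is linear in the number of species.

## The mathematics in brief

A network of `d` species and `K` channels with stoichiometric vectors
`ζ_k` and propensities `λ_k(x)` defines a Markov jump process `X(t)` on
the lattice of molecular counts.  For a positive weight vector `v`, the
**drift–diffusivity condition** (DD) asks for constants `c1 > 0`,
`c2, c3 ≥ 0` with, for all states `x ≥ 0`,

```
Σ_k λ_k(x) ⟨v, ζ_k⟩   ≤  c2 − c1 ⟨v, x⟩        (DD1)
Σ_k λ_k(x) ⟨v, ζ_k⟩²  ≤  c3 (1 + ⟨v, x⟩)       (DD2)
```

DD1 plus irreducibility gives exponential ergodicity; adding DD2 with
bounded jumps gives uniform-in-time bounds on every moment
`E[⟨v, X(t)⟩^n]`, their convergence to stationarity, and light tails
(existence of the moment generating function — the implicit assumption
behind cumulant-neglect moment closures).  The first moment eventually
enters the half-space `{x ≥ 0 : ⟨v, x⟩ ≤ γ}` with `γ = c2/c1`, and the
*smallest* such attractive set is found by a scalar search over `c1`
whose inner problem is a linear program.

Finding `v` is tractable for broad classes:

- **unimolecular networks**: the linear drift matrix `A` is Metzler, and
  Hurwitz stability of `A` is equivalent to feasibility of the LP
  `{v ≥ 1 : Aᵀv < 0}` — also in robust (interval-rate) form;
- **bimolecular networks with a conservation relation for the order-2
  channels** (cone `V_b = {v > 0 : S_bᵀ v = 0}`): the quadratic drift
  term vanishes on `V_b` and the unimolecular LP applies;
- **general bimolecular networks**: componentwise nonpositivity of the
  quadratic form `Q(v)` (an LP) or negative definiteness (a semidefinite
  condition, solved here by eigenvector cutting planes);
- **competitive Lotka–Volterra communities**: diagonal rescaling or
  copositivity of the competition matrix;
- **scalar networks with higher-order kinetics** (e.g. Schlögl's
  trimolecular switch): a univariate drift polynomial with negative
  leading coefficient.

All conditions are sufficient only: the honest negative outcome is
`no_certificate_found`, never "non-ergodic".  Non-ergodicity is probed
separately by simulation diagnostics (guard-stopped explosions,
diverging ensemble moments).

## Worked example

```python
import ergokit as ek

net = ek.build_fixture("dimerization_29")     # 0->X1, X1->0, 2X1->X2, X2->0
rep = ek.analyze(net)
print(rep.verdict, rep.method)                # ergodic conserved_lp
cert = rep.certificate
print(cert.v, cert.c1, cert.c2)               # [1. 2.] 1.0 10.0

from ergokit.bounds import optimal_attractor_conserved, closure_audit
att = optimal_attractor_conserved(net)
print(att.gamma_star)                         # 10.0
print(att.set_description)                    # {x >= 0 : <(1, 2), x> <= 10}

aud = closure_audit(net, att)                 # variance-neglect closure
print(aud.closed_equilibrium)                 # [6.4658561  1.76707195]
print(round(aud.error_lower_bound, 6))        # 0.0  (on the boundary)
```

The weight `v = (1, 2)` annihilates the dimerization stoichiometry
`(−2, 1)`, so the weighted process `X1 + 2·X2` behaves like a linear
birth–death system: it is exponentially ergodic with all moments
bounded, and its stationary mean can never exceed `γ* = 10`.  The
cumulant-neglect closure converges to a point exactly on that boundary
(`⟨v, ŷ⟩ = 6.466 + 2·1.767 = 10.0`), so the closure is consistent with
the certified attractor and the audit's closure-error lower bound is 0.

From the shell, the same analysis is

```
ergokit analyze dimerization_29 --assume-irreducible
ergokit bounds dimerization_29
ergokit simulate dimerization_29 --t-end 50 --n-paths 100 --seed 1 --out traj.csv
```

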