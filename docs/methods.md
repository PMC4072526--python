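# Methods

## Model and scope

Networks are continuous-time Markov jump processes on the nonnegative
integer lattice: `d` species, `K` channels, stoichiometric vectors
`ζ_k`, propensities `λ_k`.  Three propensity kinds are supported:

- **stochastic mass action** with the falling-factorial convention
  (`κ·x(x−1)/2` for `2S → …`, `κ·x(x−1)(x−2)/6` for `3S → …`,
  `κ·x_i·x_j` hetero).  Orders up to 3 are accepted so the Schlögl
  switch can be expressed; the certificate machinery treats order 3
  only through the scalar polynomial route.
- **bounded functions** — propensities known only through a finite
  supremum (Hill-repressed transcription and similar).  Analysis uses
  only the supremum; simulation needs a concrete closed form
  (`eval_hint`).  This separation is deliberate: every certificate
  issued for such a network holds for *every* bounded nonnegative
  feedback, which is what makes the structural-ergodicity statements
  parameter- and mechanism-free.
- **per-capita bounded** (`scaled_bounded`) — propensities of the form
  `g(x)·x_j` with `g ≤ sup`, e.g. saturating Mdm2-mediated p53
  degradation.  Analysis uses the linear envelope `sup·x_j`.

The deterministic layer (reaction-rate equations) uses the monomial
convention `κ·x^m/m!`, the thermodynamic-limit correspondent of the
stochastic falling factorial.  The difference between the two drifts is
itself scientifically meaningful (the stochastic drift roots of a
bistable autocatalytic network sit to the right of the deterministic
fixed points) and is surfaced by `drift_roots_1d`.

## Condition DD and constant extraction

For weight `v > 0` the drift of `⟨v, X⟩` decomposes exactly (orders
≤ 2) as `xᵀQ(v)x + lin(v)ᵀx + const(v)`, with the falling-factorial
correction of homodimerizations folded into the linear term, so all
certificates hold for the true stochastic drift.  Constants are
extracted tightly:

- `c1 = min_i(−lin_i/v_i)`, `c2 = const(v)` — tight on the nonnegative
  orthant (attained along coordinate rays) when `Q(v) ≤ 0` entrywise
  and the linear part decays;
- when the linear part does not decay but the quadratic dominates
  (negative diagonal per coordinate, or `Q(v)` negative definite, or
  `−Q(v)` strictly copositive), `c1` is a free choice (default 1, in
  units of inverse time) and the finite quadratic maximum is absorbed
  into `c2`;
- `c3` is the minimal constant with `diffusivity(x) ≤ c3(1 + ⟨v,x⟩)`,
  computed coefficientwise from the affine diffusivity envelope.
  Channels with `⟨v, ζ⟩ = 0` contribute nothing; any order-≥2 channel
  with `⟨v, ζ⟩ ≠ 0` makes the diffusivity superlinear, `c3 = ∞`, and
  DD2 is honestly reported false (the Schlögl case: exponential
  ergodicity without moment-stability claims beyond the first order).
- bounded channels: drift-improving placements (`⟨v,ζ⟩ ≤ 0`) are
  dropped from the DD1 upper bound; others contribute `sup·⟨v,ζ⟩` to
  `c2` (or to the linear coefficient of the scaling species).  For DD2
  they always contribute `sup·⟨v,ζ⟩²`.

Every issued certificate can be re-audited by randomized lattice
sampling (`audit_certificate`), which checks the DD inequalities
against exact propensities.

## Certificate programs

Strict LP inequalities are implemented with the scale-aware margin
`(Aᵀv)_i ≤ −ε·v_i`, `ε = 1e−6`, under the normalization `v ≥ 1`
(which also makes `⟨v, x⟩ ≥ ‖x‖₁`, so weighted-moment bounds transfer
to species counts).  The Hurwitz margin is `1e−9`; spectra within it
are treated as marginal.  Bounded channels enter the LPs through
auxiliary variables `t_k ≥ max(⟨v, ζ_k⟩, 0)` — the convex envelope of
their worst-case contribution — keeping every program a plain LP.

The negative-definiteness condition (`Q(v) ⪯ −εI`) is a small LMI; it
is solved by Kelley cutting planes over `scipy.optimize.linprog`, each
round adding the top eigenvector of the current `Q(v)` as a linear cut.
At the dimensions that occur here (d ≤ 10) this converges in a handful
of rounds, and LP infeasibility of the outer relaxation certifies
infeasibility of the LMI.

Copositivity (the Lotka–Volterra route) is decided by enumerating the
KKT points of `xᵀMx` on every face of the probability simplex — exact
for nondegenerate matrices up to the enforced dimension limit (d ≤ 10),
with an explicit nonnegative witness when copositivity fails.  Strict
copositivity margins are found by bisection on `M − δI`.

**Robust analysis.**  Interval rates enter each matrix entry with a
fixed sign, so the entrywise supremum matrix is always a valid Metzler
bound for the whole family.  When one parameter choice attains the
bound simultaneously in every entry, LP feasibility on it is
*equivalent* to robust stability; otherwise it is sufficient only, and
an infeasible program is reported as `bound_matrix_unavailable` rather
than as a negative claim.

**Conserved bounded species.**  Species confined by a conservation
relation through the initial state (gene copies: free + bound = copy
number) are detected by one LP per species and projected out before
analysis; their propensity influence is replaced by suprema (a
transcription channel from a bounded gene state becomes a bounded
channel).  The reduced drift is a valid upper envelope on the invariant
set, so reduced-network certificates transfer to the original.  This is
what closes the circadian-clock analysis: after removing the four gene
states, the remaining 5-species network is conserved-bimolecular and
one LP certifies ergodicity for all positive rates.  A network whose
species are *all* bounded is a finite irreducible chain and is reported
ergodic directly.

## Optimal attractors

`γ* = min c2(v)/c1` over certificates is computed by a deterministic
coarse scan plus golden-section refinement over `c1` (relative
tolerance 1e−6, at most 120 refinement steps), with the inner LP
minimizing `c2(v)` subject to decay at rate `c1`; the supremum decay
rate (e.g. the spectral abscissa in the unimolecular case) is tested
exactly as an endpoint candidate.  Each LP solution is re-evaluated at
the decay rate it *actually* attains (recomputed exactly from the
decomposition), so the reported `(v*, c1*, γ*)` is immune to LP
feasibility tolerances — on the birth–death process `γ*` equals the
Poisson mean to machine precision.

## Moment-bound tables

Applying the generator to `V^n = ⟨v, x⟩^n` and expanding jumps
binomially gives

    L V^n ≤ n V^{n−1}(c2 − c1 V) + Σ_{j=2..n} C(n,j) ζ̄^{j−2} c3 (1+V) V^{n−j}

with `ζ̄ = max_k |⟨v, ζ_k⟩|`; absorbing every sub-leading power into
`1 + V^{n−1}` yields the comparison recursion

    K_n = n·c2 + 2·c3·Σ_{j=2..n} C(n,j)·ζ̄^{j−2}
    asym_1 = c2/c1,   asym_n = K_n (1 + asym_{n−1}) / (n c1)
    unif_n = max(V(x0)^n, K_n (1 + unif_{n−1}) / (n c1))

valid for every order whenever DD holds with finite `c3` and bounded
jumps.  The recursion is conservative — its slack grows with `n` — so
the testable contract is *validity* (SSA ensemble moments never exceed
the table beyond Monte-Carlo error), not tightness; tightness holds at
`n = 1`, where the asymptotic bound equals `γ`.  Without DD2 the table
stops at the drift-only first-order bound.  Light-tail flags (uniform
and stationary) are set exactly when DD holds in full; this is the
conservative reading of the light-tailedness theorems, whose role here
is to justify the existence of the moment generating function that
cumulant-neglect closures presuppose.

## Moment-closure audit

The variance-neglect closure replaces `E[x_i x_j]` by `y_i y_j`, which
turns the exact first-moment equation into the stochastic drift
evaluated at real `y` (falling factorials at real arguments).  The
audit integrates this ODE to equilibrium, refines by root finding,
checks the numerical Jacobian, and reports the Euclidean distance from
the closed equilibrium to the attractor `{x ≥ 0 : ⟨v, x⟩ ≤ γ}` as a
lower bound on the closure error.  The projection is exact (KKT with a
bisected multiplier, respecting the nonnegative orthant); the metric
choice is Euclidean.  On the dimerization network the closed
equilibrium lands exactly on the attractor boundary, so the lower
bound is 0 — the closure is consistent with, though not validated by,
the certificate.

## Simulation layer

Gillespie's direct method, exact and reproducible: per-path seeds
derive from `numpy.random.SeedSequence(master_seed)`.  Mass-action
networks run through numba kernels (event records, grid sampling, and
streaming occupation averages); bounded-propensity networks use a
pure-Python engine that evaluates the closed forms.  Two explosion
guards mirror standard practice for non-ergodic models: an event cap
(default 1e7) and a total-propensity cap (default 1e6 per time unit);
guard-stopped paths are flagged censored.  Ensemble moments carry
standard errors (`sd/√n_paths`); all bound-validity checks use a
3·SE margin.

## Example-network fixtures

Thirteen networks ship as builders with documented species order and
default rates; `.rxn` round-tripping is tested on all of them.  Choices
that were genuinely open:

- **circadian clock**: the Vilar activator–repressor oscillator with
  its reference rates.  The canonical mechanism has 16 channels; this
  fixture's 18-channel listing adds degradation of the gene-bound
  activator (`DA_b → DA`, `DR_b → DR` at rate `dA`), slow relative to
  unbinding and perturbing the stationary averages by under 1%.  The
  3000-time-unit occupation average used for validation reproduces the
  reference stationary means (A ≈ 222, R ≈ 535, C ≈ 550) to about 1%
  (single-run spread ≈ 1%, well inside the 5% acceptance band); an
  equivalent 2000-cell ensemble average would cost ~1000× more compute
  for the same check, which is exactly the ergodic theorem's point.
- **bistable well (well_jumping_22)**: `0→X, X→0, 2X→3X` with
  `k1=4, k2=1, k3=0.12`, tuned so the deterministic fixed points (6.7
  stable, 10 unstable) are distinct, the stochastic drift roots (5.5,
  12.2) bracket them and stay below 50, and essentially all guarded
  runs escape within 100 time units.
- **stable-RRE / divergent-CME pair (unstable_pair_26)**: birth +
  pair-annihilation `0→X1, 0→X2, X1+X2→0` with equal birth rates.  The
  difference `x1−x2` is deterministically conserved, so each leaf has a
  unique globally exponentially stable equilibrium (Jacobian: one
  negative eigenvalue plus the conservation zero mode); stochastically
  the difference is an unbiased random walk and every moment grows
  (first moment ~ √t).  Divergence tests compare ensemble means at the
  horizon and half-horizon with a 3·SE margin.
- **carcinogenesis_41**: immigration-fed subcritical healthy cells
  mutating into supercritical malignant cells (`b2 > d2`), the didactic
  non-ergodic branching regime.

## What the synthetic conditions do and do not show

The fixtures and random-network generator exercise mass-action and
bounded-Hill kinetics on small, well-mixed, time-homogeneous networks.
Passing tests show the certificates are sound and the optimizers reach
their optima under these conditions; they say nothing about
time-varying rates, non-mass-action kinetics outside the bounded
classes, or spatial effects, all of which are outside the model class.
`no_certificate_found` is never evidence of non-ergodicity — the
conditions are sufficient only, and the divergence diagnostics are
statistical, not proofs.

## Numerical choices and problem sizes

- LPs: `scipy.optimize.linprog` (HiGHS); strictness `ε = 1e−6`;
  Hurwitz tolerance `1e−9`.
- Outer attractor search: 60-point scan + golden section, rel. tol
  1e−6.
- Irreducibility: truncated reachability (default box 30 per species,
  hard guard 1e7 states) with strongly-connected-component analysis;
  `counterexample` only for traps closed in the full lattice,
  `verified_on_truncation` otherwise at best — full irreducibility
  decision procedures are out of scope and the CLI requires either the
  check or an explicit `--assume-irreducible`.
- Test problem sizes: sweeps use 100 random log-uniform draws per
  circuit in [1e−2, 1e2]; divergence experiments 1000 runs; moment
  validity 2000 paths; the LP/spectral concordance 500 random Metzler
  matrices up to d = 8; the birth–death occupation histogram ≥ 1e5
  jumps.

## Known limitations

- The negative-definite and copositive routes record conservative
  moment orders (2 and 1); sharper order bookkeeping would need the
  exact higher-order drift inequalities, not just the quadratic form.
- The robust route only implements the bound-matrix construction; when
  no single parameter choice attains the entrywise bound the outcome is
  honest but inconclusive.
- Higher-moment constants are conservative by design; only their
  validity, monotonicity in `c1`, and the first-order tightness are
  guaranteed.
- The scalar polynomial route requires a single species; multivariate
  order-3 networks are not collapsed automatically.
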