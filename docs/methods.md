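# Methods

## The model

`mestweb` simulates a mutualist–exploiter–specialist predator–top predator
(MEST) community: a mutualist `F0` (a pollinating fig wasp standing in for
the fig–pollinator mutualism), `n` exploiters `F1..Fn` (non-pollinating
wasps that free-ride on the mutualism), a specialist predator `C`
(parasitoid wasp feeding only on the mutualist) and an omnivorous top
predator `P` (a predatory ant) that can feed on all of them.  All
functional responses are linear (Holling type I) and every rate is
dimensionless.

Biomass dynamics:

```
dF0/dt = F0 ( r0 − α0 F0 − Σ_i β_{i0} F_i − aC C − θ0 u0 P − d0 )
dFi/dt = ri Fi (1 − Fi / (F0/q)) − Σ_{j≠i} β_{ji} F_j Fi − θi ui Fi P − di Fi
dC/dt  = C ( eC aC F0 − θC uC P − dC − αC C )
dP/dt  = P W_P ,   W_P = eP Σ_k θk uk Fk + eP θC uC C − dP − αP P
```

The exploiters' carrying capacity is `F0/q`: they grow on the resource
flow generated by the mutualism, so their capacity collapses with the
mutualist, and the scale coefficient `q` measures how strongly the
community depends on the mutualism (`q → 0` removes the dependence and
leaves an ordinary food web).  We considered the alternative reading in
which the capacity is `F0^q` and rejected it empirically: under `F0^q`
the four-species reference configuration has a globally attracting stable
boundary equilibrium at every adaptation intensity — no cycles, no
period-doubling, no chaos — which contradicts the established dynamical
phenomenology of this system, whereas `F0/q` reproduces it in full (see
*Attractor structure* below).

The top predator divides a unit foraging budget over its n+2 prey.  The
stored coordinates are `θ0..θn` (efforts on `F0..Fn`); the effort on `C`
is always the simplex remainder `θC = 1 − Σθ`.  Preferences follow the
replicator dynamics on the full simplex,

```
dθj/dt = g θj ( wj − w̄ ) ,   wj = eP uj Fj ,  wC = eP uC C ,
w̄ = Σk θk wk + θC wC ,
```

with adaptation intensity `g`.  Under this reading the implied
`dθC/dt = g θC (wC − w̄)` equals minus the sum of the stored derivatives,
so total effort is exactly conserved and every face `θj = 0` is
invariant (a dropped link never reappears).  The alternative reading that
substitutes `θC` before differentiating produces the identical vector
field for `θ0..θn`, so nothing hinges on the choice; we keep the
full-simplex formulation because it makes the conservation law explicit.

### Baseline parameters

All rates are dimensionless; the baseline values used throughout are

| parameter | meaning | value |
|---|---|---|
| r0 | mutualist growth rate | 0.5 |
| α0, αC, αP | density dependence of F0, C, P | 0.13, 0.12, 0.1 |
| β | interspecific competition (all pairs among {F0, F1..Fn}) | 0–0.18 |
| aC | consumption of C on F0 | 0.2 |
| u0, ui, uC | consumption of P on F0, Fi, C | 0.11, 0.15 (ui ∈ [0, 0.3]), 0.2 |
| eC, eP | conversion efficiencies | 1, 1 |
| d0, di, dC, dP | mortalities | 0.05 each |
| q | mutualism scale coefficient | 0.25 |
| g | foraging-adaptation intensity | 0.05–0.5 |

The four-species reference configuration (`four_species_params()`) fixes
`n = 1`, `r1 = 0.35`, `u1 = 0.15`, `β10 = β01 = β = 0.18`, `g = 0.28`.

## Numerical integration and extinction pruning

Trajectories are integrated with adaptive Runge–Kutta (DOP853; LSODA for
large ensembles) in checkpointed windows.  At each checkpoint (every 100
time units) any biomass or effort below the extinction threshold
(1e−12) is snapped to exactly zero and held; because every extinction
face is invariant, checkpoint granularity affects only the recorded
extinction time.  Tiny negative excursions left by the stepper are
cleared the same way, and round-off overshoot of the effort budget past
1 is renormalised.

Pruning is **disabled** in attractor scans (`scan_options()`).  The
low-`g` attractors are slow–fast relaxation cycles in which the effort
on the exploiter falls tens of orders of magnitude below any plausible
threshold and then recovers; pruning would convert those cycles into
boundary equilibria.  Ensemble persistence runs keep the 1e−12 rule —
there, losing a link or a species *is* the measured outcome.  Scan
tolerances are rtol 1e−10 / atol 1e−14 so that the deep effort troughs
are tracked smoothly; ensemble runs use rtol 1e−8 / atol 1e−10.

## Attractor structure over the adaptation intensity

Scans integrate cold from one documented reference state,
`scan_initial_state()`: biomasses `(F0, Fi, C, P) = (1.2, 0.7, 0.8, 0.8)`,
efforts `θ0 = 0.15` with `0.30` shared over exploiters.  This state lies
inside the basin of the coexistence attractor across `g ∈ [0.05, 0.5]`;
generic states (e.g. all biomasses 0.5, uniform efforts) are also in the
basin but relax an order of magnitude more slowly at low `g`, because the
exploiter effort first collapses to ~1e−30 and regrows at rate `~g·Δw`.
The scan transient is 3×10⁴ time units with a 2×10⁴ recording window —
the low-`g` cycles have periods up to ~2×10³, so shorter windows
undercount extrema.

Distinct attractor branches are the clusters of local maxima separated
by more than 1e−3 (absolute).  With the reference configuration the
branch counts follow a period-doubling cascade and back:
1 (g=0.05–0.08) → 2 → 3 (g≈0.22) → many/irregular (g≈0.28) → 2 (g≈0.34)
→ 1 (g≥0.38).

Lyapunov exponents use the standard tangent-space (Benettin) method:
the variational system `dV/dt = J(x)V` with the analytic Jacobian,
QR-renormalised every 10 time units, log-stretch averaged over 2×10⁴
units after the transient.  A renormalisation interval of 10 is safe
here because the exponents are O(1e−3).  Convergence is reported as a
block-bootstrap band on the leading exponent.  The converged leading
exponent of the irregular regime at `g = 0.28` is ≈ 5×10⁻⁴ (tangent and
two-trajectory methods agree, and split-half averages over 1.5×10⁵ time
units are consistent), while the periodic regimes at `g = 0.08` and
`g = 0.48` give ≤ 1×10⁻⁴ up to estimator noise.  Because the chaotic
exponent is genuinely small, `classify_dynamics` treats an attractor as
chaotic when the leading exponent exceeds an explicit tolerance **or**,
with the default `le_tol=None`, when the bootstrap band lies entirely
above zero; the count of distinct maxima branches then separates simple
(1) from period-doubled (≥2) cycles, with fixed points recognised by a
collapsed peak-to-peak range.

## Boundary structures and stability maps

A *network structure* is a subset of P's foraging links; each is a
boundary face of the effort simplex, and with `m` selectable links there
are `2^m − 2` proper non-empty structures (`count_boundary_structures`).
For a structure's coexistence equilibrium the biomass brackets of all
species vanish and, when ≥ 2 links are active, the interior efforts are
pinned by equality of the per-effort returns `wj` across active prey.
The square system is solved by multi-start root finding (`hybr`), 16
seeded Latin-hypercube starts over biomasses in (0, 5], first feasible
root accepted (all biomasses strictly positive, efforts in [0, 1],
residual < 1e−10).  Stability maps solve every grid cell cold with the
same start protocol, so they are invariant to traversal order and to the
multi-start seed.

`Re(λmax)` is evaluated in one of two scopes.  The default **full**
scope is the Jacobian of the complete adaptive system; at a boundary
structure it automatically contains the diet-expansion invasion rates
`g (wk − w̄)` of each inactive link, which is where adaptive foraging
destabilises a structure.  The **ecological** scope freezes efforts and
keeps the biomass block only — the community matrix of the
fixed-preference model.  The distinction is not cosmetic: for the
structure in which P consumes only the exploiter, the ecological scope
is stable everywhere on the (u1, β) grid (max Re(λmax) ≈ −7×10⁻⁵) while
the full scope is unstable everywhere (Re(λmax) ∈ [0.017, 0.068],
dominated by the invasion rate `g (uC C* − u1 F1*)` of the unused link
to C).  The full scope is the package default because it reproduces the
qualitative stability geography of all four named structures: A (θC=0)
unstable everywhere it is feasible, B (full diet) stabilised at high u1
and β, C (θ0=θC=0) weakly unstable everywhere, D (θ0=0) widely stable at
low β.

## Persistence ensembles

`EnsembleSpec` defines the factorial design: community size N (n = N−3
exploiters), shared competition β, adaptation g, a connectance grid
(default 8 points, 0.3–1.0), and `n_param_draws × n_init_draws`
replicates per point (desk-scale default 5×5; the full design is 20×20).
Per replicate: growth rates `ri ~ U[0.3, 0.4]`, `di = 0.05`,
`ui = 0.15`; the initial diet wires `L = round(c·(n+2))` links (at least
one) chosen uniformly among all n+2 prey, each with effort `1/L`;
initial biomasses are `U[0.1, 1.0]` (a documented package choice — the
study design does not print initial conditions).  Randomness is a
two-level `SeedSequence` hierarchy, `(base_seed, connectance index,
param draw, init draw)`, making every replicate reproducible in
isolation and the surface bit-identical under a fixed base seed.

A replicate integrates in windows of `T_check = 2000` with pruning and
stops when the survivor count has been identical across three
consecutive windows (slow competitive exclusions routinely pause for a
full window, so a single repeat is not yet steady) or at
`T_total = 2×10⁴`.  Persistence is the surviving-species fraction;
pruned *efforts* rewire the diet but do not count against species
persistence.  Curve shapes are labelled by a deterministic rule: 3-point
moving average, Spearman |ρ| ≥ 0.8 for monotonic, otherwise interior
peaks with prominence ≥ 0.02 persistence units (1 → peaked, 2 →
double-peaked), else unclear.  The ρ and prominence constants are
documented choices; visual classification is not reproducible.

What the generator does *not* emulate: empirical diet topologies,
body-size or trait-based parameter correlations, saturating functional
responses, demographic stochasticity, and any spatial structure.
Passing ensemble tests therefore demonstrate the model's internal
connectance–persistence behaviour under randomized rate draws, not
agreement with field food webs.

### A known divergence

Under these study conditions the N = 15, β = 0.1 ensembles produce a
*positive* connectance–persistence trend: the dominant extinction
process in our runs is diffuse competitive exclusion among exploiters
(inter-exploiter β exceeds the self-limitation `ri q / F0` whenever the
mutualist is abundant), and predation by P thins the exploiter guild and
relieves it, so more links mean more coexistence.  A negative trend at
intermediate N is reported for this system in the literature; we could
not recover it under any variant we tested (longer horizons, mandatory
mutualist link, exploiter-only wiring, removal of exploiter–exploiter
competition, the `F0^q` capacity reading), and the variants that weaken
exclusion simply flatten the curve at persistence ≈ 1.  The discrepancy
is documented rather than tuned away; the small-community (N = 5)
positive trend, driven by top-predator starvation at low connectance,
does reproduce.

## Feedback loops

The signed digraph assigns predation +/− edge pairs, competition −/−
pairs, and collapses the mutualist–exploiter relationship to its
inhibitory (competition) edge in both directions — the qualitative net
effect used in loop analysis of this community.  Adaptive foraging
enters as a qualitative `AF` node (`P → AF` always +; `AF → C` and
`AF → F1` signed by the named strategy).  Cycles are enumerated with a
bounded simple-cycle search (length ≤ 12), canonicalised by rotating the
smallest node first; a loop's sign is the product of its edge signs.
The four-species web has exactly two maximal loops (one positive, one
negative); redirecting predation pressure via AF turns both negative
(intensify on C, relax on F1), both positive (the reverse), or one of
each (shift both the same way).

## Known limitations

- The chaotic regime's Lyapunov exponent is O(5×10⁻⁴); distinguishing
  it from zero needs ≥ 2×10⁴ time units of averaging, and classification
  of near-transition `g` values is sensitive to the transient length.
- Multi-start equilibrium search can in principle miss coexistence
  roots in pathological corners of parameter space; the maps mark such
  cells infeasible rather than guessing.
- The persistence stopping rule bounds, but does not eliminate,
  sensitivity to asymptotically slow exclusions (rates ~ differences of
  drawn growth rates).
- General-N loop enumeration is combinatorial; the length cap keeps it
  desk-scale but truncates loops longer than 12 nodes.
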