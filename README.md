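# mestweb

Dynamics, stability and feedback-loop analysis of
**mutualist–exploiter–specialist predator–top predator (MEST)
communities** with adaptive foraging.

The package is for theoretical ecologists studying the
complexity–stability question in networks that mix mutualistic and
antagonistic interactions — the motivating system is the fig-wasp
community: a pollinating wasp (mutualist, `F0`), up to dozens of
non-pollinating wasps (exploiters, `F1..Fn`), a parasitoid (specialist
predator, `C`) and a predatory ant (omnivorous top predator, `P`).

## The model

Biomasses follow a Lotka–Volterra food web with linear functional
responses, in which the exploiters' carrying capacity `F0/q` is the
resource flow generated by the mutualism:

```
dF0/dt = F0 ( r0 − α0 F0 − Σ β_{i0} F_i − aC C − θ0 u0 P − d0 )
dFi/dt = ri Fi (1 − q Fi/F0) − Σ_{j≠i} β_{ji} F_j Fi − θi ui Fi P − di Fi
dC/dt  = C ( eC aC F0 − θC uC P − dC − αC C )
dP/dt  = P W_P,   W_P = eP Σ θk uk Fk + eP θC uC C − dP − αP P
```

The top predator's diet is dynamic: its foraging efforts `θ` evolve on
the simplex by replicator dynamics driven by the per-effort fitness
returns `w_j = eP u_j F_j`,

```
dθj/dt = g θj ( w_j − w̄ ),    w̄ = Σ θk wk + θC wC ,
```

with adaptation intensity `g`.  The package provides:

- trajectory integration with extinction pruning (`integrate`),
- bifurcation scans and Lyapunov spectra over `g`
  (`bifurcation_scan`, `lyapunov_spectrum`, `classify_dynamics`),
- coexistence equilibria and `Re(λmax)` stability maps of boundary
  foraging structures over `(u1, β)` (`find_equilibrium`,
  `stability_map`, `count_boundary_structures`),
- persistence-versus-connectance ensemble experiments with a synthetic
  community generator (`EnsembleSpec`, `persistence_surface`,
  `classify_pattern`),
- signed feedback-loop enumeration with a qualitative adaptive-foraging
  node (`build_signed_digraph`, `enumerate_loops`, `maximal_loops`).

See `docs/methods.md` for the full model description, numerical choices
and known limitations.

## Worked example

Classify the attractor of the four-species community at intermediate
adaptation intensity, then count the maximal feedback loops:

```python
import numpy as np
from mestweb import (four_species_params, scan_initial_state, integrate,
                     scan_options, attractor_extrema, distinct_extrema,
                     build_signed_digraph, enumerate_loops, maximal_loops,
                     loop_sign_summary)

p = four_species_params(g=0.28)           # r1=0.35, u1=0.15, beta=0.18
series = integrate(p, scan_initial_state(p), 50_000.0, scan_options())
ext = attractor_extrema(series, "F1", transient=30_000.0)
print("distinct F1 maxima:", distinct_extrema(ext["maxima"]).size)

G = build_signed_digraph(1, include_AF=True,
                         AF_strategy="inhibitC_promoteF1")
print(loop_sign_summary(maximal_loops(enumerate_loops(G))))
```

Output:

```
distinct F1 maxima: 19
{'positive': 0, 'negative': 2}
```

Nineteen distinct maxima branches mean the exploiter's oscillations are
irregular at `g = 0.28` — this is the chaotic window between the
period-doubling cascade (2–3 branches at `g ≈ 0.22–0.34`) and the simple
cycles at low and high intensity (1 branch).  The loop census says that
when the predator shifts effort onto the parasitoid and off the
exploiter, both maximal feedback loops through the foraging trait are
negative — the stabilising, perturbation-damping configuration.

The same analyses are available from the shell:

```bash
mestweb bifurcate --g-min 0.05 --g-max 0.5 --g-steps 10 --out bif.csv
mestweb stability-map --structure D --out mapD.csv
mestweb persistence --n-species 10 --beta 0.1 --g 0.28 --seed 1
mestweb loops --af-strategy promoteC_inhibitF1
```

Every run writes a JSON manifest (config, seeds, outputs) next to its
results, so any figure can be regenerated bit-identically.

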