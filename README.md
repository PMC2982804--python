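# mtlength

Stochastic simulation and analysis of microtubule-driven cell-length
homeostasis, with a synthetic-microscopy generator and the matching image
measurement procedures for cells confined to adhesive line patterns.

## The problem

Animal cells spreading on narrow adhesive lines elongate and then stop at a
reproducible steady-state length. The mechanism studied here is a tug of war
at the cell margin: a fixed pool of `N_m` dynamic microtubules nucleates at
the cell centre and grows toward the cell tips at velocity `v_g`; plus ends
that reach the cortex (the band within `w_c = 3 µm` of the boundary) push
the margin outward, while the margin retracts at a constant rate `v_B` when
no microtubule supports it. Contact with the cortex is costly: the
catastrophe rate jumps from the interior value `c_I` to the cortical value
`c_B = 16·c_I`, and a catastrophe instantly returns the microtubule to the
centre (no rescue). The boundary `L_B` (half the cell length) obeys

    dL_B/dt = v_g · exp(−α/n) − v_B,        n = |{ i : L_B − L_i ≤ w_c }|,

where `α` is a dimensionless cooperation constant (with `exp(−α/0) := 0`).
Each microtubule follows fixed-step Euler dynamics with a per-step Bernoulli
catastrophe trial of probability `Δt·c_m` (`Δt = 0.001 min`).

Because longer cells are harder to reach, the number of plus ends at the
cortex falls as the cell extends, and the cell settles where elongation
balances retraction — at roughly `n* = α / ln(v_g / v_B) ≈ 2` contacts,
independent of `N_m` and of the cell length itself. The package simulates
this model, derives its steady-state statistics (homeostasis maps over
`(N_m, α)`, density profiles, perturbation protocols, the length-vs-`v_g`
regression), provides closed-form/renewal oracles, and implements the
image-side measurements (pattern width, cell length/Feret diameter,
filament-orientation distributions, contact-angle fate classification,
intensity-calibrated microtubule counts) on ground-truthed synthetic
micrographs.

## Worked example

```python
import mtlength as mt

params = mt.make_params(seed=1)          # published defaults: v_g=15, c_I=0.3,
                                         # c_B=4.8, v_B=0.4, N_m=11, alpha=8
traj = mt.simulate(params, duration=10_000.0)
s = mt.summarize(traj, burn_in=500.0)
print(f"cell length {s.mean_length:.1f} ± {s.sd_length:.1f} µm, "
      f"mean cortical contacts {s.mean_n_B:.2f}")
print(f"flux-balance root n* = "
      f"{mt.equilibrium_contact_count(8, 15, 0.4):.2f}")
```

prints

```
cell length 36.3 ± 1.7 µm, mean cortical contacts 1.67
flux-balance root n* = 2.21
```

The cell elongates from 20 µm and plateaus within a few hours at a tightly
controlled length (coefficient of variation < 5%), maintained by fewer than
two plus ends at the cortex on average. The simulated mean contact count
sits a fraction of a microtubule below the deterministic root `n*` because
the advance factor `exp(−α/n)` is convex near `n ≈ 2`: the fluctuating
integer count balances the flux `E[exp(−α/n)] = v_B/v_g` at a slightly
lower mean. Raising the pool to `N_m = 14` lengthens the cell to ≈ 44 µm
without changing the contact count — length control is a property of the
rates, not of the pool.

A CLI wraps the same operations (`mtlength simulate|sweep|perturb|synthimg|
measure|report`, each writing a reproducibility manifest); see
`mtlength --help`.

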