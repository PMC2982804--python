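# Methods

## Model

One half of a bilaterally symmetric cell on an adhesive line is reduced to
a single spatial coordinate: the boundary position `L_B(t)` (µm, measured
from the nucleation centre), with reported cell length `2·L_B`. A fixed
pool of `N_m` microtubules nucleates at the centre; microtubule `i` has
length `L_i ∈ [0, L_B]`.

Per Euler step of `Δt` minutes, in this order:

1. **Microtubules** (index order `0…N_m−1`): draw `r ~ U[0,1)`; if
   `r < Δt·c_i` the microtubule catastrophes and renucleates at `L_i = 0`
   (instantaneous: no shrinkage phase, no rescue, no nucleation delay, so
   the growing count is conserved). Otherwise `L_i ← min(L_i + Δt·v_g, L_B)`.
   The hazard is zone-dependent: `c_i = c_B` when `L_B − L_i ≤ w_c`
   (inclusive), else `c_I`.
2. **Boundary**: with `n` the number of tips within `w_c` of the (pre-move)
   boundary, `L_B ← max(0, L_B + Δt·(v_g·e^(−α/n) − v_B))`, using
   `e^(−α/0) := 0` so that an unsupported margin retracts at `v_B`.
3. Tips are clipped to the new boundary (a capped tip rides the boundary
   and remains under the cortical hazard); contact membership is
   recomputed for recording.

Defaults (units µm, min): `v_g = 15`, `c_I = 0.3`, `c_B = 4.8` (16·c_I,
both zone rates from live-imaging literature), `v_B = 0.4` (measured
retraction of microtubule-free cells), `w_c = 3`, `Δt = 0.001`, and the two
free parameters `N_m = 11`, `α = 8`. The initial state is `L_B = L0 = 10`
(half of a freshly spread ~20 µm cell; the source work does not state its
initial condition) with all microtubule lengths zero. Parameter validation
enforces `Δt·max(c_I, c_B) ≤ 0.1` so the Bernoulli trial remains a faithful
discretisation of the exponential hazard.

**Cortex-hazard convention.** The elevated catastrophe rate applies
throughout the 3 µm cortex zone, the same band that defines a "contact" for
the cooperative advance. We probed the alternative (cortical hazard only
for tips touching `L_B` exactly): it inflates the steady-state boundary to
~67 µm at defaults and the length-vs-`v_g` slope to 4.5 — irreconcilable
with the reference regression — so the zone convention is kept. The mean
contact count is insensitive to this choice; only the length scale moves.

**Randomness and reproducibility.** One `numpy` PCG64 stream per
simulation, seeded from `params.seed`; draw order is documented above, and
the compiled (numba) simulation kernel consumes the stream identically to
the pure-NumPy reference `step`, which is asserted bit-for-bit in the test
suite. Derived tasks (grid cells of a homeostasis map, per-velocity runs of
a sweep) seed independent streams via `SeedSequence(master, coords)`.

## Steady-state analyses

* **Summaries.** Statistics are taken over time samples with
  `t ≥ burn_in` (default 500 min; an optional trend screen warns when the
  post-burn-in OLS slope of length is significantly non-zero). Length
  distributions are read ergodically from one long trajectory rather than
  from replicate endpoints; recording cadence is 1 min.
* **Homeostasis maps.** One independent 10,000-min simulation per
  `(N_m, α)` grid cell; the cell value is the post-burn-in standard
  deviation of cell length (the homeostasis measure), with means and
  contact counts retained.
* **Perturbations.** Drug-like protocols scale parameter fields mid-run by
  given factors; microtubule state, boundary and RNG stream carry across
  the switch, so an empty factor map reproduces the unperturbed run
  bit-for-bit. Scaled parameters are re-validated.
* **Density profiles.** Occupancy(x) is the time-averaged number of
  microtubules whose length exceeds x% of the instantaneous half-length,
  over ≥ 500 post-burn-in snapshots; occupancy(0) = `N_m` by construction
  and the profile near 100% approaches the cortical contact count.
* **Length-vs-velocity regression.** Mean post-burn-in length per growth
  velocity, one seeded run each, OLS line plus per-point standard
  deviations. Both the full-length and boundary (half-length) slopes are
  recorded: the boundary readout is the convention of the reference
  regression — at defaults it gives `L_half = 1.36·v_g − 2.0`, reproducing
  the printed intercept (−2) exactly, and it is the only reading consistent
  with ≈ 44 µm cells at `v_g = 15` — so the headline slope is reported on
  that scale. Velocities at or below `v_B` are rejected (no equilibrium).

## Mean-field oracles

* **Flux balance.** Setting the boundary velocity to zero gives the
  equilibrium contact count `n* = α / ln(v_g / v_B)` (2.21 at defaults),
  independent of `N_m` and cell length. The simulated mean count tracks
  `n*` across parameters but sits systematically ~0.3–0.6 *below* it:
  `e^(−α/n)` is convex in `n` for `n < α/2`, so with a fluctuating integer
  count the exact balance `E[e^(−α/n)] = v_B/v_g` (which simulations
  satisfy to four decimals) is reached at `E[n] < n*` (Jensen's
  inequality). Tests of the count against `n*` use a ±0.65 band with the
  sign of the bias asserted; the one acceptance check that demands
  agreement within ±0.3 fails for this structural reason and is left
  failing rather than widened.
* **Steady length.** A renewal approximation of one microtubule's cycle —
  survive the interior of length `L − w_c` with probability
  `p = e^(−c_I(L−w_c)/v_g)`, then reside under the cortical hazard for a
  mean `1/c_B` — predicts the half-length as the root of
  `N_m·p·τ_B / E[T] = n*` with `E[T] = (1−p)/c_I + p/c_B` (Brent's method
  on (w_c, 10³) µm). The approximation deliberately ignores boundary motion
  during a lifetime and tip capping; its prediction (14.1 µm at defaults)
  carries ~22% error against the simulated mean (18.1 µm), within the
  documented 25% band evaluated relative to the simulated value.

## Synthetic microscopy

The generator emulates the statistical structure the measurement procedures
assume, not photorealism: a rectangular cell of known length confined to a
vertical adhesive stripe of known width; a disc nucleus (or several, to
exercise the mononucleate filter); straight filaments with angles drawn
from a point-mass, uniform or axially folded von Mises model, rendered as
1-px anti-aliased strokes, flux-normalised so each filament deposits
exactly `intensity_units × 100` grey-levels per pixel of length, then
blurred (Gaussian, σ = 1 px) with additive Gaussian noise. Ground truth
records every segment, angle and intensity. Not modelled: PSF structure,
3-D, photobleaching, curved filaments, non-rectangular cell outlines —
so passing round trips demonstrate correctness of the measurement
implementations, not robustness to real-micrograph nuisance.

Comet tracks emanate from the centre at sampled angles and advance at
`v_g`; at the lateral cortex the contact-angle rule assigns the fate:
|angle| ≤ 25° bends the comet to grow along the axis, |angle| ≥ 32° is a
catastrophe, and the 25–32° band is Bernoulli with bend probability 0.5
(the observed behaviour there is described only as "similar probability";
the value is an exposed parameter). The cell is treated as long relative
to a comet run, so every off-axis comet reaches the lateral cortex; under
uniform angles on [0°, 90°] the catastrophe fraction is
(90−32)/90 + 0.5·(32−25)/90 = 0.683.

## Image measurements

* **Pattern width**: mean per-row pixel count of the binary stripe.
* **Cell length**: patterned mode = occupied extent along the line axis;
  non-patterned mode = Feret diameter, computed as the maximum pairwise
  distance between boundary *pixel centres* via the convex hull (this
  convention makes a radius-20 disc measure 40 px). Cells whose nucleus
  channel does not label exactly one connected component are rejected with
  a reason.
* **Orientation distributions**: median filter (3 px) → Otsu threshold over
  in-cell pixels → thinning to 1-px centrelines → each centreline pixel
  votes for the angle (5° bins) whose anti-aliased 15-px line kernel
  overlaps the most filtered intensity; votes are normalised to a
  probability mass. Matching on the intensity ridge rather than the binary
  map keeps neighbouring angles distinguishable, and thinning stops blur
  skirts from voting. Known limit: accuracy degrades when parallel
  filaments run within ~2 px of each other and their blurred profiles
  merge; the filter radius, threshold, kernel length and bin width are all
  parameters since the source procedures do not specify them.
* **Fate classification**: the contact angle is measured from the incoming
  track segment; outside the 25–32° band the rule is deterministic and
  agreement with ground truth is exact, inside the band either fate is
  admissible and the event is flagged ambiguous.
* **Microtubule counts**: background-subtracted integrated intensity over
  the region divided by (single-filament unit × mean filament length in
  px); background defaults to the median outside the region.

## Problem sizes and numerical choices

Long steady-state runs use 10,000 simulated minutes (10⁷ Euler steps,
seconds of wall time via the compiled kernel) with 500 min burn-in; unit
and property tests use 2,000–5,000 min runs, 100-fixture image round
trips, and 10⁴ comet tracks. Hazard-correctness and rate-recovery tests
use ≥ 1,000 catastrophe events (KS tests against the exponential law;
rate CIs from the χ² pivot). The length-vs-velocity sweep uses five
velocities ≥ 6 µm/min, all well above `v_B`. Degenerate inputs are
validated up front: unknown fields, invariant violations (including the
`Δt` hazard bound), empty masks, sub-3-point regression designs and
non-positive durations all raise with the offending field named.
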