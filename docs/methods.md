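# Methods

## The model

`lefsim` simulates loop-extruding factors (LEFs) — an abstraction of SMC
complexes such as condensin, cohesin and bacterial SMC — on a 1D lattice of
`L` sites of physical size `a` (0.5 kb for mitotic chromatin, ~1 kb for
bacterial DNA, 2 kb for interphase monomers). A LEF occupies two sites.
It binds at rate `k_bind` on a weighted random adjacent pair (the attempt
is rejected, and the event consumed, if either site is occupied), unbinds
at rate `k_unbind`, and enlarges its loop by moving *active* subunits one
site at a time, away from the partner subunit, at speed `v`. Extrusion
halts when the target site is occupied by another subunit and may resume
if the obstacle vacates. Two dimensionless ratios control everything:

* processivity over separation, `λ/d`, with `λ = q·v/k_unbind`
  (`q = 1` one-sided, `2` two-sided; for mixtures we use
  `q = 1 + fraction_two_sided`, which reduces to the pure definitions at
  the endpoints) and `d = L/N_b`, `N_b = N·k_bind/(k_bind + k_unbind)`;
* the variant-specific rate ratios `v_diff/v`, `k_switch/k_unbind` and
  `k_switch·L/v`.

Model variants: **one-sided** (one active, one anchored subunit, random or
directionally-loaded orientation), **two-sided**, **mixtures**,
**semi-diffusive** (the passive subunit random-walks with loop-entropy
biased rates `v±_diff(ℓ) = v_diff·exp(∓(3/2)·a/ℓ)`, so that
shrink/grow = `exp(3a/ℓ)`, the Boltzmann factor of the `(3/2)kT·ln ℓ` loop
entropy across one site), **switching** (active and anchored roles swap at
`k_switch`; stall flags stay with positions), **traversal** (LEFs pass
freely through one another and co-occupy sites), and **pushing** (an
active subunit displaces one — weak — or a train — strong — of passive
subunits ahead of it).

CTCF-like barriers are directional and partially permeable: a subunit
attempting to cross rolls the stall probability `p_stall` once per
(subunit, barrier, binding event); a stall is permanent until unbinding, a
pass is remembered. Terminal-unloading sites (the bacterial *ter* region)
unbind any LEF whose subunit arrives; circular bacterial chromosomes are
represented by a linear lattice whose two ends are *ter*.

## Schedulers

Two samplers of the same kinetics:

* **Event-driven (`gillespie_run`)** — continuous-time, exact. Each
  (LEF, event-type) slot draws exponential waiting times at its rate and
  events execute in temporal order from a binary heap (next-reaction
  scheme). Step slots whose move is impossible (blocked, stalled, at an
  edge, or unbound) go dormant and are woken when a neighbouring site is
  vacated, when the LEF rebinds, or when roles switch, so the cost is
  proportional to executed transitions rather than elapsed time. Slots
  with state-dependent rates (semi-diffusive steps) would need
  rate-dependent rescheduling; this scheduler therefore refuses the
  semi-diffusive model.
* **Fixed-time-step (`fixed_step_run`)** — the discrete-time chain in
  which every candidate event fires independently with probability
  `k_i·dt` per step (enforced `≤ 0.1`). `method="sweep"` is the literal
  per-step Bernoulli sweep over a fresh random permutation of LEFs (used
  for small systems, for 3D coupling — one polymer segment per LEF step —
  and for the bacterial deterministic-extruder mode, where active subunits
  step every `dt` with probability 1). `method="events"` realizes the
  identical chain law with per-slot geometric waiting times on the same
  heap; semi-diffusive rates are handled by thinning against the constant
  bounds `v_diff` (grow) and `v_diff·e^{3/4}` (shrink; the largest
  attainable bias, at the minimum shrinkable loop ℓ = 2a), evaluating the
  current loop size at each attempt — statistically exact and the only
  practical option for long semi-diffusive runs. A subunit unblocked
  during step `k` acts from step `k+1`.

Both schedulers draw from one seeded generator; identical
`(config, params, seed)` give identical trajectories.

## Compaction observables

The compacted fraction `f` is the fraction of sites inside the union of
all loops (closed intervals `[left, right]`); `FC = 1/(1−f)`. The
package's headline `fc` is the **mean of per-snapshot FC** (a fully
covered snapshot is capped at `FC = L`, the lattice resolution limit);
the transform of the averaged fraction, `1/(1−⟨f⟩)`, is always reported
alongside (`coverage_fc`) because the two estimators genuinely diverge
near complete coverage — the per-snapshot mean is heavy-tailed there and
depends on the absolute number of uncovered sites, i.e. on `L` at fixed
`λ/d`. Gaps are maximal unlooped runs strictly between consecutive
*parent* (outermost) loops; lattice ends are uncompacted but not gaps, so
`n_g/n_l` isolates the LEF-pair orientation statistics behind the
one-sided 1/4 law. The gap statistic is reported as the ratio of
time-averaged counts.

For the traversal model the observable is coverage-based
(`coverage_fc`), matching the theoretical law `FC = e^{λ/d}` for
Poisson-placed loops of exponential size. Two finite-size corrections
matter at desk scale: coverage is depleted within ~λ of the open lattice
ends (no loops reach in from outside), so coverage is measured on the
interior window excluding 3λ per end; and the uncovered fraction at
`λ/d = 7` is ~10⁻³, so snapshots are spaced a full residence time apart
over long windows (120 residence times, 5 replicates) to decorrelate the
rare-gap statistics.

## Simulated conditions (problem sizes)

Sweeps hold `v = 1` site/time and `N` fixed and tune `k_unbind`
(`k_bind = 100·k_unbind`, so ~99% of LEFs are bound and `d ≈ L/N`),
keeping run lengths uniform in residence times across a grid. Runs burn
in for 20 residence times before measurement (sampling 10 per residence
over a further 10–20 residence times, ≥3 replicates), as appropriate for
steady-state compaction.

* One-sided plateau and gap statistic: `L = 10,000`, `N = 200`
  (`d` = 25 kb at 0.5 kb/site), `λ/d ∈ {100, 300, 1000}`.
* Two-sided threshold and mixture scan: `L = 60,000`, `N = 3000` —
  `d` = 20 sites = 10 kb, the physiological LEF spacing; at this density
  the per-snapshot FC estimator is granular enough (hundreds of
  uncovered sites below threshold) for the 1000-fold crossing to be
  well-defined.
* Semi-diffusive grid: `v_diff/v ∈ {0.1, 1, 3.5}` ×
  `λ/d ∈ {100, 300, 1000}` on a reduced lattice `L = 400`, `N = 20`
  (`d` = 20 sites preserved); at `λ/d = 1000` the processivity exceeds
  the lattice, as it does at the full scale.
* Bacterial chromosome: `L = 4000` ~1 kb sites, *parS* at site 2000 with
  loading weight 40,000× every other site (overall ~10-fold preference;
  the accepted-load fraction at parS is 10/11), `k_unbind = 2/L`,
  deterministic extruders, immediate rebinding, `N = 5`, *ter* at sites
  0–3 and 3996–3999. Maps accumulate ≥10,000 snapshots spaced 50 steps.
* Interphase: repeating unit of 100/200/400-monomer TADs (2 kb/monomer)
  × 6, convergent barriers with `p_stall = 0.8` at every boundary,
  WT parameters `λ = d = 200 kb`.

## Contact maps

Bacterial and interphase maps use the equilibrium Gaussian-chain
approximation: contact probability `∝ s_eff^{−3/2}` where the effective
contour separation collapses loops innermost-first — whole loops between
two sites contribute zero (their anchors are bridged by the LEF), two
sites inside the same loop of collapsed length ℓ at collapsed separation
`s` contribute the Brownian-bridge variance `s(1−s/ℓ)` (the unique form
vanishing at both anchors), a site inside a loop contributes `t(1−t/ℓ)`
toward the anchor point, and linkers contribute their plain length.
`s_eff` is floored at one site, which caps the power-law divergence at
contact and only rescales the map. Maps are means over steady-state
snapshots, evaluated between bin-center sites, and are validated against
a Monte-Carlo oracle that draws explicit 3D Gaussian conformations with
loop anchors constrained to coincide (Brownian-bridge construction) and
counts capture-radius contacts. The approximation is for dilute
(bacterial/interphase) chromosomes, not for strongly compacted mitotic
ones. Dot strengths are means of observed-over-expected (each diagonal
divided by its mean) in a 3×3 window on TAD corner pixels; the
arm-juxtaposition ridge is quantified by the maximum and full width at
half maximum of O/E cuts perpendicular to the anti-diagonal through
*parS*, with a ridge flagged when the median center intensity exceeds
1.5 (a documented heuristic).

The "ungapped TAD" statistic offers two predicates: full loop-union
coverage of the interval strictly between the boundaries (default), or
zero effective Gaussian separation between the boundaries
(anchor-chain connectivity); the two bracket reasonable readings of
boundary-pairing through stacked loops.

## 3D polymer model

A bead-spring chain (one monomer per lattice site, diameter `b` = 30 nm
for mitotic runs) with harmonic bonds `U_b = (k/2)(r−b)²`,
`k = 2kT/δ²`, `δ = 0.1b`, between consecutive monomers and between the
two monomers each bound LEF holds; bond lists mirror the 1D state exactly
at every MD segment boundary. Excluded volume is the soft polynomial
`U_exc(r) = ε_exc·[1 + z⁶(z−1)/ε_m]`, `z = (r/σ)²·r_m`, with
`σ = 1.05b`, `r_m = 6/7`, `ε_m = 46656/823543` and `ε_exc = 1.5 kT`;
these constants make the energy and force vanish together at the cutoff
(the minimum of `z⁷−z⁶` is exactly `−ε_m` at `z = r_m`). The optional
attraction is a smooth `sin²` well of depth `ε` on `(σ, 2b)` (zero at
both edges; the shell shape is the package's own choice), off by default.

Integration is BAOAB Langevin dynamics with unit mass, `kT` and `b`,
friction γ = 0.5 (overdamped relative to chain relaxation), plus
intermittent velocity rescaling to `T` every 100 steps as a drift guard.
The MD step is quoted on the conventional 80-unit scale of openmm-style
polymer runs; in internal units it is 0.0125, i.e. `dt·ω_bond ≈ 0.18`
with `ω_bond = √(k/m)`, well inside the stable range. Coupled runs
advance 200 (interphase) or 250 (mitosis) MD steps per LEF step.
The pair interaction uses a naive O(n²) neighbour list rebuilt every 10
steps with a 0.5b skin — adequate for the desk-scale chains (hundreds to
a few thousand monomers) the package targets; full 30,000-monomer runs
would want a cell list.

Observables: alpha-shape (concave hull) volume with probe radius
`r_hull` (600 nm for mitotic analysis; Delaunay tetrahedra with
circumradius ≤ `r_hull`; `r_hull → ∞` recovers the convex hull),
voxelized hull-overlap volume at `b/2` pitch, and sister-chromatid
backbone separation ΔR (symmetrized median nearest-neighbour distance
between backbones, i.e. monomers outside all loops plus anchors). The
normalization `R_b` is exposed as a choice between the mean consecutive
backbone-monomer distance (default) and the total backbone path length —
the two candidate readings of "backbone length" — and absolute ΔR is
always reported alongside.

## Synthetic data and what the tests show

All inputs are generated by the simulator itself; there is no external
data. The bacterial and interphase presets emulate the *geometry* of the
biological systems (loading bias, unloading, barrier layout, physical
scales) but not replication, transcription, supercoiling, chemically
detailed SMC mechanics or restricted-traversal rules; passing tests
therefore establish the internal consistency of the loop-extrusion
models and their documented phenotypes, not agreement with any
particular experimental dataset (experimental Hi-C matrices can be
loaded for side-by-side comparison but are never required).

## Numerical choices and limitations

* Within-step order of simultaneous fixed-step events is a fresh uniform
  random permutation (random heap tiebreaks / shuffled sweep).
* Binding rejection (rather than resampling) keeps the effective on-rate
  honest under crowding.
* The semi-diffusive entropic bias uses the LEF's own subtended loop
  length; nesting triggers recomputation (automatic here, since rates
  are evaluated at attempt time) but does not enter the formula.
* Diffusive subunits obey the same blocking rules as active ones;
  traversal allows unlimited pass-through and co-occupancy.
* The mean-per-snapshot FC estimator is intrinsically scale-dependent
  near full coverage; quantitative thresholds quoted from it are tied to
  the stated problem sizes (see above), and `coverage_fc` is the
  scale-free alternative.
* The event-driven scheduler's dormancy bookkeeping is validated against
  a brute-force stationary-distribution enumeration on a small lattice
  (total-variation distance < 0.02) and against the literal sweep.
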