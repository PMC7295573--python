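# lefsim

Stochastic simulation of chromosome organization by loop-extruding
factors (LEFs) — the abstraction of SMC complexes (condensin, cohesin,
bacterial SMC) as two-subunit motors that enlarge chromatin loops.

Whether SMC complexes extrude loops from both sides ("two-sided") or
only one ("one-sided", with the second subunit anchored) has large
consequences for chromosome biology. `lefsim` implements the 1D lattice
models needed to explore this question quantitatively: pure one-sided
and two-sided extrusion, mixtures, semi-diffusive anchors, stochastic
role switching, mutual traversal (Z-loops) and pushing — plus the
analyses that turn trajectories into biology: linear compaction
statistics, semi-analytic Gaussian-chain contact maps, interphase
TAD/CTCF and bacterial *parS*/*ter* scenario presets, and an optional
coupled 3D bead-spring polymer model.

## The model in brief

`N` LEFs occupy pairs of sites on a lattice of `L` sites. A LEF binds
at rate `k_bind`, unbinds at `k_unbind`, and its active subunits step
away from their partner at speed `v`, stalling at occupied sites and at
directional CTCF-like barriers (probability `p_stall`, rolled once per
encounter). Behaviour is controlled by dimensionless ratios:

- `λ/d` — processivity `λ = q·v/k_unbind` (`q` = number of active
  subunits) over the mean spacing `d = L/N_b` of bound LEFs;
- `v_diff/v` — diffusive stepping rate of a semi-diffusive anchor,
  biased by loop entropy: `v±_diff(ℓ) = v_diff·exp(∓(3/2)·a/ℓ)`;
- `k_switch/k_unbind` — active/anchor role-swap rate.

Compaction is measured as the looped fraction `f` and fold compaction
`FC = 1/(1−f)`, gaps per parent loop `n_g/n_l`, and (for traversal)
loop coverage, which follows `FC = e^{λ/d}`. Contact maps come from
the equilibrium Gaussian-chain law `P ∝ s_eff^{−3/2}` with loops
collapsed into Brownian bridges (`s_eff = s(1−s/ℓ)` inside a loop).

Headline results reproduced by the test suite: one-sided extrusion
plateaus at ~10-fold linear compaction with ~0.25 gaps per loop;
two-sided extrusion passes 1000-fold near `λ/d ≈ 50`; mixtures need
>80% two-sided LEFs; fast switching (`k_switch/k_unbind ≳ 10`) and free
traversal rescue one-sided extrusion; semi-diffusive anchors do not;
two-sided or fast-switching bacterial SMCs juxtapose chromosome arms
(the Hi-C secondary diagonal) while one-sided extrusion makes a
"+"-shaped pattern.

## Worked example

```python
from lefsim import scenarios as sc

for variant, kw in [("one-sided", {}), ("two-sided", {}),
                    ("switching", {"k_switch_over_k_unbind": 30.0})]:
    s = sc.run_compaction_point(variant, 100, n_sites=10_000, n_lefs=200,
                                replicates=3, seed=1, **kw)
    print(f"{variant:10s} lambda/d=100  FC={s.fc:8.1f}  "
          f"gaps/loop={s.gaps_per_loop:.3f}")
```

prints

```
one-sided  lambda/d=100  FC=     9.3  gaps/loop=0.236
two-sided  lambda/d=100  FC=  8701.9  gaps/loop=0.003
switching  lambda/d=100  FC=  7259.1  gaps/loop=0.012
```

— the one-sided model is pinned at ~10-fold compaction by the unlooped
gaps left between divergently oriented LEF pairs (about one gap per
four parent loops), while two-sided extrusion — or one-sided extrusion
with fast role switching — eliminates gaps and compacts thousands-fold,
the level required of mitotic chromosomes.

A bacterial chromosome with a single *parS* loading site:

```python
traj, cmap = sc.build_bacterial("switching", k_switch_L_over_v=400.0,
                                n_snapshots=10_000, seed=1)
prof = sc.secondary_diagonal_profile(cmap)
print(prof["ridge_present"], round(prof["ridge_score"], 2))   # True 4.47
cmap.render_png("bacterial_map.png")
```

The fast-switching SMCs track both arms symmetrically away from *parS*,
producing the anti-diagonal ridge seen in *B. subtilis* Hi-C; with
`variant="one-sided"` the ridge is absent and only the "+"-pattern of
*parS*-anchored contacts remains.

The command line mirrors the library:

```bash
lefsim scenario bacterial --variant switching --param 400 --out map.tsv
lefsim simulate-1d run.cfg --out traj.tsv
lefsim metrics run.cfg --out summary.tsv --replicates 3
```

where `run.cfg` is a flat key-value file (`n_sites = 10000`,
`n_lefs = 200`, `k_bind = 0.02`, `k_unbind = 0.0002`, ...).

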