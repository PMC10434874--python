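# pairforce

Effective pairwise cell–cell interaction forces, inferred from 3D nuclear
tracking data — and used to predict tissue shape.

## The problem

During early embryogenesis (mouse morulae, *C. elegans* embryos), tissue
morphology is set by mechanical interactions between cells, but those forces
cannot be measured directly in live 3D tissue.  `pairforce` implements a
top-down alternative: treat cells as particles in overdamped motion
(`V_p = F_p / γ`, with `γ = 1`, so 1 force unit moves a cell at 1 µm/min),
and statistically infer the signed force of every cell–cell pair at every
frame transition by fitting the particle model to nuclear tracking data.
For each adjacent frame pair the forces `F_i` minimize the regularized cost

```
G = Σ_p |x_p(t) − x_p_ref(t)|² / Δt  +  ω_F0 Σ_i ψ(D_i) F_i² Δt
```

where predicted positions are one-step extrapolations along the pair unit
vectors, and `ψ(D)` grows exponentially from 1 at the mean cell diameter to
`α = 300` at the cutoff (3× diameter), driving unphysical long-range forces
to zero.  `G` is strictly convex, solved in closed form; restart
correlations from randomized initializations certify uniqueness.

Binned against pair distance, the inferred forces form a distance–force
(DF) curve with a repulsive core and an attractive well; integrating gives
the distance–potential (DP) curve whose well position tracks the mean cell
diameter.  Curve metrics (distance at the potential minimum, relative
distance at 10% well energy), Morse-potential fits, and per-cell-type
curves (e.g. inner vs. outer blastomeres) characterize the tissue.  Fed
back into the particle simulator, inferred curves predict aggregate
morphology, quantified by sphericity `(36πV²)^(1/3)/S` and the aspect ratio
of a moment-fitted ellipsoid.

Intended users: biophysicists and quantitative embryologists with 3D
nuclear tracking tables (any tracker, converted to the canonical CSV
dialect `frame,time_min,cell_id,parent_id,x_um,y_um,z_um[,label]`).

## Worked example

Simulate a small aggregate under a known Lennard-Jones interaction, infer
the forces back, and compare:

```python
from pairforce import InferenceConfig, infer, bin_average, normalized_l2
from pairforce.validation import make_scenario, generate, default_truth

truth = default_truth()          # LJ: r_min = 5 um, max attraction 0.003 A.U.
scenario = make_scenario("steady_state", seed=1, total_time=300.0)
dataset = generate(scenario)     # 40 cells, 1000% force fluctuations, 1-min frames

config = InferenceConfig(mean_diameter=5.0)
forces = infer(dataset, config)  # one signed force per pair per transition
curve = bin_average(forces.table, bin_width=0.5, min_count=10)
print(f"{len(forces.table)} pair forces, {curve.distances.size} bins")
print(f"normalized L2 vs truth: {normalized_l2(curve, truth):.3f}")
```

Output:

```
120914 pair forces, 22 bins
normalized L2 vs truth: 0.060
```

120 914 individual pair forces are each dominated by the simulated cells'
intrinsic force fluctuations (SD = 10× the maximum attractive force), yet
the binned curve recovers the ground-truth interaction to a mean squared
error of ~6% of the squared peak attraction over the attractive range — at
this short recording length the residual is mostly bin-sampling noise,
which shrinks with recording time.

The same machinery runs from the shell:

```
pairforce simulate --config sim.yaml --out track.csv
pairforce infer --tracking track.csv --mean-diameter 5.0 --out forces.csv
pairforce curves --forces forces.csv --out-df df.csv --out-dp dp.csv
pairforce morph --trajectory track.csv --radius 2.5
pairforce validate --suite all --seeds 3 --out report.csv
```

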