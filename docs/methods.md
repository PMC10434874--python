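# Methods

## Model

Cells in early embryos (blastomeres) are approximated as particles whose
interaction is an *effective pairwise potential*: a single center-distance
dependent energy that subsumes cell-cell adhesion (attractive), excluded
volume and cortical tension (repulsive).  In the low-Reynolds-number regime
inertia is negligible and motion is overdamped,

    V_p = F_p / gamma,

with `gamma` the drag coefficient, assumed constant and set to 1.  Forces
are therefore expressed in units that move a particle at 1 um/min per unit
force; only relative force values are identifiable.  Persistent random
walks (substrate traction) are not modeled: without attachment to a
substrate, movement is driven entirely by cell-cell forces.

Two analytic families are built in:

* Lennard-Jones, `U = eps[(r_min/D)^12 - 2(r_min/D)^6]`, parameterized by
  the well depth and the potential-minimum distance `r_min`, which plays
  the role of the mean cell diameter.  The maximum attractive force is
  `2.6899 * eps / r_min`, attained at `D = (26/7)^(1/6) r_min / 2^(1/6)`.
* Morse, `U = Ue[exp(-2a(D-De)) - 2 exp(-a(D-De))]`.

Tabulated distance-force (DF) curves close the loop: inferred curves can be
fed back into the simulator.  They interpolate linearly, return zero force
beyond their grid (consistent with the long-range regularization below) and
hold their first value below it (a coarse-grained cell core never becomes
penetrable).  DF curves integrate into distance-potential (DP) curves by
trapezoidal quadrature with `U = 0` at the far end of the grid — pair
potentials are defined up to a constant, and the curves decay to zero.

## Force inference

For each pair of adjacent frames, the unknowns are the signed scalar forces
`F_i` (positive = repulsive) of all cell pairs within a cutoff distance at
the earlier frame.  Predicted positions are one-step Euler extrapolations
of the reference positions, making the problem separable across
transitions.  The cost is

    G = sum_p |x_p(t) - x_p_ref(t)|^2 / dt
      + omega_F0 * sum_i psi(D_i) F_i^2 * dt,

a strictly convex quadratic solved in closed form (ridge normal equations,
Cholesky).  An L-BFGS minimizer started from randomized initial forces
(uniform in ±0.03 by default) is provided as a uniqueness check; for
`omega_F0 > 0` restart correlations equal 1 to numerical precision.

Without the second term the problem is typically underdetermined (the
number of pairs exceeds 3x the number of cells, and balanced "self-stress"
force patterns produce no displacement), and inferred forces fail to decay
at long range.  `psi(D) = alpha^max(0, (D-d_body)/(cutoff-d_body))` is 1 up
to the cell-body diameter and grows exponentially to `alpha` at the cutoff,
pinning long-range forces to zero.  Defaults: `alpha = 300` (the largest
value of the convergent range in our sweeps; `alpha = 1` disables the
constraint), `cutoff = 3.0 x` mean cell diameter (restart correlations stay
at 1 for multiples >= 2.8), and `omega_F0 = 1e-4`.  The ridge weight is
deliberately small: the inferred curves are insensitive to it across
1e-6..1e-3, and it only has to break the degeneracy of the null-space
modes.  We do not use the alternative rule of sizing `omega_F0` so the
penalty is a fixed fraction of the data term, because on noise-free data
the data term vanishes at the optimum and the rule degenerates.

Distances `D_i` entering both the pair construction and the penalty are
taken at the transition start, consistent with one-step prediction.

Two friction models are available: the default *absolute* model above, and
a *relative* model in which drag acts on velocity differences between
interacting neighbors, `F_p = sum_m omega_g(D_pm) gamma ((V_p - V_m).e) e`
with `omega_g = 1` by default; its target net forces are computed from the
reference velocities and decomposed onto pair axes by the same ridge fit.
For an isolated pair the two models differ by a factor of 2 in the
recovered force (one drag reference vs. two) — an intrinsic property, not
an error.

Division handling: a mother dividing between frames is mapped onto a
*virtual cell* at the centroid of her two daughters; cells that disappear
(death, tracking loss) or appear without lineage are excluded from that one
transition and logged.

## Curve extraction

Per-pair inferred forces are scattered against pair distance.  Individual
points are dominated by the cells' intrinsic force fluctuations (see
below); the systematic relationship is the binned average — unweighted mean
force per distance bin, plotted at the mean in-bin distance, bins with
fewer than `min_count = 10` points dropped, default bin width a tenth of
the cell diameter.  Curve agreement with a reference potential is scored by
the normalized L2 norm: the mean of `(F_inf - F_ref)^2 / F_ref_max^2` over
the distances where the reference attraction is at least 10% of its peak
(`F_ref_max` = maximum attractive force).

## Simulator and synthetic scenarios

Explicit Euler integration (default step: sampling interval / 30, capped at
half the fluctuation persistency; confined scenarios reduce the step
further using the local 12-6 stiffness so the scheme stays stable in
compressed packings).  Steps that would move any particle farther than 5%
of the equilibrium distance are subdivided adaptively — this only triggers
in stiff transients, e.g. when a division drops a daughter near a
neighbor's repulsive core, and leaves ordinary dynamics untouched.  Cell-intrinsic activity is modeled as per-pair
scalar force fluctuations: zero-mean Gaussians with SD equal to a
percentage of the maximum attractive force, held piecewise-constant with a
resampling period ("persistency") of 1 min.  Fluctuations live on pairs and
act along the pair axis, so momentum is conserved exactly and aggregate
centroids do not drift.  Confinement (sphere or spherocylinder — the
eggshell/zona pellucida) is enforced by projecting escaped particles to the
nearest surface point after each step.  Division replaces a mother by two
daughters placed symmetrically along a random axis, 0.8 cell diameters
apart — inside each other's attractive basin but outside the steeply
divergent core, so the post-division relaxation remains integrable at the
standard step size.

The validation scenarios use a ground-truth Lennard-Jones potential with
`r_min = 5 um` and a maximum attractive force of 0.003 A.U.  The scale is
deliberately small: with 1000% fluctuations it drives particle speeds of
~0.1 um/min, the magnitude of blastomere nuclear movements over
minutes-scale sampling, and it keeps a fluctuating aggregate cohesive
(effective temperature well below the well depth).  Scenario conditions:

| scenario              | N      | fluct SD | sampling | duration |
|-----------------------|--------|----------|----------|----------|
| assembling            | 40     | 1000% (or 0%) | 1 min | 2400 min (360 noise-free) |
| steady state          | 40     | 1000%    | 1 min (re-read at 3/5) | 2400 min |
| proliferation         | 38→47  | 1000%    | 3 min    | 2400 min |
| sphere confinement    | 64     | 1000%    | 3 min    | 480 min  |
| capsule confinement   | 54     | 1000%    | 3 min    | 480 min  |
| random walk (control) | 40     | —        | 1 min    | 100–150 frames |

Durations are sized so that each distance bin of the binned average
collects >= ~5000 scatter points; at 1000% fluctuation every point carries
noise with SD of 10x the maximum attractive force, so the bin-mean sampling
error contributes <~0.01 to the normalized L2.  The assembling box is 2x
the close-packed aggregate diameter with initial separations of at least
one cell diameter; the proliferation schedule divides nine mothers at
evenly spaced times (population 38 to 47); confined packings are placed by
rejection sampling and pre-relaxed with capped pair forces (a pure
numerical guard, never active during recorded sampling).

What the generator emulates: aggregation, fluctuation-driven steady-state
motion, divisions, rigid confinement, and sampling at realistic intervals.
What it does not: cell shape and deformation, spatially varying drag,
external factors (cavities, extracellular matrix), hysteresis of
approach/separation, and measurement noise in nuclear centroids.  Passing
validation therefore shows the inference recovers pairwise forces from
centroid kinematics under the model's own assumptions, not that real
tissues satisfy those assumptions.

## Morphology metrics

Simulated aggregates are rendered as a union of balls (radius = half the
mean cell diameter) on a voxel grid (default voxel = radius/8, required
<= radius/4).  Volume is voxel occupancy; surface area comes from the
marching-cubes iso-surface of the *distance field* at the particle radius —
meshing the smooth distance field rather than the binary occupancy avoids
the ~10% staircase overestimate of surface area.  Sphericity is
`(36 pi V^2)^(1/3) / S` (1 for a ball, within ~1.5% discretization error at
the default voxel size); the aspect ratio is the longest/shortest semi-axis
of the ellipsoid matching the solid's second moments (for a uniform
ellipsoid the second moment per axis is `a_k^2/5`).  A point-set variant
adds `r^2/5` per axis for the balls' own moments.  Component counting flags
fragmented outcomes (failed compaction).

## Numerical choices and degenerate inputs

* Coincident particles (distance 0) are an error everywhere: forces and
  unit vectors are undefined.
* Euler steps with non-finite forces fail loudly, naming the particle.
* `omega_F0 = 0` with redundant geometry raises (closed form) or is flagged
  by restart correlations < 1 (iterative path).
* Normalization and well metrics require a negative potential minimum;
  flat or purely repulsive curves are rejected.
* Morse fitting initializes from the curve's well (depth, location,
  inverse width 2/D_min) with positivity bounds; non-convergence is
  returned flagged with diagnostics rather than raised.
* The frequency map uses data-driven axis ranges unless fixed by the
  caller.

## Known limitations

* The inferred binned curve carries an irreducible sampling variance set by
  the fluctuation-to-signal ratio (10:1 at 1000%); agreement below
  normalized L2 ~0.01 requires very long recordings.
* At coarse sampling the one-step model averages over within-interval
  motion; the inferred well broadens and weakens.  The degradation is
  reproduced qualitatively (monotone in the sampling interval) but its
  magnitude depends on the force scale, which real datasets must calibrate.
* Strong compression (capsule shorter than ~4 cell diameters for 54 cells)
  freezes the packing; displacements carry no force information and the
  inferred curve collapses toward zero — reproduced here as a failure mode,
  with the normalized L2 approaching the zero-curve value ~0.3.
* gamma is constant; only relative forces are identifiable.
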