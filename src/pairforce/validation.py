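"""Synthetic validation scenarios and end-to-end harnesses.

Each scenario simulates a particle system under a known ground-truth
potential (Lennard-Jones unless overridden) and exports the sampled
trajectory as a tracking dataset, so the full pipeline -- simulate, infer
per-pair forces, bin into a DF curve, score against the truth with the
normalized L2 metric -- can be exercised with every link known.

Scenarios
---------
``assembling``
    particles scattered in a box, then relaxing into an aggregate.
``steady_state``
    a pre-relaxed aggregate agitated by force fluctuations (SD 1000% of the
    maximum attractive force, persistency 1 min) so that it keeps moving at
    statistical steady state.
``proliferation``
    an aggregate whose population grows from 38 to 47 cells through nine
    scheduled divisions.
``sphere_constraint`` / ``spherocylinder_constraint``
    fluctuating aggregates confined in rigid shells (64 particles in a
    sphere; 54 in a capsule), emulating the zona pellucida / eggshell.
``random_walk``
    interaction-free particles taking independent Gaussian steps -- the
    negative control: no distance-force relationship exists to be found.

The ground-truth LJ force scale is fixed at a maximum attractive force of
0.03 A.U. (i.e. 0.03 um/min for an isolated pair at peak attraction), with
the potential minimum at a 5 um cell diameter.

``simulate_from_curve`` is the forward direction used for morphology
prediction: relax particle configurations under a tabulated DF curve and
report sphericity / aspect ratio / connectivity of the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import simulator
from .curves import bin_average
from .inference import InferenceConfig, infer
from .morphology import MorphologyReport, morphology_report
from .potentials import (DFCurve, LennardJones, equilibrium_distance,
                         normalized_l2)
from .simulator import (SimulationConfig, SpherocylinderConstraint,
                        SphereConstraint, run)
from .tracking_io import TrackingDataset, decimate, trajectory_to_dataset

__all__ = [
    "Scenario",
    "make_scenario",
    "default_truth",
    "generate",
    "infer_l2",
    "run_validation",
    "simulate_from_curve",
    "scattered_positions",
    "cuboid_positions",
]

#: Ground-truth force scale: maximum attractive force of the LJ potential,
#: in A.U. (= um/min at gamma = 1).  With 1000% fluctuations this drives
#: particle speeds of ~0.1 um/min, the scale of blastomere nuclear movements.
TRUTH_F_MAX = 0.003
#: Mean cell diameter = LJ potential-minimum distance (um).
TRUTH_DIAMETER = 5.0

SCENARIO_NAMES = ("assembling", "steady_state", "proliferation",
                  "sphere_constraint", "spherocylinder_constraint",
                  "random_walk")


def default_truth() -> LennardJones:
    return LennardJones.from_max_attraction(TRUTH_F_MAX, r_min=TRUTH_DIAMETER)


@dataclass
class Scenario:
    name: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: object = None  # None for random_walk


def make_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Build a named scenario with its standard parameters.

    Any parameter may be overridden by keyword (e.g. ``n=20``,
    ``fluctuation_pct=0``, ``length=16.0`` for the spherocylinder).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    truth = overrides.pop("truth", None)
    if truth is None and name != "random_walk":
        truth = default_truth()
    defaults: dict = {
        "assembling": dict(n=40, fluctuation_pct=1000.0, persistency=1.0,
                           sampling_interval=1.0, total_time=2400.0,
                           box_factor=2.0),
        "steady_state": dict(n=40, fluctuation_pct=1000.0, persistency=1.0,
                             sampling_interval=1.0, total_time=2400.0,
                             relax_time=60.0),
        "proliferation": dict(n_start=38, n_end=47, fluctuation_pct=1000.0,
                              persistency=1.0, sampling_interval=3.0,
                              total_time=2400.0, relax_time=60.0),
        "sphere_constraint": dict(n=64, radius=14.5, fluctuation_pct=1000.0,
                                  persistency=1.0, sampling_interval=3.0,
                                  total_time=480.0, relax_time=30.0,
                                  dt=0.02),
        "spherocylinder_constraint": dict(n=54, radius=7.5, length=40.0,
                                          fluctuation_pct=1000.0,
                                          persistency=1.0,
                                          sampling_interval=3.0,
                                          total_time=480.0, relax_time=30.0,
                                          dt=0.02),
        "random_walk": dict(n=40, n_frames=100, step_sd=0.3,
                            sampling_interval=1.0, box=20.0),
    }[name]
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown parameters for {name!r}: {sorted(unknown)}")
    params = {**defaults, **overrides}
    return Scenario(name=name, seed=seed, params=params, truth=truth)


def _aggregate_diameter(n: int, cell_diameter: float) -> float:
    """Diameter of an n-cell close-packed aggregate (packing fraction 0.74)."""
    return cell_diameter * (n / 0.74) ** (1.0 / 3.0)


def scattered_positions(n: int, box: float, min_separation: float,
                        rng: np.random.Generator,
                        inside=None, max_tries: int = 200000) -> np.ndarray:
    """Random positions in a centered cube of side ``box`` with a minimum
    pairwise separation; ``inside`` optionally restricts to a constraint."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} particles at separation "
                f"{min_separation} in box {box}")
        cand = rng.uniform(-box / 2.0, box / 2.0, size=3)
        if inside is not None and not bool(inside.contains(cand[None, :])[0]):
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_separation:
            continue
        pts.append(cand)
    arr = np.array(pts)
    return arr - arr.mean(axis=0)


def cuboid_positions(shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    """Centered cuboid lattice, e.g. the elongated starting block used in
    forward-simulation screens."""
    nx, ny, nz = shape
    g = np.mgrid[0:nx, 0:ny, 0:nz].reshape(3, -1).T * spacing
    return g - g.mean(axis=0)


def _relaxed_blob(n: int, truth, seed: int, relax_time: float,
                  constraint=None, box: Optional[float] = None) -> np.ndarray:
    """Pack particles loosely (inside the constraint if any) and relax them
    with capped forces into a quiescent aggregate."""
    rng = np.random.default_rng(seed)
    d_eq = equilibrium_distance(truth)
    if constraint is None:
        box = box if box is not None else 1.2 * _aggregate_diameter(n, d_eq)
        min_sep = 0.85 * d_eq
        pos = scattered_positions(n, box, min_sep, rng)
    else:
        if isinstance(constraint, SphereConstraint):
            vol = 4.0 / 3.0 * np.pi * constraint.radius**3
            box = 2.0 * constraint.radius
        else:
            r, half = constraint.radius, constraint.half_axis
            vol = np.pi * r**2 * (2 * half) + 4.0 / 3.0 * np.pi * r**3
            box = 2.0 * max(r, half + r)
        # random sequential placement fills ~30% by volume comfortably
        min_sep = min(0.9 * d_eq,
                      (0.30 * vol / (n * np.pi / 6.0)) ** (1.0 / 3.0))
        pos = scattered_positions(n, box, min_sep, rng, inside=constraint)
    if relax_time <= 0:
        return pos
    # capped forces keep the overlap-relaxation step bounded regardless of
    # how deep into the 12-6 core the initial packing reaches
    cap = 100.0 * truth.f_max_attractive
    dt = min(0.01 / cap, relax_time / 10.0)
    cfg = SimulationConfig(
        potential=truth, initial_positions=pos, total_time=relax_time,
        sampling_interval=relax_time, dt=dt, fluctuation_pct=0.0,
        constraint=constraint, max_pair_force=cap,
        rng_seed=seed + 1)
    return run(cfg).final_positions()


def _stable_dt(positions: np.ndarray, potential, safety: float = 0.1,
               coordination: int = 12) -> float:
    """Euler stability bound for the current packing.

    A compressed packing sits deep in the 12-6 core where the pair stiffness
    |dF/dD| is large; the explicit Euler step must stay below
    ~2*gamma / (coordination * stiffness).  Evaluated at the tightest pair.
    """
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    d_min = float(dist.min())
    h = 1e-4 * d_min
    stiff = abs(float(potential.force(d_min - h) - potential.force(d_min + h))) / (2 * h)
    if stiff <= 0:
        return np.inf
    return safety * 2.0 / (coordination * stiff)


def generate(scenario: Scenario) -> TrackingDataset:
    """Run a scenario's recipe and return the resulting tracking dataset."""
    p = scenario.params
    seed = scenario.seed
    name = scenario.name

    if name == "random_walk":
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-p["box"] / 2, p["box"] / 2, size=(p["n"], 3))
        rows = []
        for f in range(p["n_frames"]):
            for k in range(p["n"]):
                rows.append((f, f * p["sampling_interval"], f"c{k}", "",
                             *pos[k]))
            pos = pos + rng.normal(0.0, p["step_sd"], size=pos.shape)
        table = pd.DataFrame(rows, columns=["frame", "time_min", "cell_id",
                                            "parent_id", "x_um", "y_um",
                                            "z_um"])
        return TrackingDataset(table)

    truth = scenario.truth
    d_eq = equilibrium_distance(truth)

    if name == "assembling":
        rng = np.random.default_rng(seed)
        box = p["box_factor"] * _aggregate_diameter(p["n"], d_eq)
        pos = scattered_positions(p["n"], box, d_eq, rng)
        cfg = SimulationConfig(
            potential=truth, initial_positions=pos,
            total_time=p["total_time"],
            sampling_interval=p["sampling_interval"],
            fluctuation_pct=p["fluctuation_pct"],
            fluctuation_persistency=p["persistency"],
            rng_seed=seed + 1)
        return trajectory_to_dataset(run(cfg))

    if name == "steady_state":
        pos = _relaxed_blob(p["n"], truth, seed, p["relax_time"])
        cfg = SimulationConfig(
            potential=truth, initial_positions=pos,
            total_time=p["total_time"],
            sampling_interval=p["sampling_interval"],
            fluctuation_pct=p["fluctuation_pct"],
            fluctuation_persistency=p["persistency"],
            rng_seed=seed + 1)
        return trajectory_to_dataset(run(cfg))

    if name == "proliferation":
        n0, n1 = p["n_start"], p["n_end"]
        pos = _relaxed_blob(n0, truth, seed, p["relax_time"])
        n_div = n1 - n0
        times = np.linspace(p["total_time"] / (n_div + 1),
                            p["total_time"] * n_div / (n_div + 1), n_div)
        schedule = [(float(t), None) for t in times]
        cfg = SimulationConfig(
            potential=truth, initial_positions=pos,
            total_time=p["total_time"],
            sampling_interval=p["sampling_interval"],
            fluctuation_pct=p["fluctuation_pct"],
            fluctuation_persistency=p["persistency"],
            division_schedule=schedule,
            rng_seed=seed + 1)
        return trajectory_to_dataset(run(cfg))

    if name == "sphere_constraint":
        constraint = SphereConstraint(radius=p["radius"])
    else:
        constraint = SpherocylinderConstraint(radius=p["radius"],
                                              length=p["length"])
    pos = _relaxed_blob(p["n"], truth, seed, p["relax_time"],
                        constraint=constraint)
    dt = min(p["dt"], _stable_dt(pos, truth))
    cfg = SimulationConfig(
        potential=truth, initial_positions=pos,
        total_time=p["total_time"],
        sampling_interval=p["sampling_interval"],
        dt=dt,
        fluctuation_pct=p["fluctuation_pct"],
        fluctuation_persistency=p["persistency"],
        constraint=constraint,
        rng_seed=seed + 1)
    return trajectory_to_dataset(run(cfg))


def infer_l2(dataset: TrackingDataset, truth,
             inference_config: Optional[InferenceConfig] = None,
             bin_width: Optional[float] = None,
             min_count: int = 10) -> tuple[float, DFCurve]:
    """Full inference leg: infer forces, bin into a DF curve, score it.

    Returns the normalized L2 norm against the ground-truth potential and
    the binned curve itself.  Bin width defaults to a tenth of the mean cell
    diameter.
    """
    cfg = inference_config or InferenceConfig(mean_diameter=TRUTH_DIAMETER)
    if cfg.mean_diameter is None:
        raise ValueError("inference config must set mean_diameter")
    bw = bin_width if bin_width is not None else cfg.mean_diameter / 10.0
    table = infer(dataset, cfg)
    curve = bin_average(table.table, bw, min_count)
    return normalized_l2(curve, truth), curve


def run_validation(scenarios: Sequence[Scenario],
                   inference_config: Optional[InferenceConfig] = None,
                   subsample: Sequence[int] = (1,)) -> pd.DataFrame:
    """Generate each scenario, run inference, and tabulate L2 scores.

    ``subsample`` re-scores each generated recording at coarser sampling
    intervals (frame decimation factors), mirroring the sampling-interval
    sweeps of the synthetic validation.
    """
    rows = []
    for sc in scenarios:
        if sc.truth is None:
            raise ValueError("run_validation needs a ground-truth potential")
        ds = generate(sc)
        for every in subsample:
            sub = ds if every == 1 else decimate(ds, every)
            l2, _ = infer_l2(sub, sc.truth, inference_config)
            rows.append({
                **{k: v for k, v in sc.params.items() if np.isscalar(v)},
                "scenario": sc.name, "seed": sc.seed,
                "sampling_interval": sub.frame_interval,
                "n_cells_final": len(sub.frame_data(sub.frames[-1])[0]),
                "l2": l2,
            })
    return pd.DataFrame(rows)


def simulate_from_curve(df: DFCurve, initial: str = "cuboid",
                        n: int = 32, total_time: float = 500.0,
                        sampling_interval: float = 10.0,
                        dt: Optional[float] = None,
                        fluctuation_pct: float = 0.0,
                        seed: int = 0,
                        positions: Optional[np.ndarray] = None,
                        ) -> tuple[simulator.Trajectory, MorphologyReport]:
    """Relax particles under a tabulated DF curve and measure the outcome.

    ``initial`` is one of ``cuboid`` (elongated lattice block),
    ``scattered``, ``two_clusters`` or ``custom`` (then ``positions`` must
    be given).  Returns the trajectory and the morphology report (sphericity,
    aspect ratio, component count) of the final configuration, with the
    particle radius set to half the curve's equilibrium distance.
    """
    if np.min(df.forces) >= 0:
        import warnings

        warnings.warn("DF curve has no attractive well; particles will not "
                      "aggregate", stacklevel=2)
    d_eq = equilibrium_distance(df)
    rng = np.random.default_rng(seed)
    if initial == "custom":
        if positions is None:
            raise ValueError("custom initial configuration needs positions")
        pos = np.asarray(positions, dtype=float)
    elif initial == "cuboid":
        nx = int(np.ceil(n ** (1 / 3))) + 1
        ny = int(np.ceil(np.sqrt(n / nx)))
        nz = int(np.ceil(n / (nx * ny)))
        pos = cuboid_positions((nx, ny, nz), d_eq)[:n]
    elif initial == "scattered":
        box = 1.6 * _aggregate_diameter(n, d_eq)
        pos = scattered_positions(n, box, 0.9 * d_eq, rng)
    elif initial == "two_clusters":
        half = n // 2
        blob1 = scattered_positions(half, 1.2 * _aggregate_diameter(half, d_eq),
                                    0.85 * d_eq, rng)
        blob2 = scattered_positions(n - half,
                                    1.2 * _aggregate_diameter(n - half, d_eq),
                                    0.85 * d_eq, rng)
        offset = np.array([2.5 * _aggregate_diameter(half, d_eq), 0.0, 0.0])
        pos = np.vstack([blob1 - offset / 2, blob2 + offset / 2])
    else:
        raise ValueError(f"unknown initial configuration {initial!r}")
    cfg = SimulationConfig(
        potential=df, initial_positions=pos, total_time=total_time,
        sampling_interval=sampling_interval, dt=dt,
        fluctuation_pct=fluctuation_pct, rng_seed=seed + 1)
    traj = run(cfg)
    report = morphology_report(traj.final_positions(), radius=d_eq / 2.0)
    return traj, report
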