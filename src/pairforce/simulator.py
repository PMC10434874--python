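"""Overdamped particle dynamics under a pairwise potential.

Motion is inertia-free (low Reynolds number): each particle's velocity is its
net force divided by a drag coefficient, V = F/gamma, integrated with an
explicit Euler scheme.  The net force on a particle is the sum, over all
pairs within a cutoff distance, of the signed scalar pair force (from the
potential plus a per-pair fluctuation term) applied along the pair axis --
equal and opposite on the two partners, so total momentum is conserved
exactly and the aggregate centroid does not drift in unconstrained runs.

Cell-intrinsic mechanical activity is modeled as per-pair force fluctuations:
zero-mean Gaussian scalars with a standard deviation given as a percentage of
the potential's maximum attractive force, held piecewise-constant and
resampled synchronously with a holding time ("persistency").  Without such
activity a relaxed aggregate stops moving.

Optional features: cell division (a mother is replaced by two daughters
placed symmetrically about her position along a random axis), and rigid
confinement (sphere or spherocylinder, emulating the zona pellucida or
eggshell) enforced by projecting escaped particles back to the nearest point
of the constraint surface after each Euler step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .potentials import equilibrium_distance

__all__ = [
    "SphereConstraint",
    "SpherocylinderConstraint",
    "SimulationConfig",
    "Trajectory",
    "net_forces",
    "step",
    "sample_fluctuations",
    "divide",
    "run",
    "total_potential_energy",
]


@dataclass(frozen=True)
class SphereConstraint:
    """Rigid spherical shell of given radius centered at ``center``."""

    radius: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def project(self, positions: np.ndarray) -> np.ndarray:
        """Move particles outside the sphere to the nearest surface point."""
        x = np.atleast_2d(np.asarray(positions, dtype=float))
        c = np.asarray(self.center, dtype=float)
        rel = x - c
        r = np.linalg.norm(rel, axis=1)
        out = r > self.radius
        if np.any(out):
            x = x.copy()
            x[out] = c + rel[out] * (self.radius / r[out])[:, None]
        return x.reshape(np.shape(positions))

    def contains(self, positions: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(positions, dtype=float))
        r = np.linalg.norm(x - np.asarray(self.center), axis=1)
        return r <= self.radius * (1.0 + 1e-12)


@dataclass(frozen=True)
class SpherocylinderConstraint:
    """Capsule-shaped shell: a cylinder with hemispherical caps.

    ``length`` is the end-to-end length (caps included), so the cylindrical
    segment has half-length max(length/2 - radius, 0); with length <= 2*radius
    the capsule degenerates to a sphere.  The axis is z through the origin.
    """

    radius: float
    length: float

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be > 0")

    @property
    def half_axis(self) -> float:
        return max(self.length / 2.0 - self.radius, 0.0)

    def _axis_point(self, positions: np.ndarray) -> np.ndarray:
        a = np.zeros_like(positions)
        a[:, 2] = np.clip(positions[:, 2], -self.half_axis, self.half_axis)
        return a

    def project(self, positions: np.ndarray) -> np.ndarray:
        """Nearest-surface projection of particles outside the capsule."""
        x = np.atleast_2d(np.asarray(positions, dtype=float))
        a = self._axis_point(x)
        rel = x - a
        r = np.linalg.norm(rel, axis=1)
        out = r > self.radius
        if np.any(out):
            x = x.copy()
            # a particle exactly on the axis has no unique radial direction;
            # that cannot occur for out-of-capsule points (r > radius > 0)
            x[out] = a[out] + rel[out] * (self.radius / r[out])[:, None]
        return x.reshape(np.shape(positions))

    def contains(self, positions: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(positions, dtype=float))
        r = np.linalg.norm(x - self._axis_point(x), axis=1)
        return r <= self.radius * (1.0 + 1e-12)


@dataclass
class SimulationConfig:
    """Recipe for a simulation run.

    Times are minutes, distances um.  ``dt`` defaults to
    ``sampling_interval / 30`` (and is additionally capped at half the
    fluctuation persistency so the piecewise-constant noise is resolved).
    ``fluctuation_pct`` is the SD of the per-pair fluctuation force as a
    percentage of the potential's maximum attractive force.
    ``division_schedule`` is a sequence of (time_min, mother_id); mother_id
    may be None to let the run pick a random living cell.
    ``max_pair_force`` optionally clamps the magnitude of the deterministic
    pair force -- a numerical guard used when relaxing overlapping initial
    packings, never during production sampling.
    ``max_step_displacement`` (um, default 5% of the equilibrium distance)
    bounds how far any particle may move in one Euler step: steps that would
    exceed it are subdivided adaptively.  This only activates in stiff
    transients -- e.g. right after a division drops a daughter close to a
    neighbor's 12-6 core -- and leaves ordinary dynamics untouched.
    """

    potential: object
    initial_positions: np.ndarray
    total_time: float
    sampling_interval: float = 1.0
    dt: Optional[float] = None
    gamma: float = 1.0
    fluctuation_pct: float = 0.0
    fluctuation_persistency: float = 1.0
    cutoff: Optional[float] = None
    constraint: object = None
    division_schedule: Sequence = ()
    division_separation: Optional[float] = None
    max_pair_force: Optional[float] = None
    max_step_displacement: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self):
        self.initial_positions = np.asarray(self.initial_positions, dtype=float)
        if self.initial_positions.ndim != 2 or self.initial_positions.shape[1] != 3:
            raise ValueError("initial_positions must be (N, 3)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.fluctuation_pct < 0:
            raise ValueError("fluctuation_pct must be >= 0")
        if self.fluctuation_persistency <= 0:
            raise ValueError("fluctuation_persistency must be > 0")
        if self.sampling_interval <= 0 or self.total_time <= 0:
            raise ValueError("sampling_interval and total_time must be > 0")
        if self.dt is not None and self.dt > self.sampling_interval:
            raise ValueError("dt must not exceed sampling_interval")

    def resolved_dt(self) -> float:
        dt = self.dt if self.dt is not None else self.sampling_interval / 30.0
        if self.fluctuation_pct > 0:
            dt = min(dt, self.fluctuation_persistency / 2.0)
        # land exactly on sampling times
        n_sub = max(1, round(self.sampling_interval / dt))
        return self.sampling_interval / n_sub

    def resolved_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        return 3.0 * equilibrium_distance(self.potential)

    def resolved_separation(self) -> float:
        if self.division_separation is not None:
            return self.division_separation
        return 0.8 * equilibrium_distance(self.potential)

    def resolved_max_step(self) -> float:
        if self.max_step_displacement is not None:
            return self.max_step_displacement
        return 0.05 * equilibrium_distance(self.potential)


@dataclass
class Trajectory:
    """Sampled output of a run: per-frame times, positions and cell ids,
    plus lineage links and an event log (divisions, constraint projections)."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    parents: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def add_frame(self, time, positions, cell_ids) -> None:
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("cell ids must be unique within a frame")
        self.times.append(float(time))
        self.positions.append(np.array(positions, dtype=float))
        self.cell_ids.append(list(cell_ids))

    def final_positions(self) -> np.ndarray:
        return self.positions[-1]


def _pair_geometry(positions: np.ndarray):
    """Full pairwise displacement/distance matrices; raises on coincidence."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    n = positions.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] < 1e-12):
        i, j = np.argwhere((dist < 1e-12) & off)[0]
        raise ValueError(f"coincident particles {i} and {j} (distance 0)")
    return diff, dist


def net_forces(positions: np.ndarray, potential, cutoff: float,
               fluctuations: Optional[np.ndarray] = None,
               max_pair_force: Optional[float] = None) -> np.ndarray:
    """Per-particle net force vectors from pairwise interactions.

    For every unordered pair within ``cutoff`` the scalar force is the
    potential's value at the pair distance plus the pair's entry of the
    (symmetric, zero-diagonal) ``fluctuations`` matrix; it acts along the
    pair axis, equal and opposite on the two particles.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        return np.zeros_like(positions)
    diff, dist = _pair_geometry(positions)
    off = ~np.eye(n, dtype=bool)
    within = off & (dist <= cutoff)
    safe = np.where(off, dist, 1.0)
    scalar = np.zeros((n, n))
    scalar[within] = potential.force(safe[within])
    if max_pair_force is not None:
        np.clip(scalar, -max_pair_force, max_pair_force, out=scalar)
    if fluctuations is not None:
        scalar = np.where(within, scalar + fluctuations, 0.0)
    else:
        scalar[~within] = 0.0
    # positive (repulsive) scalar pushes p away from q along (x_p - x_q)
    unit = diff / safe[:, :, None]
    return np.einsum("pq,pqk->pk", scalar, unit)


def step(positions: np.ndarray, forces: np.ndarray, dt: float,
         gamma: float = 1.0, constraint=None) -> np.ndarray:
    """One explicit Euler update x <- x + dt*F/gamma, then constraint
    projection."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        bad = int(np.nonzero(~np.all(np.isfinite(forces), axis=1))[0][0])
        raise FloatingPointError(f"non-finite force on particle {bad}")
    new = np.asarray(positions, dtype=float) + dt * forces / gamma
    if constraint is not None:
        new = constraint.project(new)
    return new


def sample_fluctuations(n: int, pct: float, force_scale: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Fresh symmetric zero-diagonal matrix of pair fluctuation forces.

    Entries are N(0, sd) with sd = (pct/100) * force_scale, where
    ``force_scale`` is the potential's maximum attractive force.
    """
    if pct < 0:
        raise ValueError("pct must be >= 0")
    if pct == 0 or n < 2:
        return np.zeros((n, n))
    sd = pct / 100.0 * force_scale
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.normal(0.0, sd, size=iu[0].size)
    m[iu] = vals
    m.T[iu] = vals
    return m


def divide(positions: np.ndarray, cell_ids: list, parents: dict,
           mother_id: str, separation: float, rng: np.random.Generator,
           next_serial: int) -> tuple[np.ndarray, list, int]:
    """Replace a mother with two daughters placed symmetrically about her
    position along a uniformly random axis, ``separation`` apart.

    Returns the new position array, new id list and the updated serial
    counter; lineage links are recorded in ``parents`` (modified in place).
    """
    if mother_id not in cell_ids:
        raise KeyError(f"unknown mother cell {mother_id!r}")
    i = cell_ids.index(mother_id)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    offset = 0.5 * separation * axis
    d1 = f"c{next_serial}"
    d2 = f"c{next_serial + 1}"
    mother_pos = positions[i]
    keep = np.ones(len(cell_ids), dtype=bool)
    keep[i] = False
    new_positions = np.vstack([positions[keep], mother_pos + offset,
                               mother_pos - offset])
    new_ids = [cid for k, cid in enumerate(cell_ids) if keep[k]] + [d1, d2]
    parents[d1] = mother_id
    parents[d2] = mother_id
    return new_positions, new_ids, next_serial + 2


def total_potential_energy(positions: np.ndarray, potential,
                           cutoff: float) -> float:
    """Sum of pair potential energies within the cutoff (diagnostic)."""
    _, dist = _pair_geometry(np.asarray(positions, dtype=float))
    iu = np.triu_indices(dist.shape[0], k=1)
    d = dist[iu]
    d = d[d <= cutoff]
    if d.size == 0:
        return 0.0
    return float(np.sum(potential.potential(d)))


def run(config: SimulationConfig) -> Trajectory:
    """Integrate a configured run and return the sampled trajectory.

    Frames are recorded every ``sampling_interval``; the integration step and
    the fluctuation-resampling clock subdivide it exactly, so runs are
    bit-reproducible for a given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    dt = config.resolved_dt()
    cutoff = config.resolved_cutoff()
    separation = config.resolved_separation()
    max_step = config.resolved_max_step()
    pot = config.potential
    force_scale = pot.f_max_attractive if config.fluctuation_pct > 0 else 0.0

    positions = config.initial_positions.copy()
    cell_ids = [f"c{i}" for i in range(positions.shape[0])]
    next_serial = positions.shape[0]
    parents: dict = {}

    schedule = sorted(
        [(float(t), mid) for t, mid in config.division_schedule],
        key=lambda tm: tm[0],
    )
    sched_idx = 0

    traj = Trajectory(parents=parents)
    traj.add_frame(0.0, positions, cell_ids)

    n_sub = max(1, round(config.sampling_interval / dt))
    n_frames = int(round(config.total_time / config.sampling_interval))
    resample_every = max(1, round(config.fluctuation_persistency / dt))

    fluct = sample_fluctuations(len(cell_ids), config.fluctuation_pct,
                                force_scale, rng)
    global_step = 0
    for frame in range(n_frames):
        for sub in range(n_sub):
            t_now = (frame * n_sub + sub) * dt
            # apply scheduled divisions that have come due
            while sched_idx < len(schedule) and schedule[sched_idx][0] <= t_now:
                _, mother = schedule[sched_idx]
                if mother is None:
                    mother = cell_ids[int(rng.integers(len(cell_ids)))]
                positions, cell_ids, next_serial = divide(
                    positions, cell_ids, parents, mother, separation, rng,
                    next_serial)
                traj.events.append(("division", t_now, mother))
                fluct = sample_fluctuations(len(cell_ids),
                                            config.fluctuation_pct,
                                            force_scale, rng)
                sched_idx += 1
            if config.fluctuation_pct > 0 and global_step % resample_every == 0:
                fluct = sample_fluctuations(len(cell_ids),
                                            config.fluctuation_pct,
                                            force_scale, rng)
            remaining = dt
            while remaining > 0.0:
                forces = net_forces(
                    positions, pot, cutoff,
                    fluctuations=fluct if config.fluctuation_pct > 0 else None,
                    max_pair_force=config.max_pair_force)
                v_max = float(np.max(np.linalg.norm(forces, axis=1))) \
                    / config.gamma
                if v_max * remaining <= max_step:
                    dt_sub = remaining
                else:
                    dt_sub = max_step / v_max
                positions = step(positions, forces, dt_sub, config.gamma,
                                 config.constraint)
                remaining -= dt_sub
            global_step += 1
        traj.add_frame((frame + 1) * config.sampling_interval, positions,
                       cell_ids)
    return traj
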