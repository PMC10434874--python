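import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pairforce.potentials import LennardJones
from pairforce.simulator import (SimulationConfig, SphereConstraint,
                                 SpherocylinderConstraint, divide, net_forces,
                                 run, sample_fluctuations, step,
                                 total_potential_energy)

LJ = LennardJones(epsilon=1.0, r_min=5.0)


def brute_force_net(positions, potential, cutoff, fluct=None):
    """O(N^2) double-loop oracle for the vectorized force summation."""
    n = len(positions)
    out = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d_vec = positions[i] - positions[j]
            d = np.linalg.norm(d_vec)
            if d <= cutoff:
                f = float(potential.force(d))
                if fluct is not None:
                    f += fluct[i, j]
                out[i] += f * d_vec / d
    return out


class TestNetForces:
    def test_pair_at_equilibrium_feels_nothing(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        f = net_forces(pos, LJ, cutoff=15.0)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_total_force_vanishes_with_fluctuations(self, rng):
        # jittered lattice keeps pairs out of the divergent 12-6 core so the
        # cancellation can be asserted near machine precision
        grid = np.mgrid[0:3, 0:2, 0:2].reshape(3, -1).T * 5.5
        pos = grid + rng.normal(0, 0.3, size=grid.shape)
        fluct = sample_fluctuations(len(pos), 1000.0, LJ.f_max_attractive, rng)
        f = net_forces(pos, LJ, cutoff=10.0, fluctuations=fluct)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        pos = rng.uniform(0, 10, size=(5, 3))
        fluct = sample_fluctuations(5, 500.0, LJ.f_max_attractive, rng)
        got = net_forces(pos, LJ, cutoff=8.0, fluctuations=fluct)
        want = brute_force_net(pos, LJ, cutoff=8.0, fluct=fluct)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_coincident_particles_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            net_forces(pos, LJ, cutoff=10.0)


class TestStep:
    def test_zero_force_leaves_positions(self):
        pos = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(step(pos, np.zeros_like(pos), dt=1.0), pos)

    def test_unit_force_moves_one_micron_per_minute(self):
        # the force unit: 1 A.U. moves a particle at 1 um/min for gamma = 1
        pos = np.zeros((1, 3))
        new = step(pos, np.array([[1.0, 0, 0]]), dt=1.0, gamma=1.0)
        assert np.allclose(new, [[1.0, 0, 0]])

    def test_non_finite_force_names_particle(self):
        with pytest.raises(FloatingPointError, match="particle 1"):
            step(np.zeros((2, 3)),
                 np.array([[0.0, 0, 0], [np.nan, 0, 0]]), dt=0.1)

    def test_two_particle_relaxation_follows_ode_oracle(self):
        # 1-D oracle: dD/dt = 2 F(D) / gamma for an isolated pair
        d0, t_end = 4.0, 30.0
        sol = solve_ivp(lambda t, d: 2.0 * LJ.force(d[0]), (0, t_end), [d0],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        pos = np.array([[0.0, 0, 0], [d0, 0, 0]])
        cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                               total_time=t_end, sampling_interval=1.0,
                               dt=0.002, rng_seed=0)
        traj = run(cfg)
        dists = [np.linalg.norm(p[1] - p[0]) for p in traj.positions]
        assert np.all(np.diff(dists) >= -1e-12)  # monotone approach
        assert dists[-1] == pytest.approx(float(sol.y[0, -1]), abs=5e-3)
        assert dists[-1] == pytest.approx(LJ.r_min, abs=0.05)


class TestFluctuations:
    def test_zero_percent_is_silent(self, rng):
        m = sample_fluctuations(10, 0.0, 1.0, rng)
        assert np.all(m == 0.0)

    def test_negative_percent_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_fluctuations(4, -1.0, 1.0, rng)

    def test_monte_carlo_sd_matches_specification(self):
        # SD = (pct/100) * |F_max|: 1000% of 0.003 -> 0.03
        rng = np.random.default_rng(5)
        draws = []
        for _ in range(40):
            m = sample_fluctuations(24, 1000.0, 0.003, rng)
            draws.append(m[np.triu_indices(24, k=1)])
        sd = np.std(np.concatenate(draws))
        assert sd == pytest.approx(10 * 0.003, rel=0.03)

    def test_symmetry_and_zero_diagonal(self, rng):
        m = sample_fluctuations(8, 100.0, 1.0, rng)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)

    def test_holding_time_sets_resampling_cadence(self):
        # piecewise-constant noise: within one persistency window the scalar
        # pair force (hence the step length) of an isolated far-apart pair is
        # constant, and it jumps between windows
        pos = np.array([[0.0, 0, 0], [80.0, 0, 0]])
        cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                               total_time=4.0, sampling_interval=0.25,
                               dt=0.25, fluctuation_pct=1000.0,
                               fluctuation_persistency=1.0, cutoff=200.0,
                               max_step_displacement=np.inf,
                               rng_seed=3)
        traj = run(cfg)
        x = np.array([p[0] for p in traj.positions])
        steps = np.linalg.norm(np.diff(x, axis=0), axis=1)
        # four sub-steps per holding window share one force magnitude
        # (the deterministic LJ part at D ~ 80 um is ~1e-9 and negligible)
        for k in range(0, 16, 4):
            assert np.allclose(steps[k:k + 4], steps[k], rtol=1e-6)
        window_means = steps.reshape(4, 4).mean(axis=1)
        assert np.std(window_means) > 1e-3  # distinct windows differ


class TestConstraints:
    def test_inside_points_unchanged(self):
        s = SphereConstraint(radius=5.0)
        pts = np.array([[1.0, 1, 1], [0, 0, 4.9]])
        assert np.array_equal(s.project(pts), pts)

    def test_radial_projection(self):
        s = SphereConstraint(radius=3.0)
        out = s.project(np.array([[6.0, 0, 0]]))
        assert np.allclose(out, [[3.0, 0, 0]])

    def test_spherocylinder_projection_matches_surface_sampling(self, rng):
        c = SpherocylinderConstraint(radius=2.0, length=10.0)
        # brute-force oracle: nearest point among a dense surface sampling
        theta = rng.uniform(0, 2 * np.pi, 120000)
        z = rng.uniform(-c.half_axis, c.half_axis, 120000)
        cyl = np.stack([c.radius * np.cos(theta), c.radius * np.sin(theta), z],
                       axis=1)
        phi = np.arccos(rng.uniform(-1, 1, 120000))
        psi_ang = rng.uniform(0, 2 * np.pi, 120000)
        caps = np.stack([c.radius * np.sin(phi) * np.cos(psi_ang),
                         c.radius * np.sin(phi) * np.sin(psi_ang),
                         c.radius * np.cos(phi)], axis=1)
        caps[:, 2] += np.where(caps[:, 2] >= 0, c.half_axis, -c.half_axis)
        surface = np.vstack([cyl, caps])
        for pt in ([0.0, 0.0, 9.0], [3.0, 0.0, 6.0], [4.0, 4.0, 0.0]):
            pt = np.array(pt)
            got = c.project(pt[None, :])[0]
            nearest = surface[np.argmin(np.linalg.norm(surface - pt, axis=1))]
            assert np.linalg.norm(got - nearest) < 0.03

    def test_projection_idempotent(self, rng):
        c = SpherocylinderConstraint(radius=2.0, length=9.0)
        pts = rng.uniform(-8, 8, size=(50, 3))
        once = c.project(pts)
        assert np.allclose(c.project(once), once)
        assert np.all(c.contains(once))

    def test_degenerate_capsule_is_sphere(self):
        c = SpherocylinderConstraint(radius=5.0, length=8.0)
        assert c.half_axis == 0.0
        out = c.project(np.array([[0.0, 0, 10.0]]))
        assert np.allclose(out, [[0.0, 0, 5.0]])


class TestDivision:
    def test_daughters_flank_mother_centroid(self, rng):
        pos = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        ids = ["c0", "c1"]
        parents = {}
        new_pos, new_ids, serial = divide(pos, ids, parents, "c1",
                                          separation=2.0, rng=rng,
                                          next_serial=2)
        assert len(new_ids) == 3 and serial == 4
        d1, d2 = new_pos[-2], new_pos[-1]
        assert np.allclose((d1 + d2) / 2, [7.0, 0, 0])
        assert np.linalg.norm(d1 - d2) == pytest.approx(2.0)
        assert parents == {"c2": "c1", "c3": "c1"}

    def test_unknown_mother(self, rng):
        with pytest.raises(KeyError):
            divide(np.zeros((1, 3)), ["c0"], {}, "nope", 1.0, rng, 1)


class TestRun:
    def test_same_seed_is_bit_identical(self):
        pos = np.array([[0.0, 0, 0], [6.0, 0, 0], [0, 6.0, 0]])
        cfg = dict(potential=LJ, initial_positions=pos, total_time=5.0,
                   sampling_interval=1.0, fluctuation_pct=500.0,
                   rng_seed=42)
        a = run(SimulationConfig(**cfg))
        b = run(SimulationConfig(**cfg))
        for pa, pb in zip(a.positions, b.positions):
            assert np.array_equal(pa, pb)

    def test_centroid_is_conserved_without_constraint(self, rng):
        pos = rng.uniform(0, 15, size=(20, 3))
        cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                               total_time=20.0, sampling_interval=1.0,
                               fluctuation_pct=1000.0, rng_seed=9)
        traj = run(cfg)
        drift = np.linalg.norm(traj.positions[-1].mean(axis=0)
                               - pos.mean(axis=0))
        assert drift < 1e-9

    def test_energy_descends_without_fluctuations(self, rng):
        pos = rng.uniform(0, 11, size=(10, 3))
        # reject overlapping starts for a clean relaxation
        while True:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 4.0:
                break
            pos = rng.uniform(0, 11, size=(10, 3))
        cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                               total_time=10.0, sampling_interval=0.5,
                               dt=0.005, rng_seed=0)
        traj = run(cfg)
        energies = [total_potential_energy(p, LJ, 15.0)
                    for p in traj.positions]
        assert np.all(np.diff(energies) <= 1e-10)

    def test_first_order_step_size_convergence(self):
        pos = np.array([[0.0, 0, 0], [4.2, 0, 0], [0, 4.5, 0]])
        finals = {}
        for dt in (0.1, 0.05, 0.025):
            cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                                   total_time=2.0, sampling_interval=2.0,
                                   dt=dt, max_step_displacement=np.inf,
                                   rng_seed=0)
            finals[dt] = run(cfg).final_positions()
        err_coarse = np.abs(finals[0.1] - finals[0.025]).max()
        err_fine = np.abs(finals[0.05] - finals[0.025]).max()
        assert err_fine < err_coarse

    def test_scheduled_divisions_grow_population(self, rng):
        pos = rng.uniform(0, 10, size=(4, 3)) * 2
        cfg = SimulationConfig(potential=LJ, initial_positions=pos,
                               total_time=6.0, sampling_interval=1.0,
                               division_schedule=[(2.0, "c0"), (4.0, None)],
                               rng_seed=1)
        traj = run(cfg)
        assert len(traj.cell_ids[-1]) == 6
        assert len(traj.parents) == 4
        assert [e[0] for e in traj.events] == ["division", "division"]
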