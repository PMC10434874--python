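"""Statistical inference of effective pairwise forces from tracking data.

For each pair of adjacent frames, the overdamped particle model predicts the
position of particle p one step ahead of its reference position,

    x_p(t) = x_p_ref(t - dt) + dt * (sum_i +/- F_i e_i) / gamma,

where the unknowns F_i are the signed scalar forces of all cell-cell pairs
within a cutoff distance (positive = repulsive) and e_i the pair unit
vectors at t - dt.  The forces minimize the regularized cost

    G = G_xyz + G_F0,
    G_xyz = sum_p |x_p(t) - x_p_ref(t)|^2 / dt,
    G_F0  = omega_F0 * sum_i psi(D_i) * F_i^2 * dt,

where psi(D) is a distance-dependent weight that grows exponentially from 1
at the mean cell-body diameter to ``alpha`` at the cutoff, driving inferred
long-range forces to zero (without it, forces fail to decay at long range).
G is a strictly convex quadratic in {F_i} for omega_F0 > 0, so each
transition has a unique minimizer obtained in closed form (ridge normal
equations).  An iterative minimizer started from randomized initial force
values is provided as a uniqueness/consistency check.

Two friction models are supported: the *absolute* model above (drag against
a non-moving medium, V = F/gamma) and a *relative* model in which drag acts
on velocity differences between interacting neighbors,

    F_C|p = sum_m omega_g(D_pm) * gamma * ((V_p - V_m) . e_pm) e_pm,

whose target net forces are computed from the reference velocities and then
decomposed onto pair axes by the same ridge fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve as linalg_solve
from scipy.spatial import cKDTree

from .tracking_io import TrackingDataset, TransitionProblem, build_transitions

__all__ = [
    "InferenceConfig",
    "PairSet",
    "TransitionSolution",
    "InferredForceTable",
    "build_pairs",
    "psi",
    "solve_transition",
    "infer",
    "uniqueness_check",
]

#: Default ridge weight.  Calibrated once on the noise-free Lennard-Jones
#: assembling benchmark so that the penalty term G_F0 is ~1% of the data term
#: G_xyz at the optimum; small enough not to bias well-constrained forces,
#: large enough to pin down redundant directions.
DEFAULT_OMEGA_F0 = 1e-4


@dataclass
class InferenceConfig:
    """Parameters of the force inference.

    ``mean_diameter`` (um) sets the cell-body scale for the psi weight and,
    multiplied by ``cutoff_multiple``, the pair cutoff.  ``psi_alpha`` is the
    weight's value at the cutoff (alpha = 1 disables the distance-dependent
    constraint).
    """

    gamma: float = 1.0
    omega_f0: float = DEFAULT_OMEGA_F0
    psi_alpha: float = 300.0
    cutoff_multiple: float = 3.0
    mean_diameter: Optional[float] = None
    friction_model: str = "absolute"
    omega_g: Optional[Callable[[np.ndarray], np.ndarray]] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.omega_f0 < 0:
            raise ValueError("omega_f0 must be >= 0")
        if self.cutoff_multiple <= 1:
            raise ValueError("cutoff_multiple must be > 1")
        if self.friction_model not in ("absolute", "relative"):
            raise ValueError("friction_model must be 'absolute' or 'relative'")
        if self.psi_alpha < 1:
            raise ValueError("psi_alpha must be >= 1")


@dataclass
class PairSet:
    """Unordered cell pairs within the cutoff at the transition's start.

    ``units[i]`` points from member ``b`` to member ``a``; a positive
    (repulsive) force pushes ``a`` along +e and ``b`` along -e.
    """

    idx_a: np.ndarray
    idx_b: np.ndarray
    distances: np.ndarray
    units: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.idx_a.size


def build_pairs(positions: np.ndarray, cutoff: float) -> PairSet:
    """All unordered pairs with center distance <= cutoff."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 cells to build pairs")
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return PairSet(np.empty(0, int), np.empty(0, int),
                       np.empty(0), np.empty((0, 3)))
    a, b = pairs[:, 0], pairs[:, 1]
    diff = positions[a] - positions[b]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d < 1e-12):
        k = int(np.argmin(d))
        raise ValueError(f"coincident cells {a[k]} and {b[k]} (distance 0)")
    return PairSet(a, b, d, diff / d[:, None])


def psi(d, alpha: float, mean_diameter: float, cutoff: float):
    """Distance-dependent regularization weight.

    psi(D) = alpha ** max(0, (D - d_body) / (cutoff - d_body)): identically 1
    up to the cell-body diameter, exponential in distance beyond it, equal to
    ``alpha`` at the cutoff.  alpha = 1 disables the constraint.
    """
    if cutoff <= mean_diameter:
        raise ValueError("cutoff must exceed the mean cell-body diameter")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be > 0")
    expo = np.maximum(0.0, (d - mean_diameter) / (cutoff - mean_diameter))
    return alpha**expo


@dataclass
class TransitionSolution:
    pairs: PairSet
    forces: np.ndarray
    g_xyz: float
    g_f0: float
    ids: list


def _design_matrix(pairs: PairSet, n_entities: int, scale: float) -> np.ndarray:
    """Columns map pair forces to per-coordinate contributions (3N x I)."""
    a_mat = np.zeros((3 * n_entities, pairs.n_pairs))
    for i in range(pairs.n_pairs):
        a = pairs.idx_a[i]
        b = pairs.idx_b[i]
        e = pairs.units[i] * scale
        a_mat[3 * a:3 * a + 3, i] += e
        a_mat[3 * b:3 * b + 3, i] -= e
    return a_mat


def _ridge_solve(a_mat: np.ndarray, b_vec: np.ndarray, weights: np.ndarray,
                 data_scale: float, penalty_scale: float) -> np.ndarray:
    """Minimize ||A f - b||^2 * data_scale + penalty_scale * sum w_i f_i^2."""
    gram = a_mat.T @ a_mat * data_scale
    gram[np.diag_indices_from(gram)] += penalty_scale * weights
    rhs = a_mat.T @ b_vec * data_scale
    try:
        return linalg_solve(gram, rhs, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular inference system; the geometry leaves some pair forces "
            "unconstrained -- use omega_f0 > 0") from exc


def solve_transition(problem: TransitionProblem, config: InferenceConfig,
                     mean_diameter: Optional[float] = None) -> TransitionSolution:
    """Closed-form ridge solution of one frame transition."""
    d_body = mean_diameter if mean_diameter is not None else config.mean_diameter
    if d_body is None:
        raise ValueError("mean_diameter must be set (config or argument)")
    cutoff = config.cutoff_multiple * d_body
    pairs = build_pairs(problem.x_from, cutoff)
    n = problem.x_from.shape[0]
    dt = problem.dt
    if dt <= 0:
        raise ValueError("transition must advance in time")
    weights = psi(pairs.distances, config.psi_alpha, d_body, cutoff) \
        if pairs.n_pairs else np.empty(0)

    if config.friction_model == "absolute":
        a_mat = _design_matrix(pairs, n, dt / config.gamma)
        b_vec = (problem.x_to - problem.x_from).ravel()
        forces = _ridge_solve(a_mat, b_vec, weights,
                              data_scale=1.0 / dt,
                              penalty_scale=config.omega_f0 * dt)
        resid = a_mat @ forces - b_vec
        g_xyz = float(resid @ resid / dt)
    else:
        v = (problem.x_to - problem.x_from) / dt
        wg = config.omega_g if config.omega_g is not None else (lambda d: np.ones_like(d))
        targets = np.zeros((n, 3))
        w = np.asarray(wg(pairs.distances), dtype=float)
        for i in range(pairs.n_pairs):
            a, b = pairs.idx_a[i], pairs.idx_b[i]
            e = pairs.units[i]
            rel = (v[a] - v[b]) @ e
            contrib = w[i] * config.gamma * rel * e
            targets[a] += contrib
            targets[b] -= contrib
        a_mat = _design_matrix(pairs, n, 1.0)
        b_vec = targets.ravel()
        forces = _ridge_solve(a_mat, b_vec, weights,
                              data_scale=1.0,
                              penalty_scale=config.omega_f0 * dt)
        resid = a_mat @ forces - b_vec
        g_xyz = float(resid @ resid)
    g_f0 = float(config.omega_f0 * dt * np.sum(weights * forces**2)) \
        if pairs.n_pairs else 0.0
    return TransitionSolution(pairs=pairs, forces=forces, g_xyz=g_xyz,
                              g_f0=g_f0, ids=problem.ids)


@dataclass
class InferredForceTable:
    """Per-transition, per-pair inferred forces with distances at t - dt."""

    table: pd.DataFrame
    diagnostics: list = field(default_factory=list)

    def scatter(self, t0: Optional[float] = None,
                t1: Optional[float] = None) -> pd.DataFrame:
        sub = self.table
        if t0 is not None:
            sub = sub[sub["t_from"] >= t0]
        if t1 is not None:
            sub = sub[sub["t_from"] <= t1]
        return sub

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InferredForceTable":
        return cls(pd.read_csv(path, dtype={"cell_a": str, "cell_b": str}))


def infer(dataset: TrackingDataset, config: InferenceConfig,
          mean_diameter_per_frame: Optional[dict] = None) -> InferredForceTable:
    """Infer per-pair forces for every frame transition of a dataset.

    The cell-body diameter may be supplied per start frame (e.g. from
    :func:`~pairforce.tracking_io.estimate_mean_diameter` when the embryo
    volume is known) or as a single value in the config.
    """
    problems = build_transitions(dataset)
    if not problems:
        raise ValueError("dataset has fewer than two frames")
    frames = dataset.frames
    rows = []
    diagnostics = []
    for k, problem in enumerate(problems):
        d_body = None
        if mean_diameter_per_frame is not None:
            d_body = mean_diameter_per_frame.get(frames[k])
        sol = solve_transition(problem, config, mean_diameter=d_body)
        diagnostics.append({"transition": k, "t_from": problem.t_from,
                            "g_xyz": sol.g_xyz, "g_f0": sol.g_f0,
                            "n_pairs": sol.pairs.n_pairs,
                            "lost": problem.lost, "orphans": problem.orphans})
        ids = np.asarray(problem.ids)
        for i in range(sol.pairs.n_pairs):
            rows.append((k, problem.t_from, problem.t_to,
                         ids[sol.pairs.idx_a[i]], ids[sol.pairs.idx_b[i]],
                         sol.pairs.distances[i], sol.forces[i]))
    table = pd.DataFrame(rows, columns=["transition", "t_from", "t_to",
                                        "cell_a", "cell_b", "distance_um",
                                        "force_au"])
    return InferredForceTable(table, diagnostics)


def _cost_and_grad(f, a_mat, b_vec, weights, data_scale, penalty_scale):
    resid = a_mat @ f - b_vec
    cost = data_scale * resid @ resid + penalty_scale * np.sum(weights * f**2)
    grad = 2.0 * data_scale * (a_mat.T @ resid) + 2.0 * penalty_scale * weights * f
    return cost, grad


@dataclass
class UniquenessReport:
    correlations: np.ndarray
    solutions: np.ndarray
    closed_form: np.ndarray

    @property
    def min_correlation(self) -> float:
        return float(np.min(self.correlations))


def uniqueness_check(dataset: TrackingDataset, config: InferenceConfig,
                     n_restarts: int = 4, init_range: float = 0.03,
                     transition: int = 0,
                     rng: Optional[np.random.Generator] = None) -> UniquenessReport:
    """Minimize G iteratively from randomized initial force values.

    Runs an L-BFGS minimization of the transition cost from ``n_restarts``
    initial force vectors drawn uniformly from [-init_range, init_range]
    and reports the Pearson correlations of the inferred forces across all
    restart pairs, together with the closed-form ridge solution.  For
    omega_f0 > 0 the problem is strictly convex, so correlations of 1.0
    certify a unique solution.
    """
    from scipy.optimize import minimize

    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    problems = build_transitions(dataset)
    problem = problems[transition]
    d_body = config.mean_diameter
    if d_body is None:
        raise ValueError("config.mean_diameter must be set")
    cutoff = config.cutoff_multiple * d_body
    pairs = build_pairs(problem.x_from, cutoff)
    weights = psi(pairs.distances, config.psi_alpha, d_body, cutoff)
    a_mat = _design_matrix(pairs, problem.x_from.shape[0],
                           problem.dt / config.gamma)
    b_vec = (problem.x_to - problem.x_from).ravel()
    data_scale = 1.0 / problem.dt
    penalty_scale = config.omega_f0 * problem.dt

    sols = []
    for _ in range(n_restarts):
        f0 = rng.uniform(-init_range, init_range, size=pairs.n_pairs)
        res = minimize(_cost_and_grad, f0, jac=True,
                       args=(a_mat, b_vec, weights, data_scale, penalty_scale),
                       method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        sols.append(res.x)
    sols = np.array(sols)
    closed = _ridge_solve(a_mat, b_vec, weights, data_scale, penalty_scale) \
        if config.omega_f0 > 0 else np.full(pairs.n_pairs, np.nan)
    corrs = []
    for i in range(n_restarts):
        for j in range(i + 1, n_restarts):
            corrs.append(np.corrcoef(sols[i], sols[j])[0, 1])
    return UniquenessReport(np.array(corrs), sols, closed)
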