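"""Pairwise interaction potentials and distance-force / distance-potential curves.

Cells are coarse-grained as particles whose interaction is a pairwise,
center-distance-dependent force: the superposition of adhesion (attractive)
and excluded-volume / cortical-tension (repulsive) contributions.  Two
analytic families are provided (Lennard-Jones and Morse) together with
tabulated curves:

``DFCurve``
    signed force versus distance.  Sign convention throughout the package:
    **positive force = repulsive** (pushes the pair apart), so an attractive
    well is a negative dip.  Force units are arbitrary (A.U.) but anchored to
    the overdamped equation of motion: with drag coefficient gamma = 1, a
    force of 1 A.U. moves a particle at 1 um/min.
``DPCurve``
    potential energy versus distance, with U = 0 at the far end of the grid
    (pair potentials are defined up to a constant; curves decay to zero at
    long range).

The module also provides the curve-level analyses used downstream: numerical
integration of a DF curve into a DP curve, well metrics (distance at the
potential minimum, relative distance at a given fraction of the well depth),
normalization of DP curves, Morse-potential fitting, and the normalized L2
distance between an inferred curve and a reference potential.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, least_squares

__all__ = [
    "LennardJones",
    "Morse",
    "DFCurve",
    "DPCurve",
    "CurveMetrics",
    "MorseFit",
    "evaluate_force",
    "df_to_dp",
    "dp_to_df",
    "curve_metrics",
    "normalize_dp",
    "fit_morse",
    "normalized_l2",
    "attraction_range",
    "equilibrium_distance",
]

# |F_max_attractive| = LJ_FMAX_COEFF * epsilon / r_min for the 12-6 form below,
# attained at D = (26/7)^(1/6) * r_min / 2^(1/6).
LJ_FMAX_COEFF = 12.0 * ((7.0 / 13.0) ** 2 - 7.0 / 13.0) / ((13.0 / 7.0) ** (1.0 / 6.0))


def _as_positive_array(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0.0):
        raise ValueError("distances must be finite and > 0")
    return d


@dataclass(frozen=True)
class LennardJones:
    """12-6 Lennard-Jones potential parameterized by well depth and location.

    U(D) = epsilon * [ (r_min/D)^12 - 2 (r_min/D)^6 ]

    so the potential minimum (-epsilon) sits exactly at ``r_min``, which plays
    the role of the mean cell diameter.

    Parameters
    ----------
    epsilon : float
        Well depth (energy, A.U.).
    r_min : float
        Distance of the potential minimum (um).  Default 5.0 um, a typical
        blastomere diameter.
    """

    epsilon: float = 1.0
    r_min: float = 5.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.r_min <= 0:
            raise ValueError("epsilon and r_min must be > 0")

    @classmethod
    def from_max_attraction(cls, f_max: float, r_min: float = 5.0) -> "LennardJones":
        """Construct an LJ potential whose maximum attractive force is ``f_max``."""
        if f_max <= 0:
            raise ValueError("f_max must be > 0")
        return cls(epsilon=f_max * r_min / abs(LJ_FMAX_COEFF), r_min=r_min)

    def potential(self, d):
        d = _as_positive_array(d)
        x6 = (self.r_min / d) ** 6
        return self.epsilon * (x6 * x6 - 2.0 * x6)

    def force(self, d):
        """Signed force, positive repulsive: F = -dU/dD."""
        d = _as_positive_array(d)
        x6 = (self.r_min / d) ** 6
        return (12.0 * self.epsilon / d) * (x6 * x6 - x6)

    @property
    def f_max_attractive(self) -> float:
        """Magnitude of the maximum attractive force."""
        return abs(LJ_FMAX_COEFF) * self.epsilon / self.r_min

    @property
    def d_f_max(self) -> float:
        """Distance of maximum attraction."""
        return (13.0 / 7.0) ** (1.0 / 6.0) * self.r_min

    @property
    def d_equilibrium(self) -> float:
        return self.r_min


@dataclass(frozen=True)
class Morse:
    """Morse potential U(D) = Ue [exp(-2a(D-De)) - 2 exp(-a(D-De))].

    ``Ue`` is the well depth (energy, A.U.), ``De`` the distance of the
    potential minimum (um) and ``a`` the inverse width of the well (1/um).
    """

    ue: float = 1.0
    de: float = 5.0
    a: float = 1.0

    def __post_init__(self):
        if self.ue <= 0 or self.de <= 0 or self.a <= 0:
            raise ValueError("ue, de and a must be > 0")

    def potential(self, d):
        d = _as_positive_array(d)
        e = np.exp(-self.a * (d - self.de))
        return self.ue * (e * e - 2.0 * e)

    def force(self, d):
        """Signed force, positive repulsive: F = -dU/dD = 2 a Ue (e^2 - e)."""
        d = _as_positive_array(d)
        e = np.exp(-self.a * (d - self.de))
        return 2.0 * self.a * self.ue * (e * e - e)

    @property
    def f_max_attractive(self) -> float:
        # attained where exp(-a(D-De)) = 1/2, i.e. D = De + ln2/a
        return self.a * self.ue / 2.0

    @property
    def d_f_max(self) -> float:
        return self.de + np.log(2.0) / self.a

    @property
    def d_equilibrium(self) -> float:
        return self.de


@dataclass
class DFCurve:
    """Tabulated distance-force curve on a strictly increasing distance grid.

    Force is linearly interpolated inside the grid.  Beyond the last grid
    point the force is 0 (consistent with the long-range regularization that
    drives inferred forces to zero); below the first grid point the first
    value is held (short-range repulsion does not vanish for overlapping
    cells).
    """

    distances: np.ndarray
    forces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        self.forces = np.asarray(self.forces, dtype=float).ravel()
        if self.distances.size != self.forces.size:
            raise ValueError("distances and forces must have equal length")
        if self.distances.size < 1:
            raise ValueError("curve needs at least one grid point")
        if np.any(~np.isfinite(self.distances)) or np.any(~np.isfinite(self.forces)):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distance grid must be strictly increasing")

    def force(self, d):
        d = _as_positive_array(d)
        return np.interp(d, self.distances, self.forces,
                         left=self.forces[0], right=0.0)

    @property
    def f_max_attractive(self) -> float:
        f_min = float(np.min(self.forces))
        if f_min >= 0:
            raise ValueError("curve has no attractive (negative) force")
        return -f_min

    @classmethod
    def from_potential(cls, potential, distances) -> "DFCurve":
        """Tabulate an analytic potential's force on the given grid."""
        distances = _as_positive_array(distances)
        return cls(distances, potential.force(distances),
                   metadata={"source": type(potential).__name__})

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"distance_um": self.distances, "force_au": self.forces}
        counts = self.metadata.get("counts")
        if counts is not None:
            cols["count"] = np.asarray(counts, dtype=int)
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DFCurve":
        import pandas as pd

        df = pd.read_csv(path)
        meta = {}
        if "count" in df.columns:
            meta["counts"] = df["count"].to_numpy()
        return cls(df["distance_um"].to_numpy(), df["force_au"].to_numpy(), meta)


@dataclass
class DPCurve:
    """Tabulated distance-potential curve; U at the far end of the grid is the
    zero reference."""

    distances: np.ndarray
    potentials: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        self.potentials = np.asarray(self.potentials, dtype=float).ravel()
        if self.distances.size != self.potentials.size:
            raise ValueError("distances and potentials must have equal length")
        if self.distances.size < 2:
            raise ValueError("curve needs at least two grid points")
        if np.any(~np.isfinite(self.distances)) or np.any(~np.isfinite(self.potentials)):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distance grid must be strictly increasing")

    @property
    def distance_at_minimum(self) -> float:
        return float(self.distances[int(np.argmin(self.potentials))])

    @property
    def u_min(self) -> float:
        return float(np.min(self.potentials))

    def potential(self, d):
        d = _as_positive_array(d)
        return np.interp(d, self.distances, self.potentials,
                         left=self.potentials[0], right=0.0)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"distance_um": self.distances,
                      "potential_au": self.potentials}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DPCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["distance_um"].to_numpy(), df["potential_au"].to_numpy())


def evaluate_force(potential, d):
    """Signed pairwise force (positive = repulsive) at distance(s) ``d``.

    ``potential`` may be an analytic potential (:class:`LennardJones`,
    :class:`Morse`) or a tabulated :class:`DFCurve`.
    """
    _as_positive_array(d)
    return potential.force(d)


def equilibrium_distance(potential) -> float:
    """Distance at which the pair force vanishes (the potential minimum).

    For a tabulated curve this is the repulsive-to-attractive zero crossing,
    located by linear interpolation.
    """
    if hasattr(potential, "d_equilibrium"):
        return float(potential.d_equilibrium)
    dfc: DFCurve = potential
    f = dfc.forces
    d = dfc.distances
    sign_change = np.nonzero((f[:-1] > 0) & (f[1:] <= 0))[0]
    if sign_change.size == 0:
        # no repulsive-to-attractive crossing; fall back to the potential minimum
        return df_to_dp(dfc).distance_at_minimum
    i = int(sign_change[0])
    if f[i] == f[i + 1]:
        return float(d[i])
    return float(d[i] + (d[i + 1] - d[i]) * f[i] / (f[i] - f[i + 1]))


def df_to_dp(curve: DFCurve) -> DPCurve:
    """Integrate a DF curve into a DP curve.

    U(D) = integral_D^{Dmax} F(s) ds by trapezoidal quadrature, so that
    U(Dmax) = 0 and U decreases with D where the force is attractive
    (F = -dU/dD with the positive-repulsive sign convention).
    """
    if curve.distances.size < 2:
        raise ValueError("need at least two grid points to integrate")
    acc = cumulative_trapezoid(curve.forces, curve.distances, initial=0.0)
    u = acc[-1] - acc
    return DPCurve(curve.distances.copy(), u, metadata=dict(curve.metadata))


def dp_to_df(dp: DPCurve) -> DFCurve:
    """Differentiate a DP curve back into a DF curve (F = -dU/dD)."""
    f = -np.gradient(dp.potentials, dp.distances)
    return DFCurve(dp.distances.copy(), f, metadata=dict(dp.metadata))


@dataclass(frozen=True)
class CurveMetrics:
    distance_at_minimum: float
    relative_distance_at_fraction: float
    energy_fraction: float


def curve_metrics(dp: DPCurve, energy_fraction: float = 0.10) -> CurveMetrics:
    """Well metrics of a DP curve.

    ``distance_at_minimum`` is the grid location of the global minimum.
    ``relative_distance_at_fraction`` is the smallest distance beyond the
    minimum at which the potential has decayed to ``energy_fraction`` of the
    well depth (U >= fraction * U_min), expressed relative to the distance at
    the minimum.  The crossing is located by linear interpolation between
    grid points.
    """
    if not 0.0 < energy_fraction < 1.0:
        raise ValueError("energy_fraction must be in (0, 1)")
    u = dp.potentials
    d = dp.distances
    i_min = int(np.argmin(u))
    u_min = u[i_min]
    if u_min >= 0:
        raise ValueError("no attractive well: potential minimum is not negative")
    d_min = d[i_min]
    target = energy_fraction * u_min  # negative, closer to 0 than u_min
    tail_u = u[i_min:]
    tail_d = d[i_min:]
    above = np.nonzero(tail_u >= target)[0]
    if above.size == 0:
        raise ValueError(
            "potential does not decay to the requested fraction within the grid")
    j = int(above[0])
    if j == 0:
        d_cross = tail_d[0]
    else:
        u0, u1 = tail_u[j - 1], tail_u[j]
        d0, d1 = tail_d[j - 1], tail_d[j]
        d_cross = d0 + (d1 - d0) * (target - u0) / (u1 - u0)
    return CurveMetrics(float(d_min), float(d_cross / d_min), energy_fraction)


def normalize_dp(dp: DPCurve, mode: str = "unit_minimum") -> DPCurve:
    """Normalize a DP curve by the distance at its potential minimum.

    mode ``"unit_minimum"``
        D -> D/D_min and U -> U/|U_min|: the minimum becomes -1.0 at
        distance 1.0.
    mode ``"distance_sq"``
        D -> D/D_min and U -> U/D_min^2.

    Both modes are idempotent.
    """
    d_min = dp.distance_at_minimum
    u_min = dp.u_min
    if u_min >= 0:
        raise ValueError("no attractive well: potential minimum is not negative")
    if d_min <= 0:
        raise ValueError("distance at minimum must be > 0")
    if mode == "unit_minimum":
        u = dp.potentials / abs(u_min)
    elif mode == "distance_sq":
        u = dp.potentials / d_min**2
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    meta = dict(dp.metadata)
    meta["normalization"] = mode
    return DPCurve(dp.distances / d_min, u, metadata=meta)


@dataclass(frozen=True)
class MorseFit:
    potential: Morse
    rms_residual: float
    converged: bool
    message: str = ""


def fit_morse(dp: DPCurve) -> MorseFit:
    """Least-squares fit of a Morse potential to a DP curve over its grid.

    Initial values are taken from the curve's well (depth, location, and an
    inverse width of order 1/D_min).  A non-converged fit is returned flagged
    rather than raised, so callers can inspect the diagnostics.
    """
    if dp.distances.size < 5:
        raise ValueError("need at least 5 grid points to fit")
    if dp.u_min >= 0:
        raise ValueError("no attractive well to fit")
    d = dp.distances
    u = dp.potentials
    ue0 = abs(dp.u_min)
    de0 = dp.distance_at_minimum
    a0 = 2.0 / de0

    def resid(theta):
        ue, de, a = theta
        e = np.exp(-a * (d - de))
        return ue * (e * e - 2.0 * e) - u

    sol = least_squares(resid, x0=[ue0, de0, a0],
                        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return MorseFit(
        potential=Morse(ue=float(sol.x[0]), de=float(sol.x[1]), a=float(sol.x[2])),
        rms_residual=rms,
        converged=bool(sol.success),
        message=str(sol.message),
    )


def attraction_range(reference, threshold: float = 0.1) -> tuple[float, float]:
    """Distance interval where the reference attraction is strong.

    Returns the interval [lo, hi] on which the attractive force magnitude of
    ``reference`` is >= ``threshold`` times its maximum attractive force.
    """
    f_max = reference.f_max_attractive
    target = -threshold * f_max

    if hasattr(reference, "d_f_max") and hasattr(reference, "d_equilibrium"):
        d_star = reference.d_f_max
        d_eq = reference.d_equilibrium
        lo = brentq(lambda x: float(reference.force(x)) - target, d_eq, d_star)
        hi = brentq(lambda x: float(reference.force(x)) - target, d_star, 50.0 * d_eq)
        return float(lo), float(hi)

    # tabulated reference: locate threshold crossings on a dense resampling
    d = np.linspace(reference.distances[0], reference.distances[-1], 4096)
    f = reference.force(d)
    below = np.nonzero(f <= target)[0]
    if below.size == 0:
        raise ValueError("reference never reaches the attraction threshold")
    return float(d[below[0]]), float(d[below[-1]])


def normalized_l2(inferred, reference, threshold: float = 0.1,
                  n_grid: int = 512) -> float:
    """Normalized L2 distance between an inferred DF curve and a reference.

    {F_inferred(D) - F_ref(D)}^2 / F_ref_max^2 is averaged over the distances
    where the reference attractive force magnitude is >= ``threshold`` times
    its maximum attractive force (F_ref_max).  The inferred curve is evaluated
    by its own interpolation rule (0 beyond its grid).
    """
    lo, hi = attraction_range(reference, threshold)
    if not hi > lo:
        raise ValueError("empty admissible distance range")
    d = np.linspace(lo, hi, n_grid)
    f_ref = reference.force(d)
    f_inf = inferred.force(d)
    f_max = reference.f_max_attractive
    return float(np.mean((f_inf - f_ref) ** 2) / f_max**2)
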