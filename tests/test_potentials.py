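import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from pairforce.potentials import (DFCurve, DPCurve, LennardJones, Morse,
                                  attraction_range, curve_metrics, df_to_dp,
                                  dp_to_df, equilibrium_distance,
                                  evaluate_force, fit_morse, normalize_dp,
                                  normalized_l2)

LJ = LennardJones(epsilon=1.0, r_min=5.0)
MORSE = Morse(ue=1.0, de=5.0, a=1.0)


class TestAnalyticForms:
    def test_force_vanishes_at_potential_minimum(self):
        assert abs(evaluate_force(LJ, LJ.r_min)) < 1e-10
        assert abs(evaluate_force(MORSE, MORSE.de)) < 1e-10

    def test_potential_decays_to_zero_at_long_range(self):
        for pot, d_eq in ((LJ, LJ.r_min), (MORSE, MORSE.de)):
            u_min = float(pot.potential(d_eq))
            assert abs(float(pot.potential(12 * d_eq))) < 1e-6 * abs(u_min)

    def test_lj_maximum_attraction_distance_closed_form(self):
        # d^2U/dD^2 = 0 at D = (26/7)^(1/6) * sigma with sigma = r_min/2^(1/6)
        sigma = LJ.r_min / 2 ** (1 / 6)
        expected = (26 / 7) ** (1 / 6) * sigma
        res = minimize_scalar(lambda d: float(LJ.force(d)),
                              bounds=(LJ.r_min, 3 * LJ.r_min),
                              method="bounded",
                              options={"xatol": 1e-12})
        assert res.x == pytest.approx(expected, rel=1e-7)
        assert LJ.d_f_max == pytest.approx(expected, rel=1e-12)
        assert LJ.f_max_attractive == pytest.approx(-res.fun, rel=1e-9)

    @pytest.mark.parametrize("pot", [LJ, MORSE,
                                     LennardJones.from_max_attraction(0.003),
                                     Morse(ue=0.5, de=8.0, a=0.7)])
    def test_force_is_negative_potential_gradient(self, pot, rng):
        d_eq = equilibrium_distance(pot)
        d = rng.uniform(0.6 * d_eq, 3 * d_eq, size=100)
        h = 1e-6 * d_eq
        numeric = -(pot.potential(d + h) - pot.potential(d - h)) / (2 * h)
        assert np.allclose(pot.force(d), numeric, rtol=1e-6, atol=1e-12)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_force(LJ, 0.0)
        with pytest.raises(ValueError):
            evaluate_force(MORSE, -1.0)


class TestDFCurve:
    def test_interpolation_and_extrapolation_rules(self):
        c = DFCurve([1.0, 2.0, 3.0], [4.0, 2.0, 1.0])
        assert c.force(1.5) == pytest.approx(3.0)
        assert c.force(10.0) == 0.0          # beyond grid: regularized to zero
        assert c.force(0.5) == pytest.approx(4.0)  # core: hold repulsion

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            DFCurve([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            DFCurve([1.0, 2.0], [0.0, np.nan])

    def test_csv_round_trip(self, tmp_path):
        c = DFCurve([1.0, 2.0], [0.5, -0.5], metadata={"counts": [3, 4]})
        path = tmp_path / "df.csv"
        c.to_csv(path)
        back = DFCurve.from_csv(path)
        assert np.allclose(back.distances, c.distances)
        assert np.allclose(back.forces, c.forces)
        assert np.array_equal(back.metadata["counts"], [3, 4])


class TestIntegration:
    def test_zero_forces_integrate_to_zero_potential(self):
        dp = df_to_dp(DFCurve(np.linspace(1, 10, 50), np.zeros(50)))
        assert np.all(dp.potentials == 0.0)

    def test_lj_tabulation_integrates_to_analytic_potential(self):
        d = np.linspace(3.5, 40.0, 4000)
        dp = df_to_dp(DFCurve.from_potential(LJ, d))
        u_ref = LJ.potential(d)
        assert np.max(np.abs(dp.potentials - u_ref)) < 0.01 * LJ.epsilon
        assert dp.potentials[-1] == 0.0

    def test_differentiating_recovers_forces(self):
        d = np.linspace(3.5, 30.0, 3000)
        curve = DFCurve.from_potential(MORSE, d)
        back = dp_to_df(df_to_dp(curve))
        inner = slice(5, -5)
        assert np.allclose(back.forces[inner], curve.forces[inner],
                           rtol=1e-3, atol=5e-4)

    def test_single_point_curve_cannot_integrate(self):
        with pytest.raises(ValueError):
            df_to_dp(DFCurve([1.0], [1.0]))


@pytest.fixture(scope="module")
def morse_dp():
    d = np.arange(2.0, 30.0 + 1e-9, 0.005)
    return df_to_dp(DFCurve.from_potential(MORSE, d))


@pytest.fixture(scope="module")
def dp():
    d = np.arange(2.0, 25.0, 0.01)
    return df_to_dp(DFCurve.from_potential(Morse(ue=2.0, de=4.0, a=1.5), d))


class TestCurveMetrics:
    def test_distance_at_minimum_matches_construction(self, morse_dp):
        m = curve_metrics(morse_dp, 0.10)
        assert m.distance_at_minimum == pytest.approx(MORSE.de, abs=0.005)

    @pytest.mark.parametrize("fraction", [0.25, 0.10, 0.05])
    def test_relative_distance_matches_morse_closed_form(self, morse_dp,
                                                         fraction):
        # U/Ue = x^2 - 2x with x = exp(-a(D-De)); solving x^2-2x = -f on the
        # decaying branch gives x = 1 - sqrt(1-f)
        x = 1.0 - np.sqrt(1.0 - fraction)
        expected = 1.0 - np.log(x) / (MORSE.a * MORSE.de)
        m = curve_metrics(morse_dp, fraction)
        assert m.relative_distance_at_fraction == pytest.approx(expected,
                                                                rel=2e-3)

    def test_relative_distance_decreases_with_fraction(self, morse_dp):
        r1 = curve_metrics(morse_dp, 0.05).relative_distance_at_fraction
        r2 = curve_metrics(morse_dp, 0.20).relative_distance_at_fraction
        assert r1 >= r2

    def test_no_well_is_an_error(self):
        dp = DPCurve([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="well"):
            curve_metrics(dp, 0.10)


class TestNormalization:
    def test_unit_minimum_mode(self, dp):
        out = normalize_dp(dp, "unit_minimum")
        assert out.u_min == pytest.approx(-1.0)
        assert out.distance_at_minimum == pytest.approx(1.0, abs=1e-3)

    def test_distance_sq_mode(self, dp):
        out = normalize_dp(dp, "distance_sq")
        assert out.distance_at_minimum == pytest.approx(1.0, abs=1e-3)
        assert out.u_min == pytest.approx(dp.u_min / dp.distance_at_minimum**2)

    @pytest.mark.parametrize("mode", ["unit_minimum", "distance_sq"])
    def test_idempotent(self, dp, mode):
        once = normalize_dp(dp, mode)
        twice = normalize_dp(once, mode)
        assert np.allclose(twice.distances, once.distances)
        assert np.allclose(twice.potentials, once.potentials)

    def test_unknown_mode(self, dp):
        with pytest.raises(ValueError):
            normalize_dp(dp, "bogus")


class TestMorseFit:
    def test_exact_parameter_recovery(self):
        d = np.arange(2.5, 25.0, 0.01)
        dp = DPCurve(d, Morse(ue=1.0, de=5.0, a=1.0).potential(d))
        fit = fit_morse(dp)
        assert fit.converged
        assert fit.potential.ue == pytest.approx(1.0, rel=1e-4)
        assert fit.potential.de == pytest.approx(5.0, rel=1e-4)
        assert fit.potential.a == pytest.approx(1.0, rel=1e-4)

    def test_recovery_under_observation_noise(self, rng):
        d = np.arange(2.5, 25.0, 0.02)
        u = Morse(ue=1.0, de=5.0, a=1.0).potential(d)
        dp = DPCurve(d, u + rng.normal(0, 0.01, size=d.size))
        fit = fit_morse(dp)
        assert fit.potential.ue == pytest.approx(1.0, rel=0.05)
        assert fit.potential.de == pytest.approx(5.0, rel=0.05)
        assert fit.potential.a == pytest.approx(1.0, rel=0.05)

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_morse(DPCurve(np.linspace(1, 10, 20), np.zeros(20)))


class TestNormalizedL2:
    def test_identical_curves_score_zero(self):
        d = np.linspace(4.0, 12.0, 400)
        inferred = DFCurve.from_potential(LJ, d)
        assert normalized_l2(inferred, LJ) < 1e-6

    def test_zero_curve_matches_independent_quadrature(self):
        # independent oracle: dense scan for the admissible range, then plain
        # averaging of (F_ref/F_max)^2 over it
        d = np.linspace(LJ.r_min, 20 * LJ.r_min, 400001)
        f = LJ.force(d)
        f_max = LJ.f_max_attractive
        mask = f <= -0.1 * f_max
        oracle = float(np.mean((f[mask] / f_max) ** 2))
        zero = DFCurve(np.linspace(1.0, 30.0, 50), np.zeros(50))
        assert normalized_l2(zero, LJ) == pytest.approx(oracle, rel=2e-3)

    def test_score_is_nonnegative_and_detects_disagreement(self):
        d = np.linspace(4.0, 12.0, 400)
        shifted = DFCurve(d, LJ.force(d) + 0.1 * LJ.f_max_attractive)
        assert normalized_l2(shifted, LJ) > 0

    def test_attraction_range_brackets_max_attraction(self):
        lo, hi = attraction_range(LJ)
        assert lo < LJ.d_f_max < hi
        assert lo > LJ.r_min


class TestEquilibriumDistance:
    def test_analytic_families(self):
        assert equilibrium_distance(LJ) == LJ.r_min
        assert equilibrium_distance(MORSE) == MORSE.de

    def test_tabulated_zero_crossing(self):
        d = np.linspace(3.0, 15.0, 1000)
        c = DFCurve.from_potential(LJ, d)
        assert equilibrium_distance(c) == pytest.approx(LJ.r_min, abs=0.02)


@given(st.floats(min_value=0.5, max_value=20.0))
def test_lj_force_sign_splits_at_r_min(d_rel):
    d = d_rel * LJ.r_min / 5.0 + 1e-6
    f = float(LJ.force(d))
    if d < LJ.r_min:
        assert f > 0
    elif d > LJ.r_min:
        assert f < 0
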