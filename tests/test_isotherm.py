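"""Isotherm inversion: plateau handling, Dmu_s integration, both routes."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from monoion.bulk import solution_state
from monoion.constants import AVOGADRO, kT, water_density
from monoion.isotherm import (
    IsothermCurve,
    SpreadingSeries,
    build_field,
    correct_plateau,
    induced_adsorption_isobaric,
    induced_adsorption_isochemical,
    induced_adsorption_spread,
    interpolate_spreading_pressure,
    route_consistency,
    spreading_area,
    surfactant_chemical_potential,
)
from monoion.synthetic import SyntheticParams, build_system, sample_isotherms


def simple_curve(S_A2, pi_mNm, C_m=0.0, surfactant="test"):
    return IsothermCurve(surfactant=surfactant, C_m=C_m,
                         S=np.asarray(S_A2) * 1e-20,
                         pi=np.asarray(pi_mNm) * 1e-3)


class TestPlateauCorrection:
    def test_monotone_curve_unchanged(self):
        c = simple_curve([60, 50, 40, 30], [1, 3, 8, 15])
        out = correct_plateau(c)
        assert np.array_equal(out.pi, c.pi)
        assert out.plateau_corrected

    def test_tilted_plateau_flattened_matches_qp_oracle(self):
        S = np.array([70, 62, 55, 50, 46, 42, 38, 34, 31, 28.0])
        pi = np.array([1.0, 2.5, 4.0, 5.2, 5.05, 4.9, 4.75, 6.0, 9.0, 14.0])
        c = simple_curve(S, pi)
        out = correct_plateau(c)
        # independent oracle: small constrained least-squares instance
        y = pi * 1e-3

        def obj(x):
            return np.sum((x - y) ** 2)

        cons = [{"type": "ineq", "fun": (lambda x, i=i: x[i + 1] - x[i])}
                for i in range(len(y) - 1)]
        res = minimize(obj, y, constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-18})
        assert np.allclose(out.pi, res.x, atol=2e-6)
        # the projected plateau is flat at the equal-deviation level
        pool = out.pi[3:7]
        assert np.allclose(pool, pool[0])
        assert pool[0] == pytest.approx(np.mean(y[3:7]), rel=1e-9)

    def test_bad_digitization_warning(self):
        S = np.linspace(60, 30, 10)
        pi = np.linspace(10, 1, 10)  # fully decreasing under compression
        with pytest.warns(UserWarning, match="digitization"):
            correct_plateau(simple_curve(S, pi))

    def test_plateau_fixture_integrates_to_known_dmu(self, system):
        """A tilted phase-transition plateau, after correction, yields the
        same Dmu_s as the flat ground truth within 2%."""
        x = np.linspace(-5.2, 0.0, 120)
        S = np.asarray(system.S_of_x(x, 0.0))
        pi = np.asarray(system.pi(x, 0.0))
        flat = IsothermCurve("truth", 0.0, S, pi)
        # impose a flat plateau over an interior pressure band (a distinct,
        # still admissible equation of state = the ground truth)
        band = (pi > 4e-3) & (pi < 6e-3)
        pi_plateau = pi.copy()
        pi_plateau[band] = np.mean(pi[band])
        truth = IsothermCurve("truth", 0.0, S, pi_plateau)
        # digitized version: tilt the plateau by +/- 0.3 mN/m (zero mean)
        tilt = np.linspace(0.3e-3, -0.3e-3, band.sum())
        pi_tilt = pi_plateau.copy()
        pi_tilt[band] += tilt
        digitized = IsothermCurve("digitized", 0.0, S, pi_tilt)
        pi_sp, S_sp = system.pi_sp(0.0), system.S_sp(0.0)
        mu_truth = surfactant_chemical_potential(truth, pi_sp, S_sp)
        mu_corr = surfactant_chemical_potential(
            correct_plateau(digitized), pi_sp, S_sp)
        probe = np.linspace(1e-3, 15e-3, 30)
        a = np.asarray(mu_truth.dmu_at(probe))
        b = np.asarray(mu_corr.dmu_at(probe))
        assert np.max(np.abs(a - b)) <= 0.02 * np.max(np.abs(a))
        del flat


class TestSpreadingArea:
    def test_last_point_exactly_at_pi_sp(self):
        c = simple_curve([60, 45, 35, 30], [2, 8, 13, 17])
        got = spreading_area(c, 17e-3)
        assert got == pytest.approx(30e-20, rel=1e-9)

    def test_linear_tail_exact_intersection(self):
        # tail: pi = 50 - S (mN/m with S in A^2): pi_sp = 22 -> S = 28
        S = np.array([80, 60, 34, 32, 30.0])
        pi = np.array([1.0, 5.0, 16.0, 18.0, 20.0])
        got = spreading_area(simple_curve(S, pi), 22e-3)
        assert got == pytest.approx(28e-20, rel=1e-9)

    def test_k2_vs_k3_collinear(self):
        S = np.array([80, 60, 34, 32, 30.0])
        pi = np.array([1.0, 5.0, 16.0, 18.0, 20.0])
        a = spreading_area(simple_curve(S, pi), 22e-3, k_points=2)
        b = spreading_area(simple_curve(S, pi), 22e-3, k_points=3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_curve_far_from_pi_sp_rejected(self):
        c = simple_curve([60, 50, 40], [1, 2, 3])
        with pytest.raises(ValueError, match="extrapolation unsafe"):
            spreading_area(c, 20e-3)


class TestSpreadingPressureInterpolation:
    def test_knot_reproduction(self, nacl):
        s = SpreadingSeries("t", np.array([0.0, 1.0, 2.0]),
                            np.array([15e-3, 16e-3, 17.5e-3]))
        got = interpolate_spreading_pressure(s, nacl, 1.0)
        assert got == pytest.approx(16e-3, rel=1e-12)

    def test_midpoint_in_p_osm(self, nacl):
        s = SpreadingSeries("t", np.array([0.0, 2.0]),
                            np.array([15e-3, 17e-3]))
        # find the molality whose p_osm is half of p_osm(2.0)
        from scipy.optimize import brentq
        p2 = solution_state(nacl, 2.0).p_osm
        c_mid = brentq(lambda c: solution_state(nacl, c).p_osm - p2 / 2,
                       0.01, 2.0)
        got = interpolate_spreading_pressure(s, nacl, c_mid)
        assert got == pytest.approx(16e-3, rel=1e-9)

    def test_generator_linearity(self, system, sampled):
        _, series = sampled
        for C in (0.5, 1.7, 3.0):
            got = interpolate_spreading_pressure(series, system.spec, C)
            assert got == pytest.approx(system.pi_sp(C), rel=1e-2)

    def test_extrapolation_flag_required(self, nacl):
        s = SpreadingSeries("t", np.array([0.0, 1.0]),
                            np.array([15e-3, 16e-3]))
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_spreading_pressure(s, nacl, 3.0)
        got = interpolate_spreading_pressure(s, nacl, 3.0,
                                             allow_extrapolation=True)
        assert got > 16e-3


class TestChemicalPotential:
    def test_zero_at_reference(self):
        c = simple_curve([60, 45, 35, 30], [2, 8, 13, 17])
        mu = surfactant_chemical_potential(c, 17e-3, 30e-20)
        assert float(mu.dmu_at(17e-3)) == pytest.approx(0.0, abs=1e-9)

    def test_ideal_2d_gas_closed_form(self):
        # pi = kT Gamma_s  =>  Dmu_s = kT ln(Gamma_s / Gamma_s,sp)
        T = 293.15
        S = np.geomspace(300e-20, 33e-20, 400)
        pi = kT(T) / S
        curve = IsothermCurve("gas", 0.0, S, pi, T=T)
        S_sp = 32e-20
        pi_sp = kT(T) / S_sp
        mu = surfactant_chemical_potential(curve, pi_sp, S_sp)
        probe_S = np.array([250e-20, 120e-20, 60e-20, 40e-20])
        got = np.asarray(mu.dmu_at(kT(T) / probe_S))
        expected = AVOGADRO * kT(T) * np.log(S_sp / probe_S)
        assert np.allclose(got, expected, rtol=1e-3)

    def test_generator_field_within_1pct(self, system, field):
        sl = field.slice_at(0.0)
        x = np.linspace(-4.5, -0.2, 40)
        pi = np.asarray(system.pi(x, 0.0))
        got = np.asarray(sl.mu.dmu_at(pi))
        expected = np.asarray(system.dmu_s_true(x))
        assert np.max(np.abs(got - expected)) <= 0.01 * np.max(np.abs(expected))

    def test_monotonicity_required(self):
        c = simple_curve([60, 50, 40, 30], [2, 6, 5, 12])
        with pytest.raises(ValueError, match="correct_plateau"):
            surfactant_chemical_potential(c, 14e-3, 28e-20)

    def test_integration_self_convergence(self, system):
        """Doubling point density changes Dmu_s by <0.5%."""
        vals = {}
        for n in (60, 120):
            x = np.linspace(-5.2, 0.0, n)
            curve = IsothermCurve("t", 0.0,
                                  np.asarray(system.S_of_x(x, 0.0)),
                                  np.asarray(system.pi(x, 0.0)))
            mu = surfactant_chemical_potential(
                curve, system.pi_sp(0.0), system.S_sp(0.0))
            vals[n] = np.asarray(mu.dmu_at(np.linspace(1e-3, 16e-3, 25)))
        diff = np.max(np.abs(vals[60] - vals[120]))
        assert diff <= 0.005 * np.max(np.abs(vals[120]))


class TestSpreadState:
    def test_concentration_independent_series_gives_zero(self, nacl):
        s = SpreadingSeries("t", np.array([0.0, 1.0, 2.0]),
                            np.full(3, 15e-3))
        star = induced_adsorption_spread(s, nacl)
        assert np.allclose(star.dGamma_el, 0.0)

    def test_linear_slope_oracle(self, nacl):
        slope = 2.4e-10  # m (dpi/dp_osm)
        C = np.array([0.0, 0.7, 1.8])
        p = np.array([solution_state(nacl, c).p_osm if c else 0.0
                      for c in C])
        s = SpreadingSeries("t", C, 15e-3 + slope * p)
        star = induced_adsorption_spread(s, nacl)
        rho_w = water_density()
        assert np.allclose(star.dGamma_el, rho_w * C * slope, rtol=1e-9)
        assert star.slope == pytest.approx(slope, rel=1e-9)

    def test_generator_star_recovery(self, system, sampled):
        _, series = sampled
        star = induced_adsorption_spread(series, system.spec)
        truth = np.array([float(system.dGamma_el_true(0.0, c))
                          for c in star.C_m])
        scale = np.abs(truth).max()
        assert np.max(np.abs(star.dGamma_el - truth)) <= 0.03 * scale

    def test_single_concentration_rejected(self, nacl):
        s = SpreadingSeries("t", np.array([0.0]), np.array([15e-3]))
        with pytest.raises(ValueError, match="concentration"):
            induced_adsorption_spread(s, nacl)


class TestRoutes:
    def test_identical_curves_give_zero(self):
        sys0 = build_system(SyntheticParams(g=0.0))
        curves, series = sample_isotherms(sys0, n_points=40)
        field = build_field(curves, series, sys0.spec)
        A = induced_adsorption_isochemical(field)
        B = induced_adsorption_isobaric(field)
        scale = water_density() * 3.5 * 1e-10  # a generous tiny scale
        assert np.max(np.abs(A.dGamma_el)) < scale
        assert np.max(np.abs(B.dGamma_el)) < scale

    def test_anchored_at_zero_coverage(self, profiles):
        A, B = profiles
        for P in (A, B):
            assert P.Gamma_s[0] == 0.0
            assert P.dGamma_el[0] == 0.0

    def test_generator_recovery_both_routes(self, system, profiles):
        scale = abs(float(system.dGamma_el_true(system.params.x0, 3.5)))
        for P in profiles:
            S = 1.0 / (P.Gamma_s[1:] * AVOGADRO)
            truth = system.dGamma_el_true_at_S(S, 3.5)
            assert np.max(np.abs(P.dGamma_el[1:] - truth)) <= 0.03 * scale

    def test_interior_maximum_reproduced(self, system, profiles):
        A, B = profiles
        g_true = system.interior_maximum_Gamma_s(3.5)
        for P in (A, B):
            g_found, _ = P.interior_maximum()
            step = np.diff(P.Gamma_s).max()
            assert abs(g_found - g_true) <= step
            # interior: not at either end of the grid
            assert P.Gamma_s[1] < g_found < P.Gamma_s[-1]

    def test_electrolyte_stabilizes_dilute_monolayer(self, field):
        """Dmu_s drops on salt addition at fixed S in the dilute region
        of an attractive system."""
        sl0 = field.slice_at(0.0)
        sl35 = field.slice_at(3.5)
        S_probe = 100e-20
        # invert S -> pi per slice, then read Dmu_s
        from scipy.optimize import brentq

        def dmu_at_S(sl):
            f = lambda pi: float(sl.mu.S_of_pi(pi)) - S_probe
            pi = brentq(f, sl.mu.pi[0] * 1.01, sl.mu.pi[-1] * 0.99)
            return float(sl.mu.dmu_at(pi))

        assert dmu_at_S(sl35) < dmu_at_S(sl0)


class TestRouteConsistency:
    def test_identical_profiles(self, profiles):
        A, _ = profiles
        d = route_consistency(A, A)
        assert d.max_rel == 0.0 and not d.flagged

    def test_noiseless_generator_below_2pct(self, profiles):
        A, B = profiles
        d = route_consistency(A, B)
        assert d.max_rel <= 0.02
        assert not d.flagged

    def test_noisy_data_reported_not_raised(self):
        sys_ = build_system(SyntheticParams(noise=0.02), seed=7)
        curves, series = sample_isotherms(sys_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = build_field(curves, series, sys_.spec)
            A = induced_adsorption_isochemical(field)
            B = induced_adsorption_isobaric(field)
            d = route_consistency(A, B)
        assert np.isfinite(d.max_rel) and np.isfinite(d.mean_rel)


def test_build_field_requires_water_reference(system, sampled):
    curves, series = sampled
    salty = [c for c in curves if c.C_m > 0]
    with pytest.raises(ValueError, match="C_m = 0"):
        build_field(salty, series, system.spec)
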