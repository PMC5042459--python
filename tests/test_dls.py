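"""DLS mode decomposition, sizing, and diffusive-scaling checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyion as p
from polyion.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidGeometryError,
    InvalidModelError,
)


class TestScatteringVector:
    def test_hand_evaluated_value(self, geometry):
        # (4 pi * 1.33 / 633e-9) * sin(86.5 deg)
        assert p.scattering_vector(geometry) == pytest.approx(2.6354e7, rel=1e-4)

    def test_vanishes_at_zero_angle_limit(self):
        q = p.scattering_vector(p.ScatteringGeometry(633.0, 1e-6, 1.33))
        assert q == pytest.approx(0.0, abs=1.0)

    def test_linear_in_refractive_index(self):
        q1 = p.scattering_vector(p.ScatteringGeometry(633.0, 90.0, 1.2))
        q2 = p.scattering_vector(p.ScatteringGeometry(633.0, 90.0, 2.4))
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"wavelength_nm": -633.0}, {"angle_deg": 0.0}, {"angle_deg": 180.0},
        {"refractive_index": 0.9},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidGeometryError):
            p.ScatteringGeometry(**kwargs)


class TestKwwModel:
    def test_single_exponential_identity(self):
        mode = p.RelaxationMode(1.0, 1e-3, 1.0)
        assert p.kww_model([1e-3], [mode])[0] == pytest.approx(math.exp(-1))

    def test_amplitudes_sum_at_zero_lag(self):
        modes = [p.RelaxationMode(0.3, 1e-4, 0.8), p.RelaxationMode(0.6, 1e-2, 0.7)]
        assert p.kww_model([1e-12], modes)[0] == pytest.approx(0.9, rel=1e-6)

    def test_two_mode_value_is_sum_of_stretched_exponentials(self):
        modes = [p.RelaxationMode(0.5, 1e-4, 0.8), p.RelaxationMode(0.5, 1e-3, 0.8)]
        t = 5e-4
        expected = 0.5 * math.exp(-(t / 1e-4) ** 0.8) + 0.5 * math.exp(-(t / 1e-3) ** 0.8)
        assert p.kww_model([t], modes)[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_mode_list_rejected(self):
        with pytest.raises(InvalidModelError):
            p.kww_model([1e-3], [])

    @settings(derandomize=True, max_examples=25)
    @given(tau=st.floats(1e-6, 1e-2), gamma=st.floats(0.55, 1.0),
           amp=st.floats(0.1, 2.0))
    def test_strictly_decreasing_in_lag(self, tau, gamma, amp):
        # lag window tied to tau so the tail does not underflow to exactly 0
        t = tau * np.geomspace(1e-3, 30.0, 50)
        g = p.kww_model(t, [p.RelaxationMode(amp, tau, gamma)])
        assert np.all(np.diff(g) < 0)


class TestStokesEinstein:
    def test_diffusion_coefficient_hand_value(self, geometry):
        # k_B * 298.15 / (6 pi * 0.89 mPa s * 5 nm) ~ 4.9e-11 m^2/s
        solv = p.SolventSpec(298.15, 0.0, 0.89e-3)
        tau = p.radius_to_relaxation_time(5.0, geometry, solv)
        sized = p.mode_to_radius(p.RelaxationMode(1.0, tau, 0.8), geometry, solv)
        assert sized.diffusion_coefficient == pytest.approx(4.907e-11, rel=1e-3)

    def test_reciprocal_linearity_in_tau(self, geometry, solvent):
        m1 = p.mode_to_radius(p.RelaxationMode(1.0, 1e-4, 0.8), geometry, solvent)
        m2 = p.mode_to_radius(p.RelaxationMode(1.0, 2e-4, 0.8), geometry, solvent)
        assert m2.diffusion_coefficient == pytest.approx(m1.diffusion_coefficient / 2)
        assert m2.hydrodynamic_radius_nm == pytest.approx(2 * m1.hydrodynamic_radius_nm)

    @settings(derandomize=True, max_examples=40)
    @given(radius=st.floats(0.5, 5000.0), angle=st.floats(10.0, 175.0),
           temp=st.floats(278.0, 348.0))
    def test_radius_round_trip_identity(self, radius, angle, temp):
        geom = p.ScatteringGeometry(633.0, angle, 1.33)
        solv = p.solvent_properties(temp, 0.1)
        tau = p.radius_to_relaxation_time(radius, geom, solv)
        back = p.mode_to_radius(p.RelaxationMode(1.0, tau, 0.8), geom, solv)
        assert back.hydrodynamic_radius_nm == pytest.approx(radius, rel=1e-9)


class TestFitCorrelation:
    def test_single_mode_self_consistency(self, geometry, solvent, lag_grid):
        spec = p.PopulationSpec(free_radius_nm=5.0, aggregate_radius_nm=140.0,
                                free_intensity_fraction=1.0, stretch_free=0.8)
        curve = p.simulate_correlation(spec, geometry, solvent,
                                       np.geomspace(1e-7, 1e-2, 200))
        fit = p.fit_correlation(curve, 1)
        truth = p.radius_to_relaxation_time(5.0, geometry, solvent)
        mode = fit.modes[0]
        assert mode.relaxation_time == pytest.approx(truth, rel=1e-3)
        assert mode.stretch == pytest.approx(0.8, rel=1e-3)
        assert mode.amplitude == pytest.approx(1.0, rel=1e-3)

    def test_two_mode_recovery_noise_free(self, geometry, solvent, lag_grid):
        # radius ratio 140/5 -> tau ratio 28, equal intensity fractions
        spec = p.PopulationSpec(5.0, 140.0, 0.5)
        curve = p.simulate_correlation(spec, geometry, solvent, lag_grid)
        fit = p.fit_correlation(curve, 2)
        tau_f = p.radius_to_relaxation_time(5.0, geometry, solvent)
        tau_a = p.radius_to_relaxation_time(140.0, geometry, solvent)
        assert fit.modes[0].relaxation_time == pytest.approx(tau_f, rel=0.01)
        assert fit.modes[1].relaxation_time == pytest.approx(tau_a, rel=0.01)
        assert fit.modes[0].amplitude == pytest.approx(0.5, rel=0.01)
        assert fit.modes[1].amplitude == pytest.approx(0.5, rel=0.01)

    def test_overfitting_single_mode_with_two_is_flagged(self, geometry, solvent):
        spec = p.PopulationSpec(5.0, 140.0, 1.0)
        curve = p.simulate_correlation(spec, geometry, solvent,
                                       np.geomspace(1e-7, 1e-2, 200))
        fit1 = p.fit_correlation(curve, 1)
        fit2 = p.fit_correlation(curve, 2)
        # no second relaxation: the extra mode buys no real improvement
        # (the information criterion does not accept it) and the fit is flagged
        assert fit2.residual_norm < 1e-6
        assert fit1.aicc - fit2.aicc < 10.0
        total = sum(m.amplitude for m in fit2.modes)
        coalesced = fit2.modes[1].relaxation_time / fit2.modes[0].relaxation_time < 1.5
        vanished = min(m.amplitude for m in fit2.modes) < 0.02 * total
        assert coalesced or vanished
        assert fit2.warnings

    def test_constant_trace_rejected(self, geometry, solvent):
        t = np.geomspace(1e-6, 1e-2, 50)
        curve = p.CorrelationCurve(t, np.full_like(t, 0.5), geometry, solvent)
        with pytest.raises(DegenerateInputError):
            p.fit_correlation(curve, 1)

    def test_oracle_log_grid_brute_force(self, geometry, solvent):
        """The fitter agrees with an independent brute-force (tau, gamma) scan."""
        tau_true, gamma_true = 8e-4, 0.8
        t = np.geomspace(1e-6, 1e-1, 200)
        curve = p.CorrelationCurve(
            t, np.exp(-np.power(t / tau_true, gamma_true)), geometry, solvent)

        taus = np.geomspace(1e-5, 1e-2, 121)      # 40 pts/decade
        gammas = np.linspace(0.6, 1.0, 41)
        best = (np.inf, None, None)
        for tau in taus:
            for g in gammas:
                model = np.exp(-np.power(t / tau, g))
                rss = float(np.sum((model - curve.g_minus_1) ** 2))
                if rss < best[0]:
                    best = (rss, tau, g)
        fit = p.fit_correlation(curve, 1)
        tau_step = taus[1] / taus[0]
        assert best[1] / tau_step <= fit.modes[0].relaxation_time <= best[1] * tau_step
        assert abs(fit.modes[0].stretch - best[2]) <= gammas[1] - gammas[0]


class TestSelectModeCount:
    def test_single_population(self, geometry, solvent):
        curve = p.simulate_correlation(p.PopulationSpec(5.0, 140.0, 1.0),
                                       geometry, solvent,
                                       np.geomspace(1e-7, 1e-2, 200),
                                       noise_sd=0.01, seed=1)
        assert p.select_mode_count(curve) == 1

    def test_two_populations(self, geometry, solvent, lag_grid):
        curve = p.simulate_correlation(p.PopulationSpec(5.0, 140.0, 0.5),
                                       geometry, solvent, lag_grid,
                                       noise_sd=0.01, seed=2)
        assert p.select_mode_count(curve) == 2

    def test_aggregate_below_amplitude_floor(self, geometry, solvent, lag_grid):
        curve = p.simulate_correlation(p.PopulationSpec(5.0, 140.0, 0.99),
                                       geometry, solvent, lag_grid,
                                       noise_sd=0.01, seed=3)
        assert p.select_mode_count(curve) == 1


class TestIntensityFractions:
    def test_equal_amplitudes(self):
        fit = p.ModeFit([p.RelaxationMode(0.4, 1e-4, 0.8),
                         p.RelaxationMode(0.4, 1e-2, 0.8)],
                        residual_norm=0.0, n_modes=2, converged=True)
        assert p.intensity_fractions(fit) == (0.5, 0.5)

    def test_fractions_normalized(self):
        fit = p.ModeFit([p.RelaxationMode(0.3, 1e-4, 0.8),
                         p.RelaxationMode(0.9, 1e-2, 0.8)],
                        residual_norm=0.0, n_modes=2, converged=True)
        ff, fa = p.intensity_fractions(fit)
        assert ff + fa == pytest.approx(1.0)
        assert ff == pytest.approx(0.25)

    def test_lone_fast_mode_is_free(self, geometry, solvent):
        tau = p.radius_to_relaxation_time(5.0, geometry, solvent)
        fit = p.ModeFit([p.RelaxationMode(1.0, tau, 0.8)],
                        residual_norm=0.0, n_modes=1, converged=True)
        assert p.intensity_fractions(fit, geometry, solvent) == (1.0, 0.0)

    def test_lone_slow_mode_is_aggregate(self, geometry, solvent):
        tau = p.radius_to_relaxation_time(140.0, geometry, solvent)
        fit = p.ModeFit([p.RelaxationMode(1.0, tau, 0.8)],
                        residual_norm=0.0, n_modes=1, converged=True)
        assert p.intensity_fractions(fit, geometry, solvent) == (0.0, 1.0)

    def test_dominant_free_population_recovered(self, geometry, solvent, lag_grid):
        curve = p.simulate_correlation(p.PopulationSpec(5.0, 140.0, 0.95),
                                       geometry, solvent, lag_grid,
                                       noise_sd=0.01, seed=4)
        fit = p.fit_correlation(curve, 2)
        ff, fa = p.intensity_fractions(fit)
        assert abs(ff - 0.95) < 0.02
        assert abs(fa - 0.05) < 0.02


class TestDiffusiveScaling:
    ANGLES = (30.0, 60.0, 90.0, 120.0, 150.0)

    def _fits_at_angles(self, solvent, radius_nm, noise_sd=0.0, seed=None,
                        angle_independent_tau=None):
        fits = []
        for i, angle in enumerate(self.ANGLES):
            geom = p.ScatteringGeometry(633.0, angle, 1.33)
            if angle_independent_tau is None:
                tau = p.radius_to_relaxation_time(radius_nm, geom, solvent)
            else:
                tau = angle_independent_tau
            lag = np.geomspace(tau / 1000, tau * 50, 150)
            curve = p.simulate_correlation(
                p.PopulationSpec(radius_nm, 1000.0, 1.0, stretch_free=0.85),
                geom, solvent, lag, noise_sd=noise_sd,
                seed=None if seed is None else seed + i)
            if angle_independent_tau is not None:
                curve = p.CorrelationCurve(
                    lag, np.exp(-np.power(lag / tau, 0.85)), geom, solvent)
            fits.append((angle, p.fit_correlation(curve, 1)))
        return fits

    def test_noise_free_slope_is_diffusion_coefficient(self, solvent):
        fits = self._fits_at_angles(solvent, 5.0)
        geom = p.ScatteringGeometry(633.0, 90.0, 1.33)
        d_true = p.mode_to_radius(fits[0][1].modes[0],
                                  p.ScatteringGeometry(633.0, self.ANGLES[0], 1.33),
                                  solvent).diffusion_coefficient
        res = p.diffusive_scaling_check(fits, geom, solvent)
        assert res.slope == pytest.approx(d_true, rel=1e-3)
        assert res.r_squared > 0.9999
        assert res.diffusive
        assert abs(res.intercept) < 0.01 * res.slope * p.scattering_vector(geom) ** 2

    def test_noisy_slope_within_five_percent(self, solvent):
        fits = self._fits_at_angles(solvent, 5.0, noise_sd=0.02, seed=11)
        geom = p.ScatteringGeometry(633.0, 90.0, 1.33)
        tau90 = p.radius_to_relaxation_time(5.0, geom, solvent)
        d_true = 1.0 / (tau90 * p.scattering_vector(geom) ** 2)
        res = p.diffusive_scaling_check(fits, geom, solvent)
        assert res.slope == pytest.approx(d_true, rel=0.05)

    def test_angle_independent_relaxation_is_non_diffusive(self, solvent):
        fits = self._fits_at_angles(solvent, 5.0, angle_independent_tau=1e-4)
        geom = p.ScatteringGeometry(633.0, 90.0, 1.33)
        res = p.diffusive_scaling_check(fits, geom, solvent)
        assert res.r_squared < 0.1
        assert not res.diffusive

    def test_requires_three_angles(self, solvent, geometry):
        fit = p.ModeFit([p.RelaxationMode(1.0, 1e-4, 0.8)], 0.0, 1, True)
        with pytest.raises(InsufficientDataError):
            p.diffusive_scaling_check([(90.0, fit), (120.0, fit)], geometry, solvent)
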