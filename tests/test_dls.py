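"""DLS: wave vector, correlogram fits, sizing, adsorbed-layer scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiscope.dls import (
    BoundLayerSeries,
    CorrelogramTrace,
    bound_layer_thickness,
    compute_wave_vector,
    fit_correlogram,
    fit_layer_scaling,
    stokes_einstein,
)
from vesiscope.solvents import water_viscosity
from vesiscope.synthetic import gen_correlogram


class TestWaveVector:
    @pytest.mark.parametrize(
        "wavelength,n,angle,expected",
        [
            (633e-9, 1.33, 173.0, 2.635e7),
            (633e-9, 1.33, 0.0, 0.0),
            (633e-9, 1.33, 180.0, 4 * np.pi * 1.33 / 633e-9),
        ],
    )
    def test_examples(self, wavelength, n, angle, expected):
        assert compute_wave_vector(wavelength, n, angle) == pytest.approx(
            expected, rel=1e-3, abs=1.0
        )

    @given(st.floats(min_value=0.0, max_value=179.0))
    @settings(deadline=None)
    def test_monotone_in_angle(self, angle):
        q1 = compute_wave_vector(633e-9, 1.33, angle)
        q2 = compute_wave_vector(633e-9, 1.33, angle + 1.0)
        assert q2 > q1

    @pytest.mark.parametrize(
        "bad", [(-633e-9, 1.33, 90.0), (633e-9, 0.9, 90.0), (633e-9, 1.33, 200.0)]
    )
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            compute_wave_vector(*bad)


class TestStokesEinstein:
    def test_table_consistency(self):
        # D_T of the bare ~120 nm vesicles at 35 degC maps back to their size
        R = stokes_einstein(5.21e-12, 308.15, 7.19e-4, "D->R")
        assert 2 * R * 1e9 == pytest.approx(120.6, abs=0.2)

    def test_r_to_d(self):
        D = stokes_einstein(50e-9, 298.15, 8.9e-4, "R->D")
        assert D == pytest.approx(4.91e-12, rel=0.01)

    def test_viscosity_inverse_proportionality(self):
        D1 = stokes_einstein(50e-9, 298.15, 8.9e-4, "R->D")
        D2 = stokes_einstein(50e-9, 298.15, 2 * 8.9e-4, "R->D")
        assert D1 == pytest.approx(2 * D2, rel=1e-12)

    @given(
        st.floats(min_value=1e-13, max_value=1e-10),
        st.floats(min_value=274.0, max_value=372.0),
        st.floats(min_value=1e-4, max_value=1e-2),
    )
    @settings(deadline=None)
    def test_round_trip_identity(self, D, T, eta):
        R = stokes_einstein(D, T, eta, "D->R")
        assert stokes_einstein(R, T, eta, "R->D") == pytest.approx(D, rel=1e-12)

    @pytest.mark.parametrize("T,eta", [(0.0, 1e-3), (300.0, 0.0), (300.0, -1e-3)])
    def test_invalid_inputs(self, T, eta):
        with pytest.raises(ValueError):
            stokes_einstein(1e-12, T, eta)


class TestWaterViscosity:
    @pytest.mark.parametrize(
        "T_C,eta_mPas",
        [(10, 1.3059), (15, 1.1375), (20, 1.0016), (25, 0.8900),
         (30, 0.7972), (35, 0.7191), (40, 0.6527)],
    )
    def test_reference_values(self, T_C, eta_mPas):
        assert water_viscosity(T_C + 273.15) * 1e3 == pytest.approx(
            eta_mPas, rel=0.01
        )

    def test_monotone_decreasing(self):
        T = np.linspace(283.15, 313.15, 100)
        eta = water_viscosity(T)
        assert np.all(np.diff(eta) < 0)

    @pytest.mark.parametrize("T", [272.0, 273.0, 373.0, 400.0])
    def test_range_error(self, T):
        with pytest.raises(ValueError):
            water_viscosity(T)


class TestFitCorrelogram:
    def test_noiseless_exact(self, q_173):
        tau = np.logspace(-5, -2, 100)
        trace = CorrelogramTrace(tau, 1.0 * np.exp(-2 * 100.0 * tau), q_173, 308.15)
        fit = fit_correlogram(trace)
        assert fit.converged
        assert fit.gamma == pytest.approx(100.0, rel=1e-8)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-8)

    def test_noisy_recovery_within_2_percent(self, q_173):
        D = 500.0 / q_173**2  # Gamma = 500 1/s
        trace = gen_correlogram(D, q_173, amplitude=0.9, noise_sd=0.01,
                                n_points=200, seed=1)
        fit = fit_correlogram(trace)
        assert fit.gamma == pytest.approx(500.0, rel=0.02)

    def test_recovery_statistics(self, q_173):
        """Median relative error < 2% and bias < 0.5% over 100 seeds."""
        gamma_true = 5.21e-12 * q_173**2
        errs = []
        for seed in range(100):
            trace = gen_correlogram(5.21e-12, q_173, noise_sd=0.01, seed=seed)
            fit = fit_correlogram(trace)
            errs.append((fit.gamma - gamma_true) / gamma_true)
        errs = np.asarray(errs)
        assert np.median(np.abs(errs)) < 0.02
        assert abs(np.mean(errs)) < 0.005

    def test_constant_trace_flagged(self, q_173):
        tau = np.logspace(-5, -2, 50)
        trace = CorrelogramTrace(tau, np.full(50, 0.5), q_173, 308.15)
        assert not fit_correlogram(trace).converged

    def test_too_few_points(self, q_173):
        tau = np.logspace(-5, -3, 5)
        trace = CorrelogramTrace(tau, np.exp(-2 * 100 * tau), q_173, 308.15)
        with pytest.raises(ValueError):
            fit_correlogram(trace)

    def test_sizes_via_solvent_model(self, q_173):
        """Round trip through generation at a known diameter."""
        D = stokes_einstein(59.95e-9, 308.15, water_viscosity(308.15), "R->D")
        trace = gen_correlogram(D, q_173, noise_sd=0.0, seed=0)
        fit = fit_correlogram(trace)
        assert 2 * fit.R_h * 1e9 == pytest.approx(119.9, rel=1e-6)


class TestBoundLayer:
    @pytest.mark.parametrize(
        "d_mix,d_neat,expected",
        [(157.7, 119.9, 18.9), (121.4, 119.9, 0.75), (119.9, 119.9, 0.0)],
    )
    def test_thickness_examples(self, d_mix, d_neat, expected):
        assert bound_layer_thickness(d_mix, d_neat) == pytest.approx(expected)

    @given(st.floats(min_value=1.0, max_value=1e3),
           st.floats(min_value=1.0, max_value=1e3))
    @settings(deadline=None)
    def test_antisymmetry(self, a, b):
        assert bound_layer_thickness(a, b) == pytest.approx(
            -bound_layer_thickness(b, a)
        )

    def test_exact_power_law_slope(self):
        mw = np.array([1e3, 1e4, 1e5, 1e6])
        series = BoundLayerSeries(mw, 0.01 * mw**0.58, 119.9)
        slope, _ = fit_layer_scaling(series)
        assert slope == pytest.approx(0.58, rel=1e-12)

    def test_measured_layer_series_slope(self):
        """Layer thicknesses of the four polymer conditions give ~0.56."""
        mw = np.array([1.5e3, 2e4, 1e5, 4e5])
        deltas = np.array([0.75, 4.85, 7.9, 18.9])
        slope, _ = fit_layer_scaling(BoundLayerSeries(mw, deltas, 119.9))
        assert slope == pytest.approx(0.5623, abs=0.001)

    def test_flat_series(self):
        series = BoundLayerSeries(np.array([1e3, 1e4, 1e5]), np.array([5.0, 5.0, 5.0]), 100.0)
        slope, _ = fit_layer_scaling(series)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_deltas_excluded(self):
        series = BoundLayerSeries(
            np.array([1e3, 1e4, 1e5]), np.array([-0.5, 4.0, 8.0]), 100.0
        )
        slope, _ = fit_layer_scaling(series)
        # slope from the two positive points only
        expected = (np.log10(8.0) - np.log10(4.0)) / 1.0
        assert slope == pytest.approx(expected)

    def test_insufficient_positive_pairs(self):
        series = BoundLayerSeries(np.array([1e3, 1e4]), np.array([-1.0, 4.0]), 100.0)
        with pytest.raises(ValueError):
            fit_layer_scaling(series)

    def test_log_base_invariance(self):
        """The exponent is the same whether fitted in ln or log10 space."""
        mw = np.array([1.5e3, 2e4, 1e5, 4e5])
        deltas = np.array([0.75, 4.85, 7.9, 18.9])
        slope, _ = fit_layer_scaling(BoundLayerSeries(mw, deltas, 119.9))
        slope_ln = np.polyfit(np.log(mw), np.log(deltas), 1)[0]
        assert slope == pytest.approx(slope_ln, rel=1e-12)
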