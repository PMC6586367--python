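"""Self-consistent mean-field solver: threshold, resonance, sharpening,
heterogeneity, linear response, and the oscillatory drive."""

import numpy as np
import pytest

from dmftnet import (
    AdaptationParams,
    SolverConfig,
    Spectrum,
    critical_coupling,
    heterogeneous_gain,
    linear_response_prediction,
    make_adaptation_model,
    make_general_model,
    resonance_frequency,
    sharpening_iterates,
    single_unit_gain,
    solve_self_consistent_spectrum,
    solve_with_oscillatory_drive,
)
from dmftnet.metrics import q_factor, variance_decomposition

TABLE_3D = [[-1.0, -1.0, -1.0], [0.1, 0.1, 1.7], [0.1, -0.4, -0.5]]


@pytest.fixture(scope="module")
def resonant_solution(coarse_config):
    model = make_adaptation_model(AdaptationParams(0.25, 1.0))
    gc = critical_coupling(model)
    return solve_self_consistent_spectrum(model, 2 * gc, config=coarse_config)


class TestThreshold:
    def test_zero_spectrum_below_criticality(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        sol = solve_self_consistent_spectrum(model, 0.9 * gc,
                                             config=coarse_config)
        assert sol.converged
        assert sol.spectrum_x.values.max() <= 1e-8

    def test_nonzero_spectrum_above_criticality(self, resonant_solution):
        assert resonant_solution.converged
        assert resonant_solution.variance > 0.1

    def test_transition_located_at_gc(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        variances = []
        for ratio in [0.85, 0.95, 1.05, 1.15]:
            sol = solve_self_consistent_spectrum(model, ratio * gc,
                                                 config=coarse_config)
            variances.append(sol.variance)
        assert variances[0] == 0.0 and variances[1] == 0.0
        assert variances[2] > 0.0 and variances[3] > variances[2]


class TestResonantSpectrum:
    def test_peak_at_single_unit_resonance(self, resonant_solution,
                                           coarse_config):
        f0 = resonance_frequency(AdaptationParams(0.25, 1.0))
        f_p = resonant_solution.peak_frequency()
        assert abs(f_p - f0) <= 2 * coarse_config.freq_step

    def test_nonresonant_spectrum_peaks_at_zero(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(1.0, 0.1))
        gc = critical_coupling(model)
        sol = solve_self_consistent_spectrum(model, 2 * gc,
                                             config=coarse_config)
        assert sol.peak_frequency() == 0.0

    def test_fixed_point_residual(self, resonant_solution, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        _, G = single_unit_gain(model, coarse_config.frequencies)
        lhs = resonant_solution.spectrum_x.values
        rhs = G * (2 * gc) ** 2 * resonant_solution.spectrum_rate.values
        assert np.sum(np.abs(lhs - rhs)) / np.sum(lhs) < 1e-6

    def test_solution_independent_of_initial_level(self, coarse_config):
        # the fixed point must not remember the arbitrary starting constant
        from dataclasses import replace

        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        base = solve_self_consistent_spectrum(model, 2 * gc,
                                              config=coarse_config)
        alt = solve_self_consistent_spectrum(
            model, 2 * gc, config=replace(coarse_config, initial_variance=25.0))
        np.testing.assert_allclose(alt.spectrum_x.values,
                                   base.spectrum_x.values,
                                   rtol=2e-4, atol=1e-8)

    def test_q_factor_exceeds_single_unit(self, resonant_solution,
                                          coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        _, G = single_unit_gain(model, coarse_config.frequencies)
        q_unit = q_factor(Spectrum(coarse_config.freq_step, G)).q_factor
        q_net = q_factor(resonant_solution.spectrum_x).q_factor
        assert q_net > q_unit

    def test_general_three_dimensional_model(self, coarse_config):
        from dmftnet.stability import argmax_gain

        model = make_general_model(TABLE_3D)
        gc = critical_coupling(model)
        sol = solve_self_consistent_spectrum(
            model, 2 * gc,
            config=SolverConfig(freq_step=0.002, max_freq=1.0,
                                nonlinearity_method="series_pl",
                                max_iterations=400, seed=0))
        assert sol.converged and sol.variance > 0.05
        f_star = argmax_gain(model)
        assert abs(sol.peak_frequency() - f_star) <= 0.01


class TestSharpening:
    def test_first_iterate_proportional_to_gain(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        iterates, predictions = sharpening_iterates(model, 2 * gc, 3,
                                                    config=coarse_config)
        np.testing.assert_allclose(iterates[0].values, predictions[0].values,
                                   atol=1e-12)

    def test_width_shrinks_over_iterations(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        iterates, _ = sharpening_iterates(model, 2 * gc, 3,
                                          config=coarse_config)
        widths = [q_factor(s).half_max_width for s in iterates]
        assert widths[0] > widths[1] > widths[2]


class TestHeterogeneousGain:
    def test_zero_spread_is_exact_gain(self):
        f = np.linspace(0, 1, 101)
        params = AdaptationParams(0.25, 1.0)
        model = make_adaptation_model(params)
        _, G = single_unit_gain(model, f)
        np.testing.assert_allclose(
            heterogeneous_gain(1.0, 0.0, 0.25, f), G, rtol=1e-12)

    def test_dc_enhancement(self):
        G0 = heterogeneous_gain(1.0, 0.0, 0.25, [0.0])[0]
        GH0 = heterogeneous_gain(1.0, 0.5, 0.25, [0.0])[0]
        assert GH0 == pytest.approx(G0 / (1 - 0.25 * G0), rel=1e-12)
        assert GH0 > G0

    def test_low_frequency_only_deviation(self, coarse_config):
        f = coarse_config.frequencies
        params = AdaptationParams(0.25, 1.0)
        model = make_adaptation_model(params)
        _, G = single_unit_gain(model, f)
        GH = heterogeneous_gain(1.0, 0.5, 0.25, f)
        rel = np.abs(GH - G) / G
        assert rel[f < 0.02].max() > 0.01
        assert rel[f > 0.4].max() < 1e-3

    def test_too_strong_heterogeneity_rejected(self):
        with pytest.raises(ValueError):
            heterogeneous_gain(1.0, 10.0, 0.25, [0.0])


class TestLinearResponse:
    def test_zero_coupling_is_single_unit(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        f = coarse_config.frequencies
        noise = Spectrum(coarse_config.freq_step, np.ones(f.size))
        out, _ = linear_response_prediction(model, 0.0, noise, 0.1, 0.1)
        _, G = single_unit_gain(model, f)
        k = int(round(0.1 / coarse_config.freq_step))
        mask = np.ones(f.size, bool)
        mask[k] = False
        np.testing.assert_allclose(out.values[mask], G[mask], rtol=1e-10)

    def test_snr_independent_of_adaptation(self, coarse_config):
        noise = Spectrum(coarse_config.freq_step,
                         np.ones(coarse_config.frequencies.size))
        snrs = []
        for gamma, beta in [(0.25, 1.0), (1.0, 0.1)]:
            model = make_adaptation_model(AdaptationParams(gamma, beta))
            gc = critical_coupling(model)
            _, snr = linear_response_prediction(
                model, 0.3 * gc, noise, 0.2, 0.1)
            snrs.append(snr)
        assert snrs[0] == pytest.approx(snrs[1], rel=1e-12)

    def test_rejects_supercritical_coupling(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        noise = Spectrum(coarse_config.freq_step,
                         np.ones(coarse_config.frequencies.size))
        with pytest.raises(ValueError):
            linear_response_prediction(model, gc, noise, 0.1, 0.1)


@pytest.fixture(scope="module")
def driven_config():
    return SolverConfig(freq_step=0.002, max_freq=1.0,
                        nonlinearity_method="montecarlo",
                        mc_samples=256, max_iterations=60,
                        damping=0.5, seed=5)


class TestOscillatoryDrive:

    def test_zero_amplitude_equals_undriven(self, coarse_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        driven = solve_with_oscillatory_drive(model, 2 * gc, 0.0, 0.12,
                                              config=coarse_config)
        undriven = solve_self_consistent_spectrum(model, 2 * gc,
                                                  config=coarse_config)
        np.testing.assert_array_equal(driven.spectrum_x.values,
                                      undriven.spectrum_x.values)

    def test_off_grid_frequency_rejected(self, driven_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        with pytest.raises(ValueError):
            solve_with_oscillatory_drive(model, 2.0, 0.5, 0.1234567,
                                         config=driven_config)
        with pytest.raises(ValueError):
            solve_with_oscillatory_drive(model, 2.0, -0.5, 0.12,
                                         config=driven_config)

    def test_weak_drive_peaks_on_live_background(self, driven_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        sol = solve_with_oscillatory_drive(model, 2 * gc, 0.5, 0.12,
                                           config=driven_config)
        vd = variance_decomposition(sol)
        # sharp fundamental and odd harmonic, chaotic background survives
        assert sol.oscillatory_peaks[1] > 0.1
        assert sol.oscillatory_peaks[3] > 0.0
        # even harmonic carries only Monte-Carlo estimator noise
        assert sol.oscillatory_peaks[2] < 1e-3 * sol.oscillatory_peaks[1]
        assert vd.background_power > 1.0
        undriven = solve_self_consistent_spectrum(
            model, 2 * gc, config=driven_config).variance
        # total variance stays near the undriven level (weak drive)
        assert vd.background_power + vd.oscillatory_power == pytest.approx(
            undriven, rel=0.25)

    def test_strong_drive_near_resonance_suppresses_chaos(self,
                                                          driven_config):
        model = make_adaptation_model(AdaptationParams(0.25, 1.0))
        gc = critical_coupling(model)
        sol = solve_with_oscillatory_drive(model, 2 * gc, 1.5, 0.102,
                                           config=driven_config)
        vd = variance_decomposition(sol)
        undriven = solve_self_consistent_spectrum(
            model, 2 * gc, config=driven_config).variance
        assert vd.background_power < 0.25 * undriven
        assert vd.oscillatory_power > vd.background_power
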