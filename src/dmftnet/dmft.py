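"""Self-consistent mean-field theory for the network power spectrum.

In the large-``N`` limit the recurrent input to one unit becomes a
zero-mean Gaussian process whose power spectrum must satisfy

    S_x(f) = G(f) (g^2 S_phi(x)(f) + S_I(f)),

where ``G(f)`` is the squared single-unit susceptibility and
``S_phi(x)`` is the spectrum of the rate ``phi(x)``, itself a functional
of ``S_x``.  The fixed point is found by damped iteration alternating a
linear step (multiplication by ``g^2 G``) and a nonlinear step (one of
the Gaussian-nonlinearity maps).  Below the critical coupling
``g_c = 1/sqrt(max G)`` the iteration collapses to the zero spectrum;
above it, a nonzero continuous spectrum emerges whose peak frequency
equals the single-unit resonance frequency ``f_0`` — chaos inherits, and
sharpens, the single-unit frequency preference.

An oscillatory drive ``A_I cos(2 pi f_I t + theta)`` adds delta peaks to
the spectrum.  The activation is split into a Gaussian background plus a
periodic component carried as peak masses at the harmonics ``k f_I``;
the nonlinear step then uses Monte-Carlo sampling with an explicit
oscillation, and the peak/background separation is done by interpolating
the spectrum at the bins neighbouring each harmonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .rate_model import RateModel, single_unit_gain
from .spectra import Autocorr, Spectrum, autocorr_to_spectrum, spectrum_to_autocorr
from .gaussian_nonlinearity import (
    map_autocorr_piecewise_linear,
    map_autocorr_polynomial,
    map_autocorr_quadrature,
    periodogram,
    sample_gaussian_paths,
)

__all__ = [
    "SolverConfig",
    "DMFTSolution",
    "solve_self_consistent_spectrum",
    "solve_with_oscillatory_drive",
    "heterogeneous_gain",
    "linear_response_prediction",
    "sharpening_iterates",
]

_ZERO_FLOOR = 1e-10


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the self-consistency iteration.

    ``freq_step`` is the frequency bin (0.001 by default); the grid spans
    ``[0, max_freq]`` rounded up so the two-sided grid size is a power of
    two.  ``damping`` is the initial mixing weight of the update; it is
    halved automatically (not below 0.25) when the residual oscillates.
    """

    freq_step: float = 0.001
    max_freq: float = 2.0
    tolerance: float = 1e-6
    max_iterations: int = 2000
    damping: float = 1.0
    nonlinearity_method: str = "series_pl"  # polynomial | quadrature | montecarlo
    mc_samples: int = 256
    initial_variance: float = 1.0  # level of the constant starting spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq_step <= 0 or self.max_freq <= self.freq_step:
            raise ValueError("invalid frequency grid")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must lie in (0, 1]")
        if self.nonlinearity_method not in (
            "series_pl", "polynomial", "quadrature", "montecarlo"
        ):
            raise ValueError(
                f"unknown nonlinearity method {self.nonlinearity_method!r}")

    @property
    def n_onesided(self) -> int:
        """Number of grid points for f >= 0 (two-sided size is 2(n-1))."""
        m = int(np.ceil(self.max_freq / self.freq_step))
        n2 = 1 << int(np.ceil(np.log2(2 * m)))
        return n2 // 2 + 1

    @property
    def frequencies(self) -> np.ndarray:
        return self.freq_step * np.arange(self.n_onesided)


@dataclass
class DMFTSolution:
    """Converged (or best-iterate) self-consistent solution."""

    spectrum_x: Spectrum
    spectrum_rate: Spectrum
    oscillatory_peaks: Dict[int, float] = field(default_factory=dict)
    drive_frequency: Optional[float] = None
    iterations: int = 0
    converged: bool = False
    residual_history: List[float] = field(default_factory=list)
    config: Optional[SolverConfig] = None

    @property
    def variance(self) -> float:
        """Total variance: background integral plus twice the peak masses."""
        return self.spectrum_x.variance + 2.0 * sum(
            self.oscillatory_peaks.values())

    @property
    def is_zero(self) -> bool:
        return (self.spectrum_x.values.max() < _ZERO_FLOOR
                and not self.oscillatory_peaks)

    def peak_frequency(self) -> float:
        """Grid frequency of maximal background power."""
        return float(self.spectrum_x.frequencies[
            int(np.argmax(self.spectrum_x.values))])


def _nonlinear_step(spectrum: Spectrum, model: RateModel,
                    config: SolverConfig, rng) -> Spectrum:
    method = config.nonlinearity_method
    if method == "montecarlo":
        from .gaussian_nonlinearity import map_spectrum_montecarlo

        return map_spectrum_montecarlo(
            spectrum, model.nonlinearity, n_samples=config.mc_samples,
            seed=int(rng.integers(2**31)))
    ac = spectrum_to_autocorr(spectrum)
    if method == "series_pl":
        if model.nonlinearity.kind != "piecewise_linear":
            raise ValueError(
                "series_pl nonlinear step requires the piecewise_linear "
                "nonlinearity")
        out = map_autocorr_piecewise_linear(ac)
    elif method == "polynomial":
        if model.nonlinearity.poly_coeffs is None:
            raise ValueError(
                "polynomial nonlinear step requires a polynomial nonlinearity")
        out = map_autocorr_polynomial(ac, model.nonlinearity.poly_coeffs)
    else:
        out = map_autocorr_quadrature(ac, model.nonlinearity)
    return autocorr_to_spectrum(out)


def _residual(new: np.ndarray, old: np.ndarray) -> float:
    scale = np.sum(np.abs(old))
    if scale < _ZERO_FLOOR:
        return float(np.sum(np.abs(new - old)))
    return float(np.sum(np.abs(new - old)) / scale)


def solve_self_consistent_spectrum(
    model: RateModel,
    g: float,
    input_spectrum: Optional[Spectrum] = None,
    config: Optional[SolverConfig] = None,
) -> DMFTSolution:
    """Iterate ``S_x <- G (g^2 S_phi + S_I)`` to the self-consistent PSD.

    Starts from a constant (white) rate spectrum with unit variance.  For
    ``g < g_c`` the solution is the zero spectrum (detected when the
    maximum drops below 1e-10); for ``g > g_c`` the iteration converges to
    a nonzero continuous spectrum.  Stochastic (Monte-Carlo) nonlinear
    steps assess convergence on a 5-iteration moving average of the
    residual.
    """
    if g < 0:
        raise ValueError("coupling g must be non-negative")
    config = config or SolverConfig()
    rng = np.random.default_rng(config.seed)
    freqs = config.frequencies
    _, G = single_unit_gain(model, freqs)
    if input_spectrum is not None:
        if input_spectrum.values.size != freqs.size or not np.isclose(
            input_spectrum.freq_step, config.freq_step
        ):
            raise ValueError("input spectrum grid does not match the solver grid")
        S_I = input_spectrum.values
    else:
        S_I = np.zeros_like(freqs)

    # constant initial rate spectrum (variance set by the config)
    n2 = 2 * (freqs.size - 1)
    S_phi = np.full(freqs.size,
                    config.initial_variance / (config.freq_step * n2))
    S_x = G * (g * g * S_phi + S_I)

    stochastic = config.nonlinearity_method == "montecarlo"
    alpha = config.damping
    history: List[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        S_phi = _nonlinear_step(
            Spectrum(config.freq_step, S_x), model, config, rng).values
        S_new = G * (g * g * S_phi + S_I)
        if not np.all(np.isfinite(S_new)) or S_new.max() > 1e12:
            raise ArithmeticError(
                f"solver diverged at iteration {it} (unbounded spectrum)")
        res = _residual(S_new, S_x)
        history.append(res)
        S_x = (1 - alpha) * S_x + alpha * S_new
        if S_x.max() < _ZERO_FLOOR and S_I.max() == 0.0:
            S_x = np.zeros_like(S_x)
            S_phi = np.zeros_like(S_phi)
            converged = True
            break
        if stochastic:
            window = history[-5:]
            if len(window) == 5 and np.mean(window) <= config.tolerance:
                converged = True
                break
        elif res <= config.tolerance:
            converged = True
            break
        # halve damping if the residual ping-pongs
        if (len(history) >= 4 and alpha > 0.25
                and history[-1] > history[-2] > 0
                and history[-3] > history[-4] > 0
                and history[-2] < history[-3]):
            alpha = max(0.25, alpha / 2)
    return DMFTSolution(
        spectrum_x=Spectrum(config.freq_step, S_x),
        spectrum_rate=Spectrum(config.freq_step, np.clip(S_phi, 0, None)),
        iterations=it,
        converged=converged,
        residual_history=history,
        config=config,
    )


def solve_with_oscillatory_drive(
    model: RateModel,
    g: float,
    amplitude: float,
    frequency: float,
    config: Optional[SolverConfig] = None,
    max_harmonics: int = 8,
) -> DMFTSolution:
    """Self-consistent solution under phase-randomized sinusoidal drive.

    The drive PSD is a delta pair of mass ``A_I^2/4`` at ``+-f_I``.  The
    activation is split into a Gaussian background (continuous spectrum
    ``S_bkg``) plus a periodic component carried as peak masses ``b_k`` at
    the harmonics ``k f_I``.  Only the direct drive acts coherently on a
    unit; the oscillatory feedback from the rest of the network arrives
    through random couplings with random phases and therefore adds
    incoherently, in power: ``b_k = G(k f_I) (g^2 c_k + delta_k1 A_I^2/4)``
    where ``c_k`` are the peak masses of the rate.

    The nonlinear step is Monte-Carlo: Gaussian background paths plus a
    periodic part with per-sample random harmonic coefficients
    ``d_1 = chi(f_I) (A_I/2 e^{i theta} + e_1)``,
    ``d_k = chi(k f_I) e_k``, ``e_k ~ CN(0, g^2 c_k)``; the averaged
    periodogram is separated into peak masses and background by
    interpolating the spectrum at the neighbouring bins.  Because the
    oscillatory feedback loop can amplify perturbations by an order of
    magnitude near resonance, the fundamental's self-consistency
    ``c_1 = M(c_1)`` is solved by bracketing and bisection (with common
    random numbers) at each outer iteration, keeping the smallest
    non-negative root — the branch continuously connected to the weak
    drive response; plain forward iteration falls onto the fully
    entrained branch even when the chaotic background survives.
    """
    if amplitude < 0:
        raise ValueError("drive amplitude must be non-negative")
    config = config or SolverConfig(nonlinearity_method="montecarlo")
    if amplitude == 0:
        return solve_self_consistent_spectrum(model, g, config=config)
    k_ratio = frequency / config.freq_step
    if not (frequency > 0) or abs(k_ratio - round(k_ratio)) > 1e-9:
        raise ValueError(
            f"drive frequency {frequency} must be a positive multiple of "
            f"the frequency bin {config.freq_step}")
    k_I = int(round(k_ratio))
    rng = np.random.default_rng(config.seed)
    freqs = config.frequencies
    chi, G = single_unit_gain(model, freqs)
    n2 = 2 * (freqs.size - 1)
    dt = 1.0 / (n2 * config.freq_step)
    t_grid = dt * np.arange(n2)

    n_harm = min(max_harmonics, (freqs.size - 2) // k_I)
    harm_bins = k_I * np.arange(1, n_harm + 1)
    G_h = G[harm_bins]

    # Warm start from the undriven chaotic state: the background must be
    # established before the oscillatory loop is closed, otherwise the
    # iteration starts in the basin of the fully entrained solution (the
    # chaotic fluctuations are what saturate the oscillatory feedback).
    n_time = n2
    warm_method = ("series_pl"
                   if model.nonlinearity.kind == "piecewise_linear"
                   else "quadrature")
    warm = solve_self_consistent_spectrum(
        model, g, config=replace(config, nonlinearity_method=warm_method))
    S_bkg = warm.spectrum_x.values.copy()
    if S_bkg.max() < _ZERO_FLOOR:  # below criticality: no chaotic background
        S_phi = np.full(freqs.size, 1.0 / (config.freq_step * n_time))
        S_bkg = G * g * g * S_phi
    g2 = g * g
    direct = amplitude**2 / 4.0
    c = np.zeros(n_harm)  # rate peak masses
    chi_abs = np.sqrt(G[harm_bins])

    def split(S_y):
        interp = 0.5 * (S_y[harm_bins - 1] + S_y[harm_bins + 1])
        masses = np.clip(
            (S_y[harm_bins] - interp) * config.freq_step, 0.0, None)
        S_phi_bkg = S_y.copy()
        S_phi_bkg[harm_bins] = interp
        return masses, S_phi_bkg

    fund_wave = np.exp(2j * np.pi * frequency * t_grid)
    history: List[float] = []
    converged = False
    it = 0
    # tail averages smooth the Monte-Carlo noise out of the final state
    tail_S, tail_c, tail_n = np.zeros_like(S_bkg), np.zeros(n_harm), 0
    tail_start = max(config.max_iterations - 25,
                     config.max_iterations // 2)
    for it in range(1, config.max_iterations + 1):
        sub_rng = np.random.default_rng(int(rng.integers(2**31)))
        paths = sample_gaussian_paths(
            Spectrum(config.freq_step, S_bkg), config.mc_samples, sub_rng)
        e_coef = (sub_rng.standard_normal((config.mc_samples, n_harm))
                  + 1j * sub_rng.standard_normal(
                      (config.mc_samples, n_harm))) / np.sqrt(2.0)
        theta = sub_rng.uniform(0, 2 * np.pi, size=config.mc_samples)

        # harmonic (k >= 2) waveform is fixed during the fundamental root
        # solve; precompute it once per outer iteration
        base = paths.copy()
        for j in range(1, n_harm):
            if c[j] > 0:
                d_j = chi_abs[j] * np.sqrt(g2 * c[j]) * e_coef[:, j]
                base += 2 * np.real(
                    d_j[:, None] * (fund_wave ** (j + 1))[None, :])

        def rate_psd(c1):
            d_1 = chi_abs[0] * (np.sqrt(g2 * c1) * e_coef[:, 0]
                                + (amplitude / 2.0) * np.exp(1j * theta))
            y = model.nonlinearity(
                base + 2 * np.real(d_1[:, None] * fund_wave[None, :]))
            return periodogram(y, config.freq_step)

        def excess(c1):
            return float(split(rate_psd(c1))[0][0]) - c1

        # smallest non-negative root of M(c1) - c1: bracket then bisect
        # (common random numbers make the map smooth in c1)
        c_cap = 4.0 * (direct * g2 + 2.0 * max(S_bkg.max(), 1.0))
        f0_val = excess(0.0)
        if f0_val <= 0:
            c1_root = 0.0
        else:
            lo, hi = 0.0, max(4 * c[0], 1e-3)
            f_hi = excess(hi)
            while f_hi > 0 and hi < c_cap:
                lo, hi = hi, 2.0 * hi
                f_hi = excess(hi)
            if f_hi > 0:
                raise ArithmeticError(
                    f"oscillatory self-consistency has no root below "
                    f"{hi:g} at iteration {it}")
            for _ in range(25):
                mid = 0.5 * (lo + hi)
                if excess(mid) > 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-3 * max(hi, 1e-6):
                    break
            c1_root = 0.5 * (lo + hi)

        masses, S_phi_bkg = split(rate_psd(c1_root))
        c_new = masses
        c_new[0] = c1_root
        S_new = G * g2 * S_phi_bkg

        res = _residual(S_new, S_bkg) + float(
            np.sum(np.abs(c_new - c)) / max(np.sum(c), 1e-12))
        history.append(res)
        alpha = max(0.15, config.damping / (1.0 + it / 30.0))
        S_bkg = (1 - alpha) * S_bkg + alpha * S_new
        c = (1 - alpha) * c + alpha * c_new
        if it >= tail_start:
            tail_S += S_bkg
            tail_c += c
            tail_n += 1
        window = history[-10:]
        if len(window) == 10 and np.mean(window) <= max(config.tolerance,
                                                        2e-2):
            converged = True
            break
    if not converged and tail_n > 0:
        S_bkg = tail_S / tail_n
        c = tail_c / tail_n
        # stochastic steps: accept if the tail residuals show no drift
        half = len(history[-2 * tail_n:]) // 2
        if half >= 5:
            a = np.mean(history[-2 * half:-half])
            bmean = np.mean(history[-half:])
            converged = bool(abs(a - bmean) <= 0.5 * a)
    b = G[harm_bins] * g2 * c
    b[0] += G[harm_bins][0] * direct
    peaks = {int(j + 1): float(b[j]) for j in range(n_harm)}
    return DMFTSolution(
        spectrum_x=Spectrum(config.freq_step, S_bkg),
        spectrum_rate=Spectrum(config.freq_step, np.clip(S_phi_bkg, 0, None)),
        oscillatory_peaks=peaks,
        drive_frequency=frequency,
        iterations=it,
        converged=converged,
        residual_history=history,
        config=config,
    )


def heterogeneous_gain(
    mean_beta: float, spread_beta: float, gamma: float, frequencies
) -> np.ndarray:
    """Effective gain for Gaussian-heterogeneous adaptation strength.

    ``G_H(f) = G(f) / (1 - gamma^2 sigma_beta^2 / (gamma^2 + w^2) G(f))``
    with ``G`` evaluated at the mean adaptation strength.  Heterogeneity
    raises power at low frequencies only; the filter becomes invalid
    (denominator <= 0) if the spread is too large.
    """
    from .rate_model import AdaptationParams, adaptation_gain

    f = np.asarray(frequencies, dtype=float)
    G = adaptation_gain(AdaptationParams(gamma, mean_beta), f)
    w2 = (2 * np.pi * f) ** 2
    denom = 1.0 - (gamma**2 * spread_beta**2 / (gamma**2 + w2)) * G
    if np.any(denom <= 0):
        raise ValueError(
            "heterogeneity too strong: effective filter denominator "
            "non-positive at some frequency")
    return G / denom


def linear_response_prediction(
    model: RateModel,
    g: float,
    noise_spectrum: Spectrum,
    amplitude: float,
    drive_frequency: float,
    freq_step: Optional[float] = None,
):
    """Sub-critical linear response to drive plus external noise.

    ``|chi_beta(f)|^2 = G / (1 - g^2 G)`` is the mean-field response;
    the output PSD is ``|chi_beta|^2 (S_I + S_eta)`` and the
    signal-to-noise ratio at the drive frequency is
    ``SNR = A_I^2 / (4 S_eta(f_I) df)`` — independent of the single-unit
    parameters, because signal and external noise are filtered equally.
    Returns ``(output_spectrum, snr)``.
    """
    from .stability import argmax_gain

    df = freq_step or noise_spectrum.freq_step
    freqs = noise_spectrum.frequencies
    _, G = single_unit_gain(model, freqs)
    G_max = float(single_unit_gain(model, argmax_gain(model))[1])
    if g * g * G_max >= 1.0:
        raise ValueError(
            "linear response inapplicable: g >= g_c (pole in the response)")
    chi_b2 = G / (1.0 - g * g * G)
    S_out = chi_b2 * noise_spectrum.values
    k = int(round(drive_frequency / df))
    if not np.isclose(k * df, drive_frequency):
        raise ValueError("drive frequency not on the noise grid")
    S_out = S_out.copy()
    signal_height = amplitude**2 / (4 * df)
    S_out[k] += chi_b2[k] * signal_height
    S_eta_fI = noise_spectrum.values[k]
    if S_eta_fI <= 0:
        raise ValueError("noise spectrum vanishes at the drive frequency")
    snr = amplitude**2 / (4 * S_eta_fI * df)
    return Spectrum(df, S_out), float(snr)


def sharpening_iterates(
    model: RateModel,
    g: float,
    n_iterations: int = 3,
    config: Optional[SolverConfig] = None,
):
    """First solver iterates next to the ``G^n`` sharpening prediction.

    Starting from a constant rate spectrum, iterate ``n`` times and return
    ``(iterates, predictions)``: both lists hold unit-max-normalized
    spectra, the predictions being ``(G(f)/max G)^n``.  Iterate 1 is
    proportional to ``G`` itself; the spectral peak narrows with ``n``,
    which is how recurrent coupling sharpens the single-unit frequency
    preference.
    """
    config = config or SolverConfig()
    rng = np.random.default_rng(config.seed)
    freqs = config.frequencies
    _, G = single_unit_gain(model, freqs)
    n2 = 2 * (freqs.size - 1)
    S_phi = np.full(freqs.size, 1.0 / (config.freq_step * n2))
    G_hat = G / G.max()
    iterates, predictions = [], []
    for n in range(1, n_iterations + 1):
        S_x = G * (g * g * S_phi)
        iterates.append(Spectrum(config.freq_step, S_x / S_x.max()))
        predictions.append(Spectrum(config.freq_step, G_hat**n))
        S_phi = _nonlinear_step(
            Spectrum(config.freq_step, S_x), model, config, rng).values
    return iterates, predictions
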