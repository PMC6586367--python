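"""Second-order statistics of a Gaussian process through a static nonlinearity.

Given a zero-mean stationary Gaussian process ``x`` with autocorrelation
``C_x``, these maps compute the autocorrelation ``C_phi(x)`` of the
transformed process ``phi(x)``, by four interchangeable methods:

* an infinite Hermite-type series for the clipped-linear nonlinearity,
* a closed-form finite sum for polynomial nonlinearities,
* 2-d Gauss-Hermite quadrature of the bivariate-Gaussian integral
  (any nonlinearity),
* Monte-Carlo sampling in the frequency domain (any nonlinearity,
  optionally with an added coherent oscillation).

All deterministic methods agree to quadrature accuracy on shared domains;
the Monte-Carlo route agrees within sampling error.  For odd ``phi`` the
maps generate odd harmonics only.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.special import ndtr, factorial, roots_hermitenorm

from .rate_model import NonlinearitySpec
from .spectra import Autocorr, Spectrum, autocorr_to_spectrum, spectrum_to_autocorr

__all__ = [
    "map_autocorr_piecewise_linear",
    "map_autocorr_polynomial",
    "map_autocorr_quadrature",
    "map_spectrum_montecarlo",
    "gaussian_expectation",
]

_SERIES_TOL = 1e-12
_SERIES_CAP = 200


def _check_autocorr(autocorr: Autocorr) -> float:
    var = autocorr.values[0]
    if not np.all(np.isfinite(autocorr.values)):
        raise ValueError("autocorrelation contains non-finite values")
    if var < 0:
        raise ValueError("autocorrelation has negative variance")
    return float(var)


def gaussian_expectation(func, variance: float, tol: float = 1e-11) -> float:
    """``E[func(x)]`` for ``x ~ N(0, variance)`` by adaptive quadrature."""
    import warnings

    from scipy.integrate import IntegrationWarning, quad

    if variance <= 0:
        return float(func(0.0))
    sigma = np.sqrt(variance)
    norm = 1.0 / np.sqrt(2 * np.pi)
    with warnings.catch_warnings():
        # near machine precision quad reports spurious roundoff trouble
        warnings.simplefilter("ignore", IntegrationWarning)
        val, _ = quad(
            lambda z: float(func(sigma * z)) * norm * np.exp(-0.5 * z * z),
            -8.5, 8.5, epsabs=tol, epsrel=tol, limit=500,
        )
    return float(val)


def _series_coefficients(sigma: float, n_max: int) -> np.ndarray:
    """Coefficients ``sigma^2 [F^(n-1)(1/s) - F^(n-1)(-1/s)]^2 / n!``.

    ``F`` is the standard normal CDF; ``F^(n)(x) = (-1)^(n-1) He_{n-1}(x)
    pdf(x)`` for ``n >= 1`` with probabilists' Hermite polynomials.  By
    parity the jump across ``+-1/sigma`` vanishes for every even ``n``
    (an odd nonlinearity keeps odd series terms only).  Computed with the
    normalized recurrence ``He_k / sqrt(k!)`` to avoid overflow.
    """
    a = 1.0 / sigma
    var = sigma * sigma
    out = np.zeros(n_max)
    out[0] = var * (ndtr(a) - ndtr(-a)) ** 2  # / 1!
    if n_max == 1:
        return out
    pdf_a = np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi)
    # ghat_k = He_k(a) pdf(a) / sqrt(k!): same linear recurrence as He_k,
    # pre-damped by the Gaussian so it stays bounded for any sigma
    ghat = np.empty(n_max)  # ghat_k for k = 0 .. n_max-1
    ghat[0] = pdf_a
    if n_max >= 2:
        ghat[1] = a * pdf_a
    for k in range(1, n_max - 1):
        ghat[k + 1] = (a * ghat[k] - np.sqrt(k) * ghat[k - 1]) / np.sqrt(k + 1)
    for n in range(3, n_max + 1, 2):
        # jump of F^(n-1) is 2 (-1)^(n-2) He_{n-2}(a) pdf(a); squared and
        # divided by n! = (n-2)! (n-1) n using the normalized values
        out[n - 1] = var * (2.0 * ghat[n - 2]) ** 2 / ((n - 1.0) * n)
    return out


def map_autocorr_piecewise_linear(autocorr: Autocorr) -> Autocorr:
    """Clipped-linear map via the Hermite series.

    ``C_phi(tau) = sigma^2 sum_{n>=1}
    [F^(n-1)(1/sigma) - F^(n-1)(-1/sigma)]^2 rho^n(tau) / n!``
    with ``sigma^2 = C_x(0)`` and ``rho = C_x / C_x(0)``.  The series is
    truncated once the coefficient bound drops below 1e-12 of the
    accumulated variance (hard cap 200 terms); the zero-lag value is
    replaced by the direct Gaussian expectation ``E[phi_PL(x)^2]``.
    """
    var = _check_autocorr(autocorr)
    if var == 0.0:
        return Autocorr(lag_step=autocorr.lag_step,
                        values=np.zeros_like(autocorr.values))
    sigma = np.sqrt(var)
    rho = np.clip(autocorr.normalized, -1.0, 1.0)

    coeffs = _series_coefficients(sigma, _SERIES_CAP)
    total = coeffs.sum()
    # drop the (eventually decaying) tail once terms fall below tolerance
    keep = _SERIES_CAP
    running_max = np.maximum.accumulate(coeffs[::-1])[::-1]
    small = running_max < _SERIES_TOL * max(total, 1e-300)
    if small.any():
        keep = max(int(np.argmax(small)), 1)
    coeffs = coeffs[:keep]

    out = np.zeros_like(rho)
    rho_n = np.ones_like(rho)
    for c in coeffs:
        rho_n = rho_n * rho
        if c > 0:
            out += c * rho_n
    out[0] = gaussian_expectation(lambda x: np.clip(x, -1, 1) ** 2, var)
    return Autocorr(lag_step=autocorr.lag_step, values=out)


def _polynomial_derivative_expectations(coeffs: np.ndarray, variance: float
                                        ) -> np.ndarray:
    """``E[phi^(n)(x)]`` for ``x ~ N(0, variance)``, ``n = 0 .. degree``.

    Uses the central Gaussian moments ``E[x^k] = (k-1)!! sigma^k`` (even k).
    """
    p = np.polynomial.Polynomial(coeffs)
    out = []
    moments = np.zeros(len(coeffs))
    moments[0] = 1.0
    for k in range(2, len(coeffs), 2):
        moments[k] = moments[k - 2] * (k - 1) * variance
    for n in range(len(coeffs)):
        c = p.coef
        out.append(float(np.sum(c * moments[: len(c)])))
        p = p.deriv()
    return np.array(out)


def map_autocorr_polynomial(autocorr: Autocorr, polynomial) -> Autocorr:
    """Closed-form map for a polynomial nonlinearity.

    ``C_phi(tau) = sum_{n=1}^{p} (1/n!) E[phi^(n)(x)]^2 C_x^n(tau)``.
    For the cubic ``phi_3 = x - x^3/3`` this reduces to
    ``(1 + C_x(0)^2 - 2 C_x(0)) C_x + (2/3) C_x^3``.
    """
    coeffs = np.asarray(polynomial, dtype=float)
    if coeffs.size < 2 or np.all(coeffs[1:] == 0):
        raise ValueError("polynomial must have degree >= 1")
    if coeffs[0] != 0:
        raise ValueError("polynomial nonlinearity must satisfy phi(0) = 0")
    var = _check_autocorr(autocorr)
    expectations = _polynomial_derivative_expectations(coeffs, var)
    C = autocorr.values
    out = np.zeros_like(C)
    C_n = np.ones_like(C)
    for n in range(1, len(expectations)):
        C_n = C_n * C
        out += expectations[n] ** 2 / float(factorial(n)) * C_n
    return Autocorr(lag_step=autocorr.lag_step, values=out)


def _gauss_nodes_with_breaks(breaks, z_cut: float, panel_width: float,
                             order: int):
    """Composite Gauss-Legendre rule on ``[-z_cut, z_cut]``.

    Panel edges include the supplied interior break positions, so the rule
    is spectrally accurate for integrands that are smooth between breaks.
    Returns flat ``(nodes, weights)`` arrays.
    """
    edges = [-z_cut]
    for b in sorted(breaks):
        if -z_cut < b < z_cut:
            edges.append(float(b))
    edges.append(z_cut)
    t, w = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_panels = max(1, int(np.ceil((hi - lo) / panel_width)))
        sub = np.linspace(lo, hi, n_panels + 1)
        for a, b in zip(sub[:-1], sub[1:]):
            half = 0.5 * (b - a)
            nodes.append(a + half * (t + 1.0))
            weights.append(half * w)
    return np.concatenate(nodes), np.concatenate(weights)


def map_autocorr_quadrature(
    autocorr: Autocorr,
    nonlinearity: NonlinearitySpec,
    z_cut: float = 8.5,
    panel_width: float = 2.125,
    order: int = 16,
) -> Autocorr:
    """Bivariate-Gaussian integral map by 2-d composite quadrature.

    ``C_phi(tau) = E[phi(sqrt(C0 - C^2/C0) u + (C/sqrt(C0)) v)
    phi(sqrt(C0) v)]`` with independent standard normal ``u, v``.  Both
    integrals use composite Gauss-Legendre rules whose panels are split at
    the kinks of the nonlinearity (known breakpoints of the clipped-linear
    function; the inner integral is evaluated in the variable where those
    kink positions are fixed), so the rule keeps spectral accuracy even
    for non-smooth ``phi``.  At zero lag the inner integral collapses to
    ``E[phi(x)^2]``.
    """
    var = _check_autocorr(autocorr)
    if var == 0.0:
        return Autocorr(lag_step=autocorr.lag_step,
                        values=np.zeros_like(autocorr.values))
    if np.max(np.abs(autocorr.values)) > var * (1 + 1e-9):
        raise ValueError("|C_x(tau)| must not exceed C_x(0)")
    C = np.clip(autocorr.values, -var, var)
    sqrt_var = np.sqrt(var)
    amp = np.sqrt(np.clip(var - C**2 / var, 0.0, None))  # per-lag inner scale
    degenerate = amp < 1e-12 * max(sqrt_var, 1e-300)
    norm = 1.0 / np.sqrt(2 * np.pi)
    breaks = np.asarray(nonlinearity.breakpoints, dtype=float)

    # outer rule in z: kinks of phi(sqrt(var) z) sit at fixed z = s/sqrt(var)
    z_nodes, z_w = _gauss_nodes_with_breaks(
        breaks / sqrt_var if breaks.size else (), z_cut, panel_width, order)
    z_weights = z_w * norm * np.exp(-0.5 * z_nodes**2)
    phi_z = np.asarray(nonlinearity(sqrt_var * z_nodes))

    # inner rule in t (u-variable): integrand phi(a t + b) n(t); kinks at
    # t = (s - b)/a, which differ per (lag, z) -- build per-pair panels by
    # shifting a base rule split at the mapped breakpoints.
    t_base, w_base = np.polynomial.legendre.leggauss(order)
    n_sub = max(1, int(np.ceil(2 * z_cut / panel_width)))

    out = np.empty_like(C)
    live = np.where(~degenerate)[0]
    Z = z_nodes.size
    chunk = max(1, int(2e6 // max(Z, 1)))
    for start in range(0, live.size, chunk):
        idx = live[start:start + chunk]
        a = amp[idx][:, None]                     # (J, 1)
        b = (C[idx] / sqrt_var)[:, None] * z_nodes[None, :]  # (J, Z)
        # panel edges in t for each (lag, z): [-z_cut, mapped breaks, z_cut]
        edges = np.empty((idx.size, Z, breaks.size + 2))
        edges[..., 0] = -z_cut
        edges[..., -1] = z_cut
        if breaks.size:
            mapped = (breaks[None, None, :] - b[..., None]) / a[..., None]
            edges[..., 1:-1] = np.clip(np.sort(mapped, axis=-1), -z_cut, z_cut)
        inner_val = np.zeros((idx.size, Z))
        for s in range(breaks.size + 1):
            lo, hi = edges[..., s], edges[..., s + 1]
            width = hi - lo
            # subdivide each segment proportionally to its width
            for p in range(n_sub):
                a_p = lo + width * p / n_sub
                h_p = width / (2 * n_sub)
                t = a_p[..., None] + h_p[..., None] * (t_base + 1.0)
                w = h_p[..., None] * w_base
                gauss_w = norm * np.exp(-0.5 * t**2)
                inner_val += np.sum(
                    w * gauss_w * np.asarray(
                        nonlinearity(a[..., None] * t + b[..., None])),
                    axis=-1,
                )
        out[idx] = inner_val @ (z_weights * phi_z)

    if degenerate.any():
        # rho = +-1: phi(x1) phi(x2) with x1 = sign * x2; a 1-d expectation
        for j in np.where(degenerate)[0]:
            sign = 1.0 if C[j] >= 0 else -1.0
            out[j] = gaussian_expectation(
                lambda x: np.asarray(nonlinearity(sign * x))
                * np.asarray(nonlinearity(x)),
                var,
            )
    return Autocorr(lag_step=autocorr.lag_step, values=out)


def sample_gaussian_paths(
    spectrum: Spectrum, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Time-domain sample paths of a Gaussian process with the given PSD.

    Independent complex Gaussian Fourier coefficients with variance
    ``S(f) df`` per (two-sided) bin and Hermitian symmetry; returns an
    array of shape ``(n_samples, n_time)`` with
    ``n_time = spectrum.n_two_sided``.
    """
    n = spectrum.n_two_sided
    m = spectrum.values.size - 1
    target = spectrum.values * spectrum.freq_step  # E|X_k|^2 / n_time^2 scale
    # rfft coefficient variances: bin 0 and Nyquist are real-valued
    re = rng.standard_normal((n_samples, m + 1))
    im = rng.standard_normal((n_samples, m + 1))
    coef = np.empty((n_samples, m + 1), dtype=complex)
    coef[:, 1:m] = (re[:, 1:m] + 1j * im[:, 1:m]) / np.sqrt(2.0)
    coef[:, 0] = re[:, 0]
    coef[:, m] = re[:, m]
    coef *= np.sqrt(target)[None, :]
    return np.fft.irfft(coef, n=n) * n


def periodogram(paths: np.ndarray, freq_step: float) -> np.ndarray:
    """One-sided averaged periodogram matching the package normalization.

    Normalized so that ``df * (two-sided sum)`` equals the mean sample
    variance of the paths.
    """
    n = paths.shape[-1]
    coef = np.fft.rfft(paths, axis=-1) / n
    power = np.mean(np.abs(coef) ** 2, axis=0)
    return power / freq_step


def map_spectrum_montecarlo(
    spectrum: Spectrum,
    nonlinearity: NonlinearitySpec,
    oscillatory: Optional[Tuple[float, float]] = None,
    n_samples: int = 500,
    seed: int = 0,
) -> Spectrum:
    """Monte-Carlo map ``S_x -> S_phi(x)``.

    Draws Gaussian sample paths with PSD ``S_x``, optionally adds
    ``A cos(2 pi f t + theta)`` with a fresh uniform phase per sample,
    applies ``phi`` pointwise and averages the periodogram.
    Reproducible given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = spectrum.n_two_sided
    dt = 1.0 / (n * spectrum.freq_step)
    paths = sample_gaussian_paths(spectrum, n_samples, rng)
    if oscillatory is not None:
        amp, f_osc = oscillatory
        k = f_osc / spectrum.freq_step
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"oscillatory frequency {f_osc} is not on the grid "
                f"(df={spectrum.freq_step})"
            )
        t = dt * np.arange(n)
        theta = rng.uniform(0, 2 * np.pi, size=n_samples)
        paths = paths + amp * np.cos(2 * np.pi * f_osc * t[None, :]
                                     + theta[:, None])
    out = periodogram(nonlinearity(paths), spectrum.freq_step)
    return Spectrum(freq_step=spectrum.freq_step, values=out)
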