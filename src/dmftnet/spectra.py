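"""Containers for power spectra and autocorrelations.

Both objects live on uniform grids and form a Fourier pair through the
discrete Wiener-Khinchin relation.  Storage convention: a spectrum keeps
its values for ``f >= 0`` only (even symmetry implicit), on the grid
``f_k = k * freq_step`` for ``k = 0 .. n_freq/2`` where ``n_freq`` is the
(power-of-two) size of the underlying two-sided grid; an autocorrelation
keeps non-negative lags only, ``tau_j = j * lag_step`` with
``lag_step = 1 / (n_freq * freq_step)``.

With these conventions the variance is the two-sided sum
``freq_step * sum_k S(f_k)`` (interior bins counted twice), equal to the
zero-lag autocorrelation value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Spectrum", "Autocorr", "spectrum_to_autocorr", "autocorr_to_spectrum"]


def _two_sided_sum(values: np.ndarray) -> float:
    # values on k = 0..M (M = Nyquist bin of an even-length two-sided grid)
    return float(values[0] + 2.0 * values[1:-1].sum() + values[-1])


@dataclass(frozen=True)
class Spectrum:
    """Power spectral density sampled on ``f_k = k * freq_step``, ``f >= 0``."""

    freq_step: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.freq_step <= 0:
            raise ValueError("freq_step must be positive")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("spectrum values must be a 1-d array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        floor = -1e-12 * max(v.max(initial=0.0), 1.0)
        if v.min() < floor:
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "values", np.clip(v, 0.0, None))

    @property
    def frequencies(self) -> np.ndarray:
        return self.freq_step * np.arange(self.values.size)

    @property
    def n_two_sided(self) -> int:
        return 2 * (self.values.size - 1)

    @property
    def max_freq(self) -> float:
        return self.freq_step * (self.values.size - 1)

    @property
    def variance(self) -> float:
        """Two-sided integral ``df * sum S``."""
        return self.freq_step * _two_sided_sum(self.values)

    def value_at(self, f: float) -> float:
        k = int(round(f / self.freq_step))
        if abs(k * self.freq_step - f) > 1e-9 * max(1.0, abs(f)):
            raise ValueError(f"frequency {f} is not on the grid (df={self.freq_step})")
        if not (0 <= k < self.values.size):
            raise ValueError(f"frequency {f} outside the grid")
        return float(self.values[k])

    def write(self, path) -> None:
        header = (
            f"frequency\tvalue  # one-sided PSD, even symmetry implicit, "
            f"df={self.freq_step:g}"
        )
        np.savetxt(path, np.column_stack([self.frequencies, self.values]),
                   header=header, delimiter="\t")

    @staticmethod
    def read(path) -> "Spectrum":
        data = np.loadtxt(path)
        f, v = data[:, 0], data[:, 1]
        return Spectrum(freq_step=float(f[1] - f[0]), values=v)


@dataclass(frozen=True)
class Autocorr:
    """Autocorrelation sampled on ``tau_j = j * lag_step``, ``tau >= 0``."""

    lag_step: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("autocorr values must be a 1-d array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("autocorr values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def lags(self) -> np.ndarray:
        return self.lag_step * np.arange(self.values.size)

    @property
    def variance(self) -> float:
        return float(self.values[0])

    @property
    def normalized(self) -> np.ndarray:
        """``rho(tau) = C(tau) / C(0)``; all-zero if the variance vanishes."""
        if self.values[0] <= 0:
            return np.zeros_like(self.values)
        return self.values / self.values[0]

    def write(self, path) -> None:
        header = (
            f"lag\tvalue  # one-sided autocorrelation, even symmetry implicit, "
            f"dtau={self.lag_step:g}"
        )
        np.savetxt(path, np.column_stack([self.lags, self.values]),
                   header=header, delimiter="\t")

    @staticmethod
    def read(path) -> "Autocorr":
        data = np.loadtxt(path)
        t, v = data[:, 0], data[:, 1]
        return Autocorr(lag_step=float(t[1] - t[0]), values=v)


def spectrum_to_autocorr(spectrum: Spectrum) -> Autocorr:
    """Inverse discrete Fourier transform of the (two-sided) spectrum.

    ``C(tau_j) = df * sum_k S(f_k) exp(2 pi i f_k tau_j)``; implemented with
    an inverse real FFT on the one-sided values.
    """
    n = spectrum.n_two_sided
    c_full = np.fft.irfft(spectrum.values, n=n) * spectrum.freq_step * n
    lag_step = 1.0 / (n * spectrum.freq_step)
    return Autocorr(lag_step=lag_step, values=c_full[: n // 2 + 1])


def autocorr_to_spectrum(autocorr: Autocorr) -> Spectrum:
    """Forward transform; exact inverse of :func:`spectrum_to_autocorr`."""
    m = autocorr.values.size - 1
    n = 2 * m
    c_full = np.concatenate([autocorr.values, autocorr.values[-2:0:-1]])
    s = np.fft.rfft(c_full).real * autocorr.lag_step
    freq_step = 1.0 / (n * autocorr.lag_step)
    # clip tiny negative FFT round-off
    s = np.where(s < 0, np.where(s > -1e-12 * max(abs(s).max(), 1.0), 0.0, s), s)
    return Spectrum(freq_step=freq_step, values=s)
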