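"""Scalar characterizations of spectra and autocorrelations.

Q-factor (peak frequency over half-maximum width) measures the coherence
of stochastic oscillations; the correlation time is the normalized first
moment of ``|C_x|`` and captures both the oscillatory decay and slow
tails; the signal/background split quantifies how much of the spectral
peak at a drive frequency is entrained oscillation versus chaotic
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .dmft import DMFTSolution
from .spectra import Autocorr, Spectrum

__all__ = [
    "OscillationReport",
    "SignalNoiseReport",
    "q_factor",
    "correlation_time",
    "split_signal_background",
    "variance_decomposition",
]


@dataclass(frozen=True)
class OscillationReport:
    peak_frequency: float
    half_max_width: Optional[float] = None
    q_factor: Optional[float] = None
    correlation_time: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "peak_frequency": self.peak_frequency,
            "half_max_width": self.half_max_width,
            "q_factor": self.q_factor,
            "correlation_time": self.correlation_time,
        }


@dataclass(frozen=True)
class SignalNoiseReport:
    background_at_drive: float
    oscillatory_at_drive: float
    snr: float
    snr_infinite: bool = False
    background_power: Optional[float] = None
    oscillatory_power: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "background_at_drive": self.background_at_drive,
            "oscillatory_at_drive": self.oscillatory_at_drive,
            "snr": self.snr,
            "snr_infinite": self.snr_infinite,
            "background_power": self.background_power,
            "oscillatory_power": self.oscillatory_power,
        }


def q_factor(spectrum: Spectrum) -> OscillationReport:
    """Quality factor ``Q = f_p / width_at_half_maximum``.

    The peak position is refined by parabolic interpolation around the
    grid argmax (ties broken toward lower frequency); the half-maximum
    crossings are found by linear interpolation on the main lobe (the
    contiguous region around the peak above half maximum), so harmonic
    side lobes do not widen the measure.  A spectrum whose maximum sits
    at ``f = 0`` is non-resonant and carries no Q-factor.
    """
    v = spectrum.values
    df = spectrum.freq_step
    i = int(np.argmax(v))
    if i == 0:
        return OscillationReport(peak_frequency=0.0)
    if i == v.size - 1:
        raise ValueError("spectral peak at the grid edge; grid too narrow")
    # parabolic refinement
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    f_p = df * (i + float(np.clip(delta, -0.5, 0.5)))
    half = v[i] / 2.0
    # main lobe: walk out from the peak to the first crossings
    j = i
    while j > 0 and v[j - 1] >= half:
        j -= 1
    if j == 0 and v[0] >= half:
        raise ValueError("no lower half-maximum crossing inside the grid")
    f_lo = df * (j - 1 + (half - v[j - 1]) / (v[j] - v[j - 1]))
    k = i
    while k < v.size - 1 and v[k + 1] >= half:
        k += 1
    if k == v.size - 1 and v[-1] >= half:
        raise ValueError("no upper half-maximum crossing inside the grid")
    f_hi = df * (k + (v[k] - half) / (v[k] - v[k + 1]))
    width = f_hi - f_lo
    return OscillationReport(
        peak_frequency=float(f_p),
        half_max_width=float(width),
        q_factor=float(f_p / width),
    )


def correlation_time(autocorr: Autocorr, floor: float = 1e-4) -> float:
    """Normalized first moment of ``|C_x|``.

    ``t_c = int tau |C(tau)| dtau / int |C(tau)| dtau`` by trapezoidal
    integration, truncated at the last lag where ``|C|`` exceeds
    ``floor * C(0)``.  Raises if the autocorrelation has not decayed
    below the floor within the available lags (horizon too short).
    """
    C = np.abs(autocorr.values)
    if C[0] <= 0:
        raise ValueError("autocorrelation has zero variance")
    above = np.where(C > floor * C[0])[0]
    horizon = int(above[-1])
    if horizon == C.size - 1:
        raise ValueError(
            "autocorrelation has not decayed below the floor within the "
            "available lags; horizon too short")
    lags = autocorr.lags[: horizon + 1]
    Ch = C[: horizon + 1]
    num = np.trapezoid(lags * Ch, lags)
    den = np.trapezoid(Ch, lags)
    return float(num / den)


def split_signal_background(
    solution: Union[DMFTSolution, Spectrum],
    drive_frequency: Optional[float] = None,
    freq_step: Optional[float] = None,
) -> SignalNoiseReport:
    """Split the spectral value at the drive bin into signal and background.

    ``A_bkg`` interpolates the background from the neighbouring bins,
    ``A_osc = S(f_I) - A_bkg`` (equivalently ``b_1 / df`` for a solver
    solution carrying explicit peak masses); ``SNR = A_osc / A_bkg``.
    """
    if isinstance(solution, DMFTSolution):
        spec = solution.spectrum_x
        if drive_frequency is None:
            drive_frequency = solution.drive_frequency
        b1 = solution.oscillatory_peaks.get(1, 0.0)
        has_peaks = bool(solution.oscillatory_peaks)
    else:
        spec = solution
        b1 = None
        has_peaks = False
    if drive_frequency is None:
        raise ValueError("drive frequency required")
    df = freq_step or spec.freq_step
    k = int(round(drive_frequency / df))
    if not np.isclose(k * df, drive_frequency, rtol=1e-9, atol=1e-12):
        raise ValueError("drive frequency not on the grid")
    if k < 1 or k + 1 >= spec.values.size:
        raise ValueError("drive frequency too close to the grid edge")
    a_bkg = 0.5 * (spec.values[k - 1] + spec.values[k + 1])
    if has_peaks:
        a_osc = b1 / df
    else:
        a_osc = spec.values[k] - a_bkg
    if a_bkg <= 0:
        return SignalNoiseReport(
            background_at_drive=0.0, oscillatory_at_drive=float(a_osc),
            snr=np.inf, snr_infinite=True)
    return SignalNoiseReport(
        background_at_drive=float(a_bkg),
        oscillatory_at_drive=float(a_osc),
        snr=float(a_osc / a_bkg),
    )


def variance_decomposition(solution: DMFTSolution) -> SignalNoiseReport:
    """Split the total variance into background and oscillatory power.

    ``P_bkg = df * (two-sided sum of the background)``;
    ``P_osc = 2 sum_k b_k``; their sum is the total variance.
    """
    p_bkg = solution.spectrum_x.variance
    p_osc = 2.0 * sum(solution.oscillatory_peaks.values())
    base = split_signal_background(solution) if solution.drive_frequency \
        else None
    return SignalNoiseReport(
        background_at_drive=base.background_at_drive if base else 0.0,
        oscillatory_at_drive=base.oscillatory_at_drive if base else 0.0,
        snr=base.snr if base else 0.0,
        snr_infinite=base.snr_infinite if base else False,
        background_power=float(p_bkg),
        oscillatory_power=float(p_osc),
    )
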