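"""Single-unit rate models.

A unit is a ``D``-dimensional linear system ``x' = A x`` whose first
variable receives the recurrent and external input and whose output rate
is ``phi(x^1)``.  The special case ``D = 2`` with

    x' = -x - a + input
    a' = -gamma a + gamma beta x

describes a rate neuron with spike-frequency adaptation: the auxiliary
variable ``a`` is driven by the activation ``x`` and feeds back
negatively, with timescale ratio ``gamma`` and strength ``beta``.  Time
is dimensionless (measured in units of the timescale of ``x``) and
frequencies are ordinary frequencies ``f`` (cycles per unit time);
``omega = 2 pi f`` appears only internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "AdaptationParams",
    "NonlinearitySpec",
    "RateModel",
    "piecewise_linear",
    "cubic",
    "make_adaptation_model",
    "make_general_model",
    "single_unit_gain",
    "evaluate_nonlinearity",
    "adaptation_gain",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Adaptation parameters: timescale ratio ``gamma`` and strength ``beta``."""

    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


def _phi_pl(x):
    return np.clip(x, -1.0, 1.0)


def _phi_cubic(x):
    x = np.asarray(x, dtype=float)
    return x - x**3 / 3.0


@dataclass(frozen=True)
class NonlinearitySpec:
    """Static nonlinearity ``phi`` with ``phi(0) = 0`` and ``phi'(0) = 1``.

    The unit-slope condition at the origin is assumed by the stability
    analysis; it is checked numerically for custom callables.
    """

    kind: str
    func: Callable[[np.ndarray], np.ndarray]
    # Polynomial coefficients in increasing order, where the nonlinearity
    # is a polynomial (used by the closed-form autocorrelation map).
    poly_coeffs: Optional[tuple] = None
    # Locations where phi is not smooth (kinks); quadrature rules split
    # their panels there.  Empty for smooth nonlinearities.
    breakpoints: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("piecewise_linear", "cubic", "tanh", "custom"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        f0 = float(np.asarray(self.func(0.0)))
        if abs(f0) > 1e-12:
            raise ValueError("nonlinearity must satisfy phi(0) = 0")
        h = 1e-6
        slope = float(np.asarray(self.func(h) - self.func(-h))) / (2 * h)
        if abs(slope - 1.0) > 1e-5:
            raise ValueError(
                f"nonlinearity must satisfy phi'(0) = 1 (measured {slope:.6g})"
            )

    def __call__(self, x):
        return self.func(np.asarray(x, dtype=float))


def piecewise_linear() -> NonlinearitySpec:
    """Odd saturating nonlinearity: identity on (-1, 1), clipped to +-1."""
    return NonlinearitySpec(kind="piecewise_linear", func=_phi_pl,
                            breakpoints=(-1.0, 1.0))


def cubic() -> NonlinearitySpec:
    """Cubic approximation of tanh, ``phi(x) = x - x^3/3`` (unbounded)."""
    return NonlinearitySpec(
        kind="cubic", func=_phi_cubic, poly_coeffs=(0.0, 1.0, 0.0, -1.0 / 3.0)
    )


def tanh_nonlinearity() -> NonlinearitySpec:
    return NonlinearitySpec(kind="tanh", func=np.tanh)


@dataclass(frozen=True)
class RateModel:
    """A ``D``-dimensional linear-nonlinear rate unit.

    ``interaction`` is the matrix ``A`` governing the linear dynamics of
    one unit; it must be non-singular with all eigenvalues in the open
    left half-plane so that the uncoupled unit is stable.  Variable 1 is
    the activation/output variable.
    """

    interaction: np.ndarray
    nonlinearity: NonlinearitySpec
    adaptation: Optional[AdaptationParams] = None

    def __post_init__(self) -> None:
        A = np.asarray(self.interaction, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 1:
            raise ValueError("interaction must be a square matrix")
        eig = np.linalg.eigvals(A)
        if np.any(np.abs(eig) < 1e-12):
            raise ValueError("interaction matrix must be non-singular")
        if np.any(eig.real >= 0):
            raise ValueError(
                "interaction matrix must have eigenvalues with negative real part"
            )
        object.__setattr__(self, "interaction", A)

    @property
    def dim(self) -> int:
        return self.interaction.shape[0]

    def susceptibility(self, frequencies) -> np.ndarray:
        """Linear response of the activation variable, ``chi0(f)``.

        ``chi0(f) = [(2 pi i f I - A)^-1]_{11}``.
        """
        return single_unit_gain(self, frequencies)[0]

    def gain(self, frequencies) -> np.ndarray:
        """Squared modulus of the susceptibility, ``G(f) = |chi0(f)|^2``."""
        return single_unit_gain(self, frequencies)[1]

    def to_dict(self) -> dict:
        d = {
            "dim": self.dim,
            "interaction": self.interaction.tolist(),
            "nonlinearity": self.nonlinearity.kind,
        }
        if self.adaptation is not None:
            d["gamma"] = self.adaptation.gamma
            d["beta"] = self.adaptation.beta
        return d

    @staticmethod
    def from_dict(d: dict) -> "RateModel":
        phi = _nonlinearity_from_name(d.get("nonlinearity", "piecewise_linear"))
        if "gamma" in d:
            return make_adaptation_model(
                AdaptationParams(float(d["gamma"]), float(d["beta"])), phi
            )
        return make_general_model(np.asarray(d["interaction"], dtype=float), phi)


def _nonlinearity_from_name(name: str) -> NonlinearitySpec:
    if name == "piecewise_linear":
        return piecewise_linear()
    if name == "cubic":
        return cubic()
    if name == "tanh":
        return tanh_nonlinearity()
    raise ValueError(f"unknown nonlinearity name {name!r}")


def make_adaptation_model(
    params: AdaptationParams, nonlinearity: Optional[NonlinearitySpec] = None
) -> RateModel:
    """Two-variable unit with spike-frequency adaptation.

    The interaction matrix is ``[[-1, -1], [gamma*beta, -gamma]]`` so that
    ``x' = -x - a + input`` and ``a' = -gamma a + gamma beta x``.  It always
    has eigenvalues with negative real part (trace ``-(1+gamma) < 0``,
    determinant ``gamma (1+beta) > 0``).
    """
    if nonlinearity is None:
        nonlinearity = piecewise_linear()
    g, b = params.gamma, params.beta
    A = np.array([[-1.0, -1.0], [g * b, -g]])
    return RateModel(interaction=A, nonlinearity=nonlinearity, adaptation=params)


def make_general_model(
    interaction, nonlinearity: Optional[NonlinearitySpec] = None
) -> RateModel:
    """General ``D``-dimensional unit; variable 1 is the output variable."""
    if nonlinearity is None:
        nonlinearity = piecewise_linear()
    return RateModel(interaction=np.asarray(interaction, dtype=float),
                     nonlinearity=nonlinearity)


def single_unit_gain(model: RateModel, frequencies):
    """Susceptibility ``chi0(f)`` and gain ``G(f)`` of an uncoupled unit.

    Returns ``(chi0, G)`` where ``chi0(f)`` is element (1, 1) of
    ``(2 pi i f I - A)^-1`` and ``G = |chi0|^2``.  ``2 pi i f I - A`` is
    always invertible because ``A`` has no purely imaginary eigenvalues.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    A = model.interaction
    D = model.dim
    I = np.eye(D)
    M = 2j * np.pi * f[:, None, None] * I[None, :, :] - A[None, :, :]
    e1 = np.zeros(D)
    e1[0] = 1.0
    rhs = np.broadcast_to(e1[:, None], (f.size, D, 1)).copy()
    col = np.linalg.solve(M, rhs)
    chi = col[:, 0, 0]
    gain = np.abs(chi) ** 2
    if np.isscalar(frequencies) or np.ndim(frequencies) == 0:
        return chi[0], gain[0]
    return chi, gain


def adaptation_gain(params: AdaptationParams, frequencies):
    """Closed-form gain of the adaptation unit.

    ``G(f) = (gamma^2 + w^2) / (w^4 + (1 + gamma^2 - 2 beta gamma) w^2
    + gamma^2 (1 + beta)^2)`` with ``w = 2 pi f``.
    """
    g, b = params.gamma, params.beta
    w2 = (2 * np.pi * np.asarray(frequencies, dtype=float)) ** 2
    return (g**2 + w2) / (w2**2 + (1 + g**2 - 2 * b * g) * w2 + g**2 * (1 + b) ** 2)


def evaluate_nonlinearity(spec: NonlinearitySpec, values):
    """Elementwise ``phi(values)``."""
    return spec(values)
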