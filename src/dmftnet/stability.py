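"""Fixed-point stability of the random network.

The network of ``N`` coupled ``D``-dimensional units has a fixed point at
the origin (``phi(0) = 0``).  Its Jacobian is an ``ND x ND`` block matrix
whose blocks all commute, so each eigenvalue ``lam_J`` of the Gaussian
connectivity matrix maps to ``D`` Jacobian eigenvalues through the
rational relation

    lam_J = prod_i (lam_B - lam_A_i) / prod_j (lam_B - lam_Aminus_j),

where ``A-`` is ``A`` with its first row and column removed.  In the
large-``N`` limit the ``lam_J`` fill the disk of radius ``g`` (circular
law), and stability is lost at the critical coupling ``g_c`` defined by
``g_c^2 max_f G(f) = 1``.

For the adaptation model the map inverts in closed form and the loss of
stability happens either through a saddle-node bifurcation (a real
eigenvalue crosses zero; ``g_c = 1 + beta``) or, for adaptation strength
above the Hopf boundary ``beta_H(gamma)``, through a Hopf bifurcation at

    g_c^2 = 1 - gamma (gamma + 2 beta)
            + 2 gamma sqrt(beta (beta + 2 gamma + 2)),

with critical eigenfrequency ``f_m`` equal to the resonance frequency
``f_0`` of the single-unit gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .rate_model import AdaptationParams, RateModel, single_unit_gain

__all__ = [
    "StabilityReport",
    "hopf_boundary_beta",
    "critical_coupling",
    "critical_coupling_closed_form",
    "classify_regime",
    "resonance_frequency",
    "argmax_gain",
    "jacobian_eigenvalues_from_connectivity",
    "finite_jacobian_spectrum",
]

#: refuse to assemble dense Jacobians beyond this size (ND)
DEFAULT_EIG_CAP = 6000


@dataclass(frozen=True)
class StabilityReport:
    critical_coupling: float
    regime: str  # "resonant" | "non_resonant"
    hopf_boundary_beta: float
    resonance_frequency: float  # f_0 (= f_m); 0 in the non-resonant regime
    argmax_gain: float  # frequency maximizing G(f)

    def to_dict(self) -> dict:
        return {
            "critical_coupling": self.critical_coupling,
            "regime": self.regime,
            "hopf_boundary_beta": self.hopf_boundary_beta,
            "resonance_frequency": self.resonance_frequency,
            "argmax_gain": self.argmax_gain,
        }


def hopf_boundary_beta(gamma: float) -> float:
    """Adaptation strength separating saddle-node from Hopf instability.

    ``beta_H(gamma) = -1 - gamma + sqrt(2 gamma^2 + 2 gamma + 1)``.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return -1.0 - gamma + np.sqrt(2.0 * gamma**2 + 2.0 * gamma + 1.0)


def critical_coupling_closed_form(params: AdaptationParams) -> float:
    """Closed-form ``g_c(gamma, beta)`` for the adaptation model."""
    g, b = params.gamma, params.beta
    if b > hopf_boundary_beta(g):
        return float(np.sqrt(1.0 - g * (g + 2 * b) + 2 * g * np.sqrt(b * (b + 2 * g + 2))))
    return 1.0 + b


def argmax_gain(model: RateModel, f_max: float = 50.0) -> float:
    """Frequency ``f >= 0`` maximizing the single-unit gain ``G(f)``.

    Dense grid scan followed by bracketed scalar refinement.
    """
    grid = np.linspace(0.0, f_max, 20001)
    _, G = single_unit_gain(model, grid)
    if not np.all(np.isfinite(G)):
        raise ArithmeticError("non-finite gain encountered during maximization")
    i = int(np.argmax(G))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda f: -single_unit_gain(model, float(f))[1],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    f_best = float(res.x)
    if single_unit_gain(model, f_best)[1] < G[i]:
        f_best = float(grid[i])
    # snap tiny offsets onto the f = 0 bin for monotone (non-resonant) gains
    return 0.0 if f_best < 1e-8 else f_best


def critical_coupling(model: RateModel) -> float:
    """Critical coupling ``g_c = 1 / sqrt(max_f G(f))``.

    For adaptation models the closed form is evaluated as well and the two
    routes are required to agree to 1e-6 relative.
    """
    f_star = argmax_gain(model)
    G_max = float(single_unit_gain(model, f_star)[1])
    gc = 1.0 / np.sqrt(G_max)
    if model.adaptation is not None:
        gc_cf = critical_coupling_closed_form(model.adaptation)
        if abs(gc - gc_cf) > 1e-6 * gc_cf:
            raise AssertionError(
                f"closed-form g_c = {gc_cf!r} disagrees with numeric g_c = {gc!r}"
            )
        gc = gc_cf
    return float(gc)


def resonance_frequency(params: AdaptationParams) -> float:
    """Resonance frequency ``f_0`` of the single-unit gain (Hopf regime).

    ``f_0 = (1 / 2 pi) sqrt(-gamma^2 + gamma sqrt(beta (beta + 2 gamma + 2)))``,
    which also equals the critical eigenfrequency ``f_m`` at the Hopf
    bifurcation.  Raises for non-resonant parameters, where the gain is
    monotonically decreasing and ``f_0`` is undefined.
    """
    g, b = params.gamma, params.beta
    radicand = -(g**2) + g * np.sqrt(b * (b + 2 * g + 2))
    if radicand < 0:
        raise ValueError(
            "resonance frequency undefined: beta <= beta_H(gamma) (non-resonant)"
        )
    return float(np.sqrt(radicand) / (2 * np.pi))


def classify_regime(params: AdaptationParams) -> StabilityReport:
    """Full stability report for an adaptation model."""
    from .rate_model import make_adaptation_model

    beta_h = hopf_boundary_beta(params.gamma)
    resonant = params.beta > beta_h
    model = make_adaptation_model(params)
    gc = critical_coupling(model)
    f0 = resonance_frequency(params) if resonant else 0.0
    return StabilityReport(
        critical_coupling=gc,
        regime="resonant" if resonant else "non_resonant",
        hopf_boundary_beta=float(beta_h),
        resonance_frequency=f0,
        argmax_gain=argmax_gain(model),
    )


def jacobian_eigenvalues_from_connectivity(
    model: RateModel, connectivity_eigenvalue: complex
) -> np.ndarray:
    """The ``D`` Jacobian eigenvalues associated with one eigenvalue of J.

    Solves ``charpoly_A(lam) - lam_J * charpoly_Aminus(lam) = 0`` (the
    polynomial obtained by clearing denominators in the forward eigenvalue
    map).  For the adaptation model this is the closed form

        lam_B = (1/2) (-1 - gamma + lam_J
                       +- sqrt((lam_J - 1 + gamma)^2 - 4 gamma beta)).
    """
    lam_J = complex(connectivity_eigenvalue)
    A = model.interaction
    if model.adaptation is not None:
        g, b = model.adaptation.gamma, model.adaptation.beta
        disc = np.sqrt(complex((lam_J - 1 + g) ** 2 - 4 * g * b))
        roots = np.array(
            [0.5 * (-1 - g + lam_J + disc), 0.5 * (-1 - g + lam_J - disc)]
        )
    else:
        pA = np.poly(A)  # decreasing powers, degree D
        if model.dim == 1:
            pAm = np.array([1.0])
        else:
            pAm = np.poly(A[1:, 1:])
        # charpoly_A(lam) - lam_J * charpoly_Aminus(lam), aligned degrees
        q = pA.astype(complex)
        q[1:] -= lam_J * pAm
        roots = np.roots(q)
        lam_Am = np.linalg.eigvals(A[1:, 1:]) if model.dim > 1 else np.array([])
        for r in roots:
            if lam_Am.size and np.min(np.abs(r - lam_Am)) < 1e-8:
                raise ArithmeticError(
                    "degenerate case: Jacobian eigenvalue coincides with an "
                    "eigenvalue of the reduced matrix A-"
                )
    return roots


def connectivity_eigenvalue_from_jacobian(
    model: RateModel, jacobian_eigenvalue: complex
) -> complex:
    """Forward eigenvalue map ``lam_B -> lam_J`` (phi'(0) = 1)."""
    lam = complex(jacobian_eigenvalue)
    A = model.interaction
    lam_A = np.linalg.eigvals(A)
    num = np.prod(lam - lam_A)
    if model.dim == 1:
        return complex(num)
    lam_Am = np.linalg.eigvals(A[1:, 1:])
    den = np.prod(lam - lam_Am)
    if abs(den) < 1e-12:
        raise ArithmeticError(
            "forward map undefined: lam_B coincides with an eigenvalue of A-"
        )
    return complex(num / den)


def finite_jacobian_spectrum(
    model: RateModel, connectivity: np.ndarray, cap: int = DEFAULT_EIG_CAP
) -> np.ndarray:
    """All ``N D`` eigenvalues of the finite-network Jacobian.

    Assembles ``B = kron(A, I_N) + kron(e1 e1^T, J)`` (phi'(0) = 1) and
    diagonalizes it directly.
    """
    J = np.asarray(connectivity, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("connectivity must be a square matrix")
    N = J.shape[0]
    D = model.dim
    if N * D > cap:
        raise MemoryError(
            f"dense Jacobian of size {N * D} exceeds the cap {cap}; "
            "use jacobian_eigenvalues_from_connectivity on eig(J) instead"
        )
    A = model.interaction
    Delta1 = np.zeros((D, D))
    Delta1[0, 0] = 1.0
    B = np.kron(A, np.eye(N)) + np.kron(Delta1, J)
    return np.linalg.eigvals(B)
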