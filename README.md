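# dmftnet

Dynamical mean-field theory (DMFT) and microscopic simulation of large
random networks of **multi-dimensional rate neurons**, with a focus on
spike-frequency adaptation.

## The problem

A classic result for random recurrent networks of one-variable rate
units is a transition to chaos at coupling strength g = 1. Real neurons,
however, carry slow intrinsic processes — adaptation, synaptic
filtering, refractoriness — that make their dynamics multi-dimensional.
This package implements a self-consistent theory for networks of units

    dx_i/dt = -x_i - a_i + Σ_j J_ij φ(x_j) + I_i(t)
    da_i/dt = -γ a_i + γ β x_i,          J_ij ~ N(0, g²/N),

(and the general D-variable analogue dx_iᵅ/dt = Σ_β A^{αβ} x_iᵝ + δ^{α1}(…)),
where `a_i` is an adaptation variable with timescale ratio γ and strength
β, and φ is a saturating nonlinearity (by default the odd clipped-linear
function, φ(x) = x on (−1, 1), ±1 outside).

Key quantities, all computable with this package:

- **Single-unit gain** G̃(f) = |χ̃₀(f)|², χ̃₀(f) = [(2πif·I − A)⁻¹]₁₁ —
  the squared frequency-response of one uncoupled unit.
- **Critical coupling** g_c, defined by g_c² · max_f G̃(f) = 1. For the
  adaptation model it has a closed form with two branches separated by
  the Hopf boundary β_H(γ) = −1 − γ + √(2γ² + 2γ + 1): a saddle-node
  branch g_c = 1 + β and a Hopf branch
  g_c² = 1 − γ(γ+2β) + 2γ√(β(β+2γ+2)). Adaptation always *stabilizes*:
  g_c > 1 for γ, β > 0.
- **Self-consistent power spectrum.** Above g_c the network is chaotic
  and the activation spectrum solves
  S_x(f) = G̃(f)·(g² S_φ(x)(f) + S_I(f)), where S_φ(x) is the rate
  spectrum — a functional of S_x obtained by pushing a Gaussian process
  through φ. The package solves this fixed point iteratively, with four
  interchangeable implementations of the nonlinear step (Hermite series,
  polynomial closed form, bivariate quadrature, Monte-Carlo).
- **Resonant chaos.** For β > β_H(γ) the gain peaks at
  f₀ = (1/2π)√(−γ² + γ√(β(β+2γ+2))) and the chaotic spectrum inherits
  that peak — recurrent coupling *sharpens* it (higher Q-factor) but
  does not move it.
- **Signal transmission.** With an oscillatory drive
  A_I cos(2πf_I t + θ_i), the spectrum develops delta peaks at the
  harmonics of f_I. The signal-to-noise ratio SNR = A_osc/A_bkg is flat
  in the sub-critical (externally noisy) regime but shaped like a notch
  filter around f₀ in the chaotic regime; strong drive near f₀
  suppresses the chaos entirely.
- A **microscopic simulator** (fixed-step RK4 on the full N·D system)
  serves as the empirical oracle for all of the above.

## Worked example

```python
import dmftnet as dn

params = dn.AdaptationParams(gamma=0.25, beta=1.0)
model = dn.make_adaptation_model(params)

report = dn.classify_regime(params)
print(report.regime)                # resonant
print(report.critical_coupling)    # 1.1717142769009368
print(report.resonance_frequency)  # 0.10131148802561572

sol = dn.solve_self_consistent_spectrum(model, 2 * report.critical_coupling)
print(sol.converged, sol.iterations)  # True 142
print(sol.variance)                   # 2.3430100488583854
print(sol.peak_frequency())           # 0.102
```

The network sits in the resonant regime: its fixed point destabilizes
through a Hopf bifurcation at g_c ≈ 1.17, and at twice that coupling the
chaotic activity has variance ≈ 2.34 with a narrow spectral peak at
f_p ≈ 0.102 — within one frequency bin of the single-unit resonance
f₀ ≈ 0.1013, even though the coupling is strongly nonlinear.

The same workflows are scriptable from the shell:

```bash
dmftnet stability --gamma 0.25 --beta 1 --out out/
dmftnet solve     --gamma 0.25 --beta 1 --out out/
dmftnet simulate  --gamma 0.25 --beta 1 --n-units 1000 --out out/
dmftnet signal-scan --drive-amplitude 0.5 --out out/
```

Each command writes plain-text tables plus a JSON report carrying the
full configuration echo; reruns with the same seed are byte-identical.

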