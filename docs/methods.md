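# Methods

## Model

One unit is a linear system plus output nonlinearity: D variables
x = (x¹, …, x^D) with dx/dt = A x, where only the first variable
receives input and only φ(x¹) is transmitted. A must be non-singular
with all eigenvalues in the open left half-plane (the uncoupled unit is
stable); the constructors reject anything else. The adaptation model is
the D = 2 case A = [[−1, −1], [γβ, −γ]]: an auxiliary variable driven by
the activation that feeds back negatively, with timescale ratio γ > 0
and strength β ≥ 0. Time is dimensionless (units of the activation
timescale); all spectra use ordinary frequency f, with ω = 2πf kept
internal.

The nonlinearity must satisfy φ(0) = 0 and φ′(0) = 1 — the stability
analysis assumes unit slope at the origin, so custom callables are
checked numerically (central difference, tolerance 1e−5) at
construction. Built-ins: the odd clipped-linear function (bounded,
kinks at ±1), the cubic x − x³/3 (unbounded; solver iterations can
diverge with it, and the solver reports the offending iterate), and
tanh.

## Stability

The network Jacobian at the origin decomposes over the eigenvalues λ_J
of the coupling matrix: each λ_J yields D Jacobian eigenvalues through
charpoly_A(λ) = λ_J · charpoly_{A⁻}(λ), with A⁻ the matrix A without
its first row and column. For the adaptation model the inversion is the
quadratic formula; for general D we find polynomial roots
(`numpy.roots`) and reject roots within 1e−8 of an eigenvalue of A⁻
(the excluded set of the forward map). In the large-N limit λ_J fills
the disk of radius g (circular law), giving the critical coupling
g_c = 1/√(max_f G̃). The maximum of G̃ is located by a dense grid
(20001 points, f ≤ 50) plus bounded scalar refinement (xatol 1e−10);
for adaptation models the closed form is evaluated too and the two
routes are required to agree to 1e−6 relative — a permanent internal
cross-check, not a test-only one. Peaks below f = 1e−8 are snapped to
zero so monotone (non-resonant) gains report f* = 0 exactly.

## Self-consistent spectrum

Grid: f ∈ [0, max_freq] with bin Δf (defaults 0.001 and 2.0); the
number of two-sided points is rounded up to a power of two for the FFT
bridge, so the stored one-sided grid reaches slightly beyond max_freq
(2.048 at the defaults). Spectra are stored one-sided (even symmetry
implicit) and satisfy Δf·(two-sided sum) = variance; autocorrelations
are stored for non-negative lags with lag step 1/(NΔf). The
spectrum↔autocorrelation bridge is `numpy.fft.rfft/irfft`; round trips
are identity to ~1e−15.

The fixed point of S_x = G̃·(g²S_φ + S_I) is found by damped forward
iteration starting from a constant rate spectrum. The starting level
(variance 1 by default) is configurable and the converged solution is
verified not to depend on it. Convergence: relative L1 change ≤ 1e−6;
the all-zero solution is detected when max S_x < 1e−10. Damping starts
at 1 and halves (floor 0.25) when the residual alternates. Typical
converged iteration counts at the default grid: ~100 below threshold,
140–200 at g = 1.5–2 g_c, ~1500 at g = 1.05 g_c (critical slowing
down).

## Nonlinearity maps (Gaussian second-order statistics)

Four interchangeable routes compute C_φ(x) from C_x; their pairwise
agreement is the package's central oracle suite.

1. **Hermite series (clipped-linear only).** C_φ(τ) = σ² Σ_{n≥1}
   J_n² ρⁿ(τ)/n! with ρ = C_x/C_x(0) and J_n the jump of the (n−1)-th
   derivative of the standard normal CDF across ±1/σ. Coefficients are
   computed with the Gaussian-damped normalized Hermite recurrence
   (He_k(a)·pdf(a)/√k!), which stays bounded for any σ; only odd terms
   survive (odd φ). Truncation: drop the tail once it falls below
   1e−12 of the accumulated sum, hard cap 200 terms; the zero-lag value
   is replaced by the direct quadrature of E[φ²]. The ρⁿ (normalized)
   form of the series is used; it is the reading consistent with the
   n = 1 coefficient Erf²(1/√(2C_x(0))) of the Price-theorem route, and
   it is validated against the quadrature and Monte-Carlo oracles.
2. **Polynomial closed form.** C_φ = Σ_{n=1}^{p} (E[φ⁽ⁿ⁾])² C_xⁿ/n!,
   with Gaussian-moment evaluation of the derivative expectations. The
   1/n! factor is kept (it is required for consistency with the
   other routes, which the tests verify). For x − x³/3 this reduces to
   (1 + C₀² − 2C₀)C + (2/3)C³.
3. **Bivariate quadrature.** The double Gaussian integral over
   (background, shared) variables is evaluated with composite
   Gauss–Legendre rules whose panels are split at the nonlinearity's
   kink positions (a declared `breakpoints` field; the inner integral is
   taken in the variable in which those positions are fixed). Panel
   width 2.125 standard deviations, 16 nodes per panel, domain ±8.5σ.
   This keeps spectral accuracy for non-smooth φ, where fixed-order
   Gauss–Hermite stalls near 1e−4; measured agreement with the series
   is ≤ 3e−9 across σ² from 1e−8 to 100. Lags with |ρ| = 1 collapse to
   a 1-D expectation and are handled exactly.
4. **Monte-Carlo.** Frequency-domain sampling: independent complex
   Gaussian coefficients with variance S(f)Δf and Hermitian symmetry,
   inverse FFT, φ applied pointwise, averaged periodogram. Optionally an
   added coherent oscillation with per-sample uniform phase. One seed
   per call; reproducible.

## Oscillatory drive

The drive PSD is a delta pair of mass A_I²/4 at ±f_I (f_I must sit on
the grid). State: the background spectrum S_bkg plus rate peak masses
c_k at harmonics k·f_I (k ≤ 8 by default); the activation peak masses
follow as b_k = G̃(kf_I)(g²c_k + δ_{k1}A_I²/4). Two modelling points:

- Only the direct drive acts *coherently* on a unit. The oscillatory
  feedback from the rest of the network arrives through random couplings
  with random phases and therefore adds *incoherently* — in power, not
  amplitude. Sample paths accordingly carry d₁ = χ̃₀(f_I)(A_I/2·e^{iθ}
  + e₁), d_k = χ̃₀(kf_I)e_k with e_k ~ CN(0, g²c_k), reproducing both
  the mean power and the across-units power distribution.
- The fundamental's self-consistency c₁ = M(c₁) is solved by bracketing
  and bisection at every outer iteration (common random numbers make
  M smooth), keeping the **smallest** non-negative root. The map has a
  second, fully entrained fixed point (background suppressed, pure
  limit cycle); plain forward iteration falls onto it even for weak
  drive because the oscillatory loop gain exceeds one before the
  chaotic background — which saturates that loop — has built up. The
  solver also warm-starts the background from the converged undriven
  solution for the same reason. With strong drive near the resonance
  the smallest root grows and the background decays across outer
  iterations, recovering chaos suppression; against a microscopic
  simulation (N = 1000, A_I = 1.5, f_I ≈ f₀) the solver's
  background/oscillation split matches within ~10%.

The Monte-Carlo steps leave a noise floor in the residual, so the
driven solver damps with a decaying schedule (α = 0.5/(1 + n/30),
floor 0.15), averages the final 25 iterates, and reports convergence
when the moving-average residual reaches 2e−2 or the tail residuals
show no drift. Peak/background separation on the grid uses neighbour
interpolation: A_bkg = (S(f_I−Δf)+S(f_I+Δf))/2, A_osc = S(f_I) − A_bkg.

## Heterogeneous adaptation

Gaussian quenched disorder in β (mean β̄, spread σ_β) enters the theory
as an effective filter G̃_H = G̃/(1 − γ²σ_β²/(γ²+ω²)·G̃), used as a
drop-in replacement for G̃; the function raises if the denominator is
not positive everywhere (heterogeneity too strong). The microscopic
simulator samples β_i as drawn — including negative values, with a
warning and a reported fraction — and builds per-unit interaction
matrices.

## Microscopic simulator

Fixed-step classical RK4, default dt = 0.05 (≤ a tenth of the fastest
unit timescale, enforced), burn-in 200 and duration 2000 time units by
default. Initial conditions: x_i ~ N(0, 0.5²), auxiliary variables at
zero. Named seed streams for connectivity, initial conditions, drive
phases and heterogeneity, so each randomness source can be frozen
independently; identical configurations are bit-identical. Because the
dynamics are chaotic, step-halving robustness is asserted on attractor
statistics (variance, peak frequency), not on trajectories.

Spectral estimation is a Hann-window Welch average (50% overlap)
additionally averaged across units, normalized to the package's
two-sided-sum convention. The estimator's expectation is the true
spectrum convolved with the window kernel, so quantitative
theory-versus-simulation comparisons convolve the theoretical spectrum
with the same kernel (`expected_welch_spectrum`) rather than comparing
raw curves — this removes a known bias at narrow resonance peaks
without touching either measurement.

## Metrics

Q-factor: peak by parabolic interpolation around the grid argmax
(f = 0 eligible; a spectrum peaked at zero is non-resonant and carries
no Q), half-maximum width measured on the main lobe only (contiguous
region above half max), so harmonic side lobes do not contaminate it.
Correlation time: trapezoidal normalized first moment of |C|, truncated
at the last lag with |C| > 1e−4·C(0); an error is raised if the
autocorrelation has not decayed below that floor within the horizon.
Both are invariant under positive rescaling of the spectrum.

## Validation problem sizes

The heavier end-to-end checks run at desk scale, chosen to keep the
full suite in the tens of minutes while leaving the statistical
conclusions unambiguous: theory-versus-simulation spectra use N = 1000
units for 450 time units per connectivity realization, averaged over
six realizations (the mean-field prediction is realization-free, so
averaging over quenched draws is the matched comparison; a single
realization at this N carries quenched spectral wiggles comparable to
the finite-N bias itself); the
activation-distribution check uses N = 2000 for 250 time units; the
SNR-versus-f_I scan averages three solver seeds over ten drive
frequencies; trend checks (Q vs g, t_c vs γ) use the default Δf = 0.001
grid. Monte-Carlo steps use 256 sample paths per iteration.

## Known limitations

- At N ~ 1000 the empirical resonance peak of a single connectivity
  realization wobbles by a few grid bins around f₀ (quenched
  finite-size effect); comparisons at that size either average over
  realizations or tolerate peak-sized L1 contributions.
- The driven solver's stochastic residual floor (~2%) limits how finely
  SNR curves can be resolved per seed; the scan tests average seeds.
- The entrained and chaotic branches coexist over part of the drive
  parameter space; the smallest-root policy selects the branch
  continuously connected to the weak-drive response, which matches the
  microscopic simulations performed here, but no claim is made about
  global stability of either branch.
- Heterogeneity is treated only through the effective filter above;
  per-neuron mean-field systems are exercised only via the simulator.
- The maximum Lyapunov exponent is not computed; "chaotic" is used in
  the operational sense of a nonzero continuous self-consistent
  spectrum with decaying autocorrelation.
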