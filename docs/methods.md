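# Methods

## Phase model and estimator

The observed system is a pair of weakly interacting, noisy,
self-sustained oscillators reduced to their phase dynamics,

    dφ_i/dt = Σ_k c_k^i Φ_{i,k}(φ_i, φ_j) + ξ_i(t),     i = 1, 2,

where the base functions are a real Fourier expansion on the two-torus.
For each oscillator the basis contains the constant (its coefficient is
the natural frequency ω_i) and, for every wavenumber pair (k, s) with
|k|, |s| ≤ K taken over a canonical half-lattice, the pair
cos(k·φ_own + s·φ_partner), sin(k·φ_own + s·φ_partner).  With the
default K = 2 this is 25 base functions per oscillator.  Terms with
s ≠ 0 depend on the partner's phase and constitute the coupling
function; their coefficient subvector feeds the coupling strength and
similarity statistics.  ξ_i are independent white Gaussian noises; the
2×2 noise matrix E is kept diagonal (no noise cross-correlation, no
correlated parameter diffusion).

Inference proceeds over consecutive, non-overlapping blocks of length
`t_w`.  Phase velocities are forward finite differences of the unwrapped
phases over the sampling step h, and the basis is evaluated at the
midpoints of consecutive samples.  Within a block, the Gaussian
posterior is found by iterating to a stationary point:

1. `E_ii = h · mean(r_i²)` from the residuals r_i of the velocities
   against the current model;
2. `Ξ_post = Ξ_prior + (h / E_ii) ΦᵀΦ` per oscillator;
3. `c = Ξ_post⁻¹ [ Ξ_prior c_prior + (h / E_ii) Φᵀ φ̇ − (h/2) Σ_n ∂Φ/∂φ ]`,
   the last term being the Itô drift correction.

Iteration stops when the parameter vector changes by less than 1e-6
(relative) or after 100 iterations.  In the flat-prior, vanishing-noise
limit the update reduces to ordinary least squares of the
finite-difference velocities on the basis; the test suite asserts this
equivalence to 1e-8 against an independent `lstsq` oracle.

Between blocks the posterior mean is carried forward unchanged and the
covariance is widened by the diffusion matrix `diag((p_w · c_i)²)`; the
propagation parameter `p_w` is the fraction of each parameter's value
allowed as between-block drift.  The first block uses a flat prior
(zero mean, concentration 1e-8).

### Numerical safeguards

* Blocks whose concentration matrix has reciprocal condition number
  below √ε ≈ 1.5e-8 (ε = double-precision machine epsilon) raise a
  singular-matrix error: beyond that point half the mantissa is lost
  and the solved coefficients are numerically meaningless.  This is the
  practical "window too short" failure mode — on cardiorespiratory-scale
  data the slowest basis component (the slow oscillator's fundamental,
  or a slow beat |k·ω₁ + s·ω₂|) stays nearly collinear with the constant
  within a too-short block.
* The noise estimate is floored away from zero, and non-finite
  parameters or noise estimates abort the block as singular rather than
  propagating.
* Σ and Ξ are maintained per oscillator via Cholesky factorizations
  (they are block-diagonal because E is diagonal).

## Window and propagation-parameter selection

Pass 1 runs the inference at the smallest feasible window — a scan that
starts at four velocity samples per base function and grows
geometrically (factor 1.25) until a full sequential run completes
without a singular block; the scan is capped so at least eight blocks
remain.  Pass 1 uses p_w = 0.2.

The block-wise series of every inferred coefficient (first two blocks
excluded as the flat-prior transient, mean removed) is then
Fourier-transformed at the block rate.  A spectral line is significant
when its amplitude exceeds 5× a robust per-parameter noise floor, taken
as the 95th percentile of that parameter's amplitude spectrum.  Two
bins are never considered: DC, and the single-cycle bin — a variation
completing fewer than two cycles in the record cannot be distinguished
from the slow random wander of the sequential estimates.  (A plain
5×median rule misfires here: with hundreds of blocks the extreme order
statistics of a pure-noise spectrum reach ~6× its median, while genuine
modulation lines measured on the test system sit at 35–54×.)  The
highest significant frequency over all parameters is `f_max`; if no
parameter shows significant variability the optimizer refuses with a
hint to pick `t_w` directly, since stationary dynamics favour the
longest window the record affords.

The optimal window allocates eight blocks per period of the fastest
variation, `t_w_opt = 1/(8 f_max)` (kept exact in the plan; the actual
run snaps it to a whole number of samples), and the propagation
parameter follows the piecewise rule 0.1 / 0.2 / 2·t_w_opt⁻¹ for slow /
intermediate / fast dynamics, with breakpoints at 40 s and 10 s.  The
rule is continuous at 10 s and deliberately not at 40 s, and always
satisfies p_w_opt > 1/t_w_opt.  Pass 2 reruns the inference at the
optimized settings.

### Diagnostics

`qsigma_surface` maps the block-mean quadrature covariance
`Q_Σ = Σ_ij Σ_ij²` over a (t_w, p_w) grid, recording infeasible points
as NaN; `validation_mse` compares inferred coefficient series against
ground truth (block-averaged, first two blocks excluded).  On the
bundled test system the measured Q_Σ is, for every propagation
parameter and noise level examined, monotone decreasing in t_w across
the feasible range, so its maximum sits at the feasibility edge; the
MSE(p_w) curve at the optimized window shows the expected interior
minimum.  The Q_Σ sweep in `scripts/acceptance.py` therefore reports
the product p_w · argmax(Q_Σ) averaged over p_w ∈ {0.2, 0.5}.

## Synthetic data

`simulate_phase_pair` integrates the coupled phase pair with
Euler–Maruyama at h = 0.01 s (records of 2000 s).  Defaults place the
system at cardiorespiratory scales: ω₁ = 2π·0.3 rad/s (respiration-like)
with modulation ω₁(t) = ω₁c − 0.5·sin(2π f₁ t), ω₂ = 2π·1.1 rad/s
(heart-like), self terms a₁ = 0.8, a₄ = 0.6, couplings a₂ = 0 and
a₃(t) = 0.8 − 0.3·sin(2π f₃ t + π/2), modulation frequencies
f₁ = f₃ = 0.005 Hz, and noise amplitude 0.3 on both oscillators (the
increment per step is E_ii·√h·N(0,1), so the inference's √Ê estimates
the configured amplitude).  Ground-truth channels ω₁(t) and a₃(t) are
stored on the simulation grid.  `simulate_poincare_pair` integrates the
4-D noisy limit-cycle pair (ω₂ = 4.91, ε₁ = 0.05, ε₂(t) = 0.2 −
0.1·sin(2π f₂ t), ω₁(t) = 1 − 0.4·sin(2π f₁ t)) and returns unwrapped
state-space angles.  A dense fixed-step high-order deterministic
integration (`solve_ivp`, rtol 1e-10) of the same vector fields serves
as the reference oracle for the noise-free paths.

The raw-signal fixtures emulate three breathing patterns — constant
0.25 Hz with bounded smoothed-random-walk variability ("free"),
f(t) = 0.3 + 0.2·sin(2π t/560) Hz ("sine"), and a chaotic law from the
z-component of a Lorenz system (σ = 10, ρ = 28, β = 8/3, time axis
compressed by 0.02, affinely rescaled to 0.1–0.5 Hz) — driving a
1.1 Hz "cardiac" oscillator through a 0.5·sin(φ_resp) phase coupling,
with 1% additive observation noise.  These fixtures are smooth cosines:
they exercise the filtering/phase pipeline and the optimizer, but they
do not reproduce ECG morphology (QRS complexes), amplitude
nonstationarity, movement artefacts, or measurement drift, so passing
tests demonstrate correctness of the algorithmic chain, not robustness
to real recording artefacts.

## Phase extraction

Band-pass filtering uses a linear-phase FIR kernel (length ≈ 3 periods
of the low band edge, odd tap count) applied forward and backward
(`filtfilt`), so no phase lag is introduced; conventional bands are
0.145–0.6 Hz (respiration) and 0.6–2 Hz (heart).  The protophase is the
angle of the analytic signal.  The protophase-to-phase transformation
estimates the protophase density through its Fourier coefficients
S_n = ⟨e^{-inθ}⟩ (default 10 harmonics, amplitudes below 1e-4 dropped)
and maps θ through the cumulative density, yielding a phase that grows
uniformly on average, with σ(0) = 0 and σ(θ+2π) = σ(θ)+2π; at least 20
cycles of input are required.  The transformation is applied to
measured/fixture signals only — the simulated phase models provide
phases directly.

## Problem sizes and defaults

Simulated records are 2000 s at h = 0.01 s (200 001 samples); the Q_Σ
sweep uses a 12-point geometric window grid from 2 s to 20 s at two
propagation parameters; MSE curves use the optimized 25 s window over a
7-point p_w grid.  Coupling surfaces default to a 100×100 wrapped grid
(figures only; statistics always use the coefficient vectors).

## Known limitations

* K = 2 limits the representable nonlinearity of coupling functions;
  strongly non-sinusoidal interactions alias into low-order terms.
* Near-resonant frequency pairs produce slow beat terms that keep the
  basis collinear over short blocks and push the feasibility floor up.
* The similarity index is computed on coefficient vectors; for the
  orthogonal Fourier basis this matches surface correlation up to
  weighting, but the two are not numerically identical.
* Networks of more than two oscillators, correlated noises, and
  correlated parameter diffusion are out of scope.
* The time-variability of the selection rule's own inputs is assumed
  slow; regimes where f_max itself drifts would require re-running the
  optimizer on segments.
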