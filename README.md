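# dbiwin — adaptive time windows for dynamical Bayesian inference

`dbiwin` infers **time-varying coupled-oscillator dynamics** from phase
time-series, with the analysis window chosen from the data instead of by
hand.  It is aimed at physiological interactions at cardiorespiratory
scales (respiration ↔ heart), where frequencies, coupling strengths and
coupling functions all drift on time scales of tens to hundreds of
seconds, but applies to any pair of weakly interacting oscillators.

## The model and the method

Two interacting oscillators are described by their phase dynamics

    dφ_i/dt = ω_i + q_i(φ_i, φ_j) + ξ_i(t),        i = 1, 2

with coupling functions q_i expanded on a finite Fourier basis of order
K (default 2) and white Gaussian noise ξ_i.  Dynamical Bayesian
inference (DBI) estimates the basis coefficients c and noise matrix E
block by block: within each window of length `t_w` a Gaussian posterior
over c is computed; between windows the posterior covariance is widened
by a diffusion term `diag((p_w·c_i)²)` — the propagation parameter `p_w`
encodes how much parameter variability the filter can follow.

Both `t_w` and `p_w` were traditionally free parameters.  `dbiwin`
determines them from the data in two passes:

1. infer with the smallest feasible window and `p_w = 0.2`;
2. Fourier-transform the inferred parameter time-series and locate the
   fastest significantly varying frequency `f_max`;
3. allocate eight windows per period of that fastest variation,
   `t_w_opt = 1 / (8 f_max)`, and select

       p_w_opt = 0.1          if t_w_opt > 40 s
                 0.2          if 10 s ≤ t_w_opt ≤ 40 s
                 2 / t_w_opt  if t_w_opt < 10 s

4. re-infer at the optimized settings.

Per block, the quadrature covariance `Q_Σ = Σ_ij Σ_ij²` summarizes the
inference quality (smaller = tighter posteriors), and the coupling is
quantified by its strength `CPL_i` (Euclidean norm of the cross-oscillator
coefficients) and the similarity index `ρ` (correlation between
coupling-coefficient vectors — shape, independent of amplitude).

Ground-truth generators (coupled noisy phase oscillators with
sinusoidally modulated frequency and coupling; coupled noisy Poincaré
limit-cycle oscillators; respiration-like raw-signal fixtures with sine
or chaotic Lorenz-z frequency laws) make the whole chain testable end to
end, and a phase-extraction stage (zero-phase FIR band-pass → Hilbert
protophase → protophase-to-phase transformation) connects raw signals to
the inference.

## Worked example

```python
from dbiwin import PhasePairConfig, simulate_phase_pair, optimize
from dbiwin.coupling_analysis import time_resolved_similarity
from dbiwin.window_optimizer import validation_mse

series = simulate_phase_pair(PhasePairConfig(duration=2000.0, seed=1))
plan, run = optimize(series)
print(f"f_max      = {plan.f_max:.4f} Hz")
print(f"t_w_opt    = {plan.t_w_opt:.1f} s")
print(f"p_w_opt    = {plan.p_w_opt:.1f}")
err = validation_mse(run, series.ground_truth, series.h)
print(f"MSE omega1 = {err['omega1']['mse']:.4f}")
print(f"MSE a3     = {err['a3']['mse']:.4f}")
ts = time_resolved_similarity(run)
print(f"mean CPL_1 = {ts.cpl_1.mean():.3f}")
print(f"mean rho_1 = {ts.rho_1.mean():.3f}")
```

prints

```
f_max      = 0.0050 Hz
t_w_opt    = 24.9 s
p_w_opt    = 0.2
MSE omega1 = 0.0038
MSE a3     = 0.0056
mean CPL_1 = 0.803
mean rho_1 = 0.993
```

The generator modulates the first oscillator's frequency and the 2→1
coupling amplitude at f₁ = f₃ = 0.005 Hz; the optimizer recovers exactly
that frequency from the data, allocates eight blocks per 200 s period
(t_w_opt ≈ 25 s) and picks p_w = 0.2 from the mid branch of the selection
rule.  The optimized run then tracks ω₁(t) and a₃(t) with mean-square
errors far below their modulation amplitudes (0.5 and 0.3), the mean 2→1
coupling strength reflects the configured a₃ ≈ 0.8, and the coupling
function's *shape* stays nearly constant (ρ ≈ 0.99) while its amplitude
oscillates.

The same workflow is available from the shell:

```sh
dbiwin simulate --system phase --duration 2000 --seed 1 --out phases.tsv
dbiwin optimize --in phases.tsv --out-plan plan.txt --out-run run.tsv
dbiwin couplings --tw 25 --pw 0.2 --in phases.tsv --out couplings.tsv
dbiwin pipeline --config config.yaml     # raw signals -> phases -> plan -> couplings
```

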