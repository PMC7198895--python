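"""Adaptive determination of the inference time window and propagation parameter.

The block length ``t_w`` is a tradeoff: long blocks give tight posteriors
(small quadrature covariance Q_Sigma) but too few blocks to resolve
parameter time-variation; short blocks track fast variation but inflate
the posterior, and below a feasibility floor the inference fails outright
with a singular concentration matrix.  The two-pass algorithm implemented
by :func:`optimize` resolves the tradeoff from the data itself:

1. run a first inference with the smallest feasible window and
   ``p_w = 0.2``;
2. Fourier-transform the block-wise inferred parameters and find the
   highest significantly varying frequency ``f_max``;
3. allocate eight blocks per period of that fastest variation,
   ``t_w_opt = T_min / 8 = 1 / (8 f_max)``, and pick the propagation
   parameter by the piecewise rule

       p_w_opt = 0.1           if t_w_opt > 40 s
                 0.2           if 10 s <= t_w_opt <= 40 s
                 2 / t_w_opt   if t_w_opt < 10 s;

4. rerun the inference at the optimized settings.

Diagnostic surfaces (Q_Sigma over a t_w x p_w grid, per-parameter MSE
against ground truth) used to validate the rule on simulations are also
provided here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import (
    FourierModel,
    InferenceRun,
    InferenceSettings,
    SingularModelError,
    run_sequential,
)

__all__ = [
    "WindowPlan",
    "QSigmaSurface",
    "smallest_feasible_window",
    "estimate_fmax",
    "optimal_window",
    "optimal_propagation",
    "optimize",
    "qsigma_surface",
    "validation_mse",
    "block_mean_qsigma",
]

log = logging.getLogger(__name__)

#: blocks skipped at the start of a run when summarizing it (transient of
#: the flat first-block prior)
N_TRANSIENT_BLOCKS = 2

#: minimum number of blocks the initial pass must provide for a usable
#: parameter spectrum
MIN_INITIAL_BLOCKS = 16


@dataclass
class WindowPlan:
    """Outcome of the two-pass window/propagation optimization."""

    f_max: float
    t_w_opt: float
    p_w_opt: float
    initial_t_w: float
    spectra: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def T_min(self) -> float:
        """Period of the fastest-changing parameter."""
        return 1.0 / self.f_max


@dataclass
class QSigmaSurface:
    """Block-mean Q_Sigma over a (t_w, p_w) grid; NaN marks infeasible points."""

    t_w_grid: np.ndarray
    p_w_grid: np.ndarray
    values: np.ndarray  # shape (len(p_w_grid), len(t_w_grid))

    def t_w_max(self) -> np.ndarray:
        """For each p_w, the t_w at which Q_Sigma is maximal."""
        out = np.empty(len(self.p_w_grid))
        for i, row in enumerate(self.values):
            if np.all(np.isnan(row)):
                out[i] = np.nan
            else:
                out[i] = self.t_w_grid[np.nanargmax(row)]
        return out


def block_mean_qsigma(run: InferenceRun) -> float:
    """Mean Q_Sigma over blocks, excluding the initial transient blocks."""
    q = run.q_sigma[N_TRANSIENT_BLOCKS:]
    if q.size == 0:
        q = run.q_sigma
    return float(np.mean(q))


def smallest_feasible_window(
    phases,
    p_w: float = 0.2,
    order: int = 2,
    growth: float = 1.25,
) -> float:
    """Scan upward from the basis-dimension floor for a workable t_w.

    The floor guarantees at least four velocity samples per base function;
    from there, windows grow geometrically until a full sequential run
    completes without a singular-matrix failure.  The returned window
    always admits >= 8 blocks of the record (an unusable pass otherwise).
    """
    model = FourierModel(order=order)
    h = float(phases.h)
    duration = len(phases.phi1) * h
    floor = 4 * model.n_params * h
    cap = duration / 8.0
    t_w = floor
    while t_w <= cap:
        t_w_snapped = max(1, int(round(t_w / h))) * h
        settings = InferenceSettings(t_w=t_w_snapped, p_w=p_w, order=order)
        try:
            run_sequential(phases, settings)
        except SingularModelError:
            t_w *= growth
            continue
        return t_w_snapped
    raise SingularModelError(
        "no feasible time window below duration/8; record too short or too "
        "degenerate for the chosen basis order"
    )


def estimate_fmax(
    run: InferenceRun,
    significance: float = 5.0,
) -> tuple[float, dict[str, np.ndarray]]:
    """Highest significantly varying frequency among the inferred parameters.

    The block-wise series of every parameter (first transient blocks
    excluded, mean removed) is Fourier-transformed at the block rate
    ``1/t_w``.  A spectral line is significant when its amplitude exceeds
    ``significance`` times that parameter's noise floor, estimated
    robustly as the 95th percentile of its amplitude spectrum (with
    hundreds of bins the extreme order statistics of pure noise reach
    several times the median, so a median-based floor would fire on
    noise); ``f_max`` is the highest significant frequency over all
    parameters.  The DC bin and the first harmonic of the record length
    are excluded: a variation completing less than two cycles in the
    record is indistinguishable from a slow trend of the sequential
    estimates.  Returns ``(f_max, spectra)`` where ``spectra`` holds the
    common frequency axis and the per-parameter amplitude matrix.
    """
    C = run.parameter_series()[N_TRANSIENT_BLOCKS:]
    n_blocks = C.shape[0]
    if n_blocks < MIN_INITIAL_BLOCKS:
        raise ValueError(
            f"only {n_blocks} usable blocks; at least {MIN_INITIAL_BLOCKS} "
            "are needed for a parameter spectrum -- use a smaller t_w or a "
            "longer record"
        )
    t_w = run.settings.t_w
    C = C - C.mean(axis=0)
    F = np.fft.rfft(C, axis=0)
    amp = 2.0 * np.abs(F) / n_blocks
    freqs = np.fft.rfftfreq(n_blocks, d=t_w)
    f_max = 0.0
    for j in range(amp.shape[1]):
        a = amp[2:, j]  # drop DC and the single-cycle (trend) bin
        floor = np.percentile(a, 95.0)
        if floor <= 0:
            continue
        sig = np.nonzero(a >= significance * floor)[0]
        if sig.size:
            f_max = max(f_max, float(freqs[2:][sig[-1]]))
    if f_max <= 0:
        raise ValueError(
            "no detectable time-variability in any inferred parameter; the "
            "dynamics appear stationary -- pick t_w directly (larger is "
            "better) instead of using the adaptive rule"
        )
    return f_max, {"freqs": freqs, "amplitudes": amp}


def optimal_window(f_max: float) -> float:
    """Eight blocks per period of the fastest parameter variation."""
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    return 1.0 / (8.0 * f_max)


def optimal_propagation(t_w_opt: float) -> float:
    """Piecewise propagation-parameter rule (cardiorespiratory scaling).

    0.1 for slow dynamics (t_w_opt > 40 s), 0.2 in the mid range
    [10 s, 40 s], and 2 / t_w_opt for fast dynamics (t_w_opt < 10 s).
    Continuous at 10 s (2/10 = 0.2), deliberately not at 40 s.
    """
    if t_w_opt <= 0:
        raise ValueError("t_w_opt must be positive")
    if t_w_opt > 40.0:
        return 0.1
    if t_w_opt >= 10.0:
        return 0.2
    return 2.0 / t_w_opt


def optimize(
    phases,
    initial_t_w: float | None = None,
    order: int = 2,
    significance: float = 5.0,
) -> tuple[WindowPlan, InferenceRun]:
    """Full two-pass algorithm; returns the plan and the optimized run."""
    h = float(phases.h)
    if initial_t_w is None:
        initial_t_w = smallest_feasible_window(phases, p_w=0.2, order=order)
    log.info("initial pass: t_w=%.3f s, p_w=0.2", initial_t_w)
    first = run_sequential(
        phases, InferenceSettings(t_w=initial_t_w, p_w=0.2, order=order)
    )
    f_max, spectra = estimate_fmax(first, significance=significance)
    t_w_opt = optimal_window(f_max)
    p_w_opt = optimal_propagation(t_w_opt)
    log.info(
        "plan: f_max=%.5f Hz, t_w_opt=%.2f s, p_w_opt=%.3f", f_max, t_w_opt, p_w_opt
    )
    plan = WindowPlan(
        f_max=f_max,
        t_w_opt=t_w_opt,
        p_w_opt=p_w_opt,
        initial_t_w=initial_t_w,
        spectra=spectra,
    )
    t_w_run = max(1, int(round(t_w_opt / h))) * h  # snap to the sample grid
    optimized = run_sequential(
        phases, InferenceSettings(t_w=t_w_run, p_w=p_w_opt, order=order)
    )
    return plan, optimized


def qsigma_surface(
    phases,
    t_w_grid: np.ndarray,
    p_w_grid: np.ndarray,
    order: int = 2,
) -> QSigmaSurface:
    """Block-mean Q_Sigma for every (t_w, p_w) grid point.

    Infeasible points (singular blocks, too-short records) are recorded as
    NaN rather than aborting the sweep.
    """
    t_w_grid = np.asarray(t_w_grid, dtype=float)
    p_w_grid = np.asarray(p_w_grid, dtype=float)
    h = float(phases.h)
    values = np.full((len(p_w_grid), len(t_w_grid)), np.nan)
    for i, p_w in enumerate(p_w_grid):
        for j, t_w in enumerate(t_w_grid):
            t_w_s = max(1, int(round(t_w / h))) * h
            try:
                run = run_sequential(
                    phases, InferenceSettings(t_w=t_w_s, p_w=p_w, order=order)
                )
            except (SingularModelError, ValueError) as exc:
                log.debug("grid point (t_w=%.3g, p_w=%.3g) infeasible: %s",
                          t_w, p_w, exc)
                continue
            values[i, j] = block_mean_qsigma(run)
    return QSigmaSurface(t_w_grid=t_w_grid, p_w_grid=p_w_grid, values=values)


#: ground-truth channel -> (oscillator, basis term) for the phase-pair system
_TRUTH_TERMS = {
    "omega1": (1, ("const", 0, 0)),
    "omega2": (2, ("const", 0, 0)),
    "a3": (1, ("sin", 0, 1)),
    "a1": (1, ("sin", 1, 0)),
    "a2": (2, ("sin", 0, 1)),
    "a4": (2, ("sin", 1, 0)),
}


def validation_mse(
    run: InferenceRun,
    ground_truth: dict[str, np.ndarray],
    h: float,
) -> dict[str, dict[str, np.ndarray | float]]:
    """Per-parameter error series Delta c(t) and their mean-square error.

    ``ground_truth`` maps channel names (``omega1``, ``a3``, ...) to
    per-sample true values on the simulation grid with step ``h``.  The
    truth is averaged within each block for comparability with the
    block-wise inferred value; the first transient blocks are excluded
    from both the series and the MSE.
    """
    model = run.settings.model
    n_block = int(round(run.settings.t_w / h))
    n_blocks = len(run.states)
    C = run.parameter_series()
    out: dict[str, dict[str, np.ndarray | float]] = {}
    for name, truth in ground_truth.items():
        if name not in _TRUTH_TERMS:
            continue
        osc, (kind, k, s) = _TRUTH_TERMS[name]
        idx = model.global_index(osc, model.term_index(kind, k, s))
        truth = np.asarray(truth, dtype=float)
        if truth.size < n_blocks * n_block:
            raise ValueError(f"ground-truth channel {name!r} shorter than the run")
        blocks = truth[: n_blocks * n_block].reshape(n_blocks, n_block)
        truth_block = blocks.mean(axis=1)
        delta = C[:, idx] - truth_block
        d = delta[N_TRANSIENT_BLOCKS:]
        out[name] = {
            "delta": delta,
            "mse": float(np.mean(d * d)),
            "inferred": C[:, idx],
            "truth": truth_block,
        }
    return out
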