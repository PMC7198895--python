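"""Ground-truth generators for validating the adaptive-window inference.

Two test systems at cardiorespiratory scales:

* a pair of coupled noisy *phase* oscillators whose first frequency and
  whose 2->1 coupling amplitude vary slowly and sinusoidally in time
  (:func:`simulate_phase_pair`) -- every true parameter is known per
  sample, so inference error can be computed exactly;
* a pair of coupled noisy *Poincare* limit-cycle oscillators
  (:func:`simulate_poincare_pair`), whose phases must be read off the
  state-space angle, standing in for signals one would measure.

Both are integrated with Euler--Maruyama at the stated sampling step; a
deterministic high-order reference integration of the same vector field is
used as an oracle in the tests.  :func:`aperiodic_driver` provides a
chaotic (Lorenz z-component) frequency law and :func:`make_fixture` writes
raw two-signal fixtures emulating respiration-like breathing patterns
(free / sine-modulated / aperiodic) driving a faster "cardiac" oscillator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PhasePairConfig",
    "PoincareConfig",
    "PhasePairSeries",
    "simulate_phase_pair",
    "simulate_poincare_pair",
    "aperiodic_driver",
    "make_fixture",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhasePairConfig:
    """Parameters of the coupled phase-oscillator test system.

    The dynamics are::

        dphi1/dt = omega1(t) + a1 sin(phi1) + a3(t) sin(phi2) + E11 xi1
        dphi2/dt = omega2    + a2 sin(phi1) + a4 sin(phi2)    + E22 xi2

    with slow sinusoidal laws ``omega1(t) = omega1_const - mod_omega *
    sin(2 pi f1 t)`` and ``a3(t) = a3_const - mod_a3 * sin(2 pi f3 t +
    pi/2)``; ``xi_i`` are independent unit white noises, so ``E11, E22``
    are the noise *amplitudes* (an increment contributes ``E_ii *
    sqrt(h)`` per step).  Defaults place the oscillators at respiration-
    and heart-like frequencies (0.3 Hz and 1.1 Hz).
    """

    omega1_const: float = TWO_PI * 0.3
    omega2: float = TWO_PI * 1.1
    a1: float = 0.8
    a2: float = 0.0
    a3_const: float = 0.8
    a4: float = 0.6
    f1: float = 0.005
    f3: float = 0.005
    mod_omega: float = 0.5
    mod_a3: float = 0.3
    E11: float = 0.3
    E22: float = 0.3
    h: float = 0.01
    duration: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("sampling step h must be positive")
        n = self.duration / self.h
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError("duration must be a whole number of steps")
        if self.E11 < 0 or self.E22 < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    def omega1(self, t: np.ndarray) -> np.ndarray:
        return self.omega1_const - self.mod_omega * np.sin(TWO_PI * self.f1 * t)

    def a3(self, t: np.ndarray) -> np.ndarray:
        return self.a3_const - self.mod_a3 * np.sin(TWO_PI * self.f3 * t + np.pi / 2)


@dataclass(frozen=True)
class PoincareConfig:
    """Parameters of the coupled noisy Poincare (limit-cycle) oscillators.

    Each unit relaxes onto a unit-radius cycle; diffusive coupling acts on
    the state variables.  The first oscillator's frequency and the 1->2
    coupling vary slowly: ``omega1(t) = omega1_const - 0.4 sin(2 pi f1 t)``
    and ``eps2(t) = eps2_const - 0.1 sin(2 pi f2 t)``.
    """

    omega1_const: float = 1.0
    omega2: float = 4.91
    eps1: float = 0.05
    eps2_const: float = 0.2
    f1: float = 0.005
    f2: float = 0.005
    mod_omega: float = 0.4
    mod_eps2: float = 0.1
    noise_strengths: tuple[float, float, float, float] = (0.02, 0.02, 0.02, 0.02)
    h: float = 0.01
    duration: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("sampling step h must be positive")
        if any(e < 0 for e in self.noise_strengths):
            raise ValueError("noise strengths must be nonnegative")

    def omega1(self, t: np.ndarray) -> np.ndarray:
        return self.omega1_const - self.mod_omega * np.sin(TWO_PI * self.f1 * t)

    def eps2(self, t: np.ndarray) -> np.ndarray:
        return self.eps2_const - self.mod_eps2 * np.sin(TWO_PI * self.f2 * t)


@dataclass
class PhasePairSeries:
    """Two unwrapped phase trajectories on a common uniform time grid."""

    time: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    h: float
    ground_truth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.phi1) == len(self.phi2)):
            raise ValueError("time and phase arrays must have equal length")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def mean_velocities(self) -> tuple[float, float]:
        d = self.duration
        return (
            float(self.phi1[-1] - self.phi1[0]) / d,
            float(self.phi2[-1] - self.phi2[0]) / d,
        )


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"non-finite values in {what}: integration unstable, reduce the step h"
        )


def simulate_phase_pair(config: PhasePairConfig) -> PhasePairSeries:
    """Euler--Maruyama integration of the coupled phase-oscillator pair.

    Noise increments are ``E_ii * sqrt(h) * N(0, 1)``, independent between
    oscillators and steps.  The ground-truth channels ``omega1`` and ``a3``
    are sampled on the same grid for exact error computation downstream.
    """
    n = int(round(config.duration / config.h))
    h = config.h
    rng = np.random.default_rng(config.seed)
    t = np.arange(n + 1) * h
    om1 = config.omega1(t)
    a3 = config.a3(t)
    noise = rng.standard_normal((n, 2))
    sq = math.sqrt(h)
    phi1 = np.empty(n + 1)
    phi2 = np.empty(n + 1)
    phi1[0] = rng.uniform(0, TWO_PI)
    phi2[0] = rng.uniform(0, TWO_PI)
    p1, p2 = phi1[0], phi2[0]
    a1, a2c, a4 = config.a1, config.a2, config.a4
    om2 = config.omega2
    e1, e2 = config.E11 * sq, config.E22 * sq
    sin = math.sin
    for k in range(n):
        d1 = om1[k] + a1 * sin(p1) + a3[k] * sin(p2)
        d2 = om2 + a2c * sin(p1) + a4 * sin(p2)
        p1 = p1 + d1 * h + e1 * noise[k, 0]
        p2 = p2 + d2 * h + e2 * noise[k, 1]
        phi1[k + 1] = p1
        phi2[k + 1] = p2
    _check_finite(phi1, "phi1")
    _check_finite(phi2, "phi2")
    return PhasePairSeries(
        time=t,
        phi1=phi1,
        phi2=phi2,
        h=h,
        ground_truth={"omega1": om1, "a3": a3},
    )


def phase_pair_rhs(config: PhasePairConfig):
    """Deterministic vector field of the phase pair, for reference integration."""

    def rhs(t, y):
        p1, p2 = y
        om1 = config.omega1_const - config.mod_omega * math.sin(TWO_PI * config.f1 * t)
        a3 = config.a3_const - config.mod_a3 * math.sin(
            TWO_PI * config.f3 * t + math.pi / 2
        )
        return [
            om1 + config.a1 * math.sin(p1) + a3 * math.sin(p2),
            config.omega2 + config.a2 * math.sin(p1) + config.a4 * math.sin(p2),
        ]

    return rhs


def simulate_poincare_pair(config: PoincareConfig) -> PhasePairSeries:
    """Euler--Maruyama integration of the coupled Poincare oscillators.

    Protophases are the planar angles ``atan2(y_i, x_i)``, unwrapped.  The
    ground-truth channels hold ``omega1(t)`` and ``eps2(t)``.
    """
    n = int(round(config.duration / config.h))
    h = config.h
    rng = np.random.default_rng(config.seed)
    t = np.arange(n + 1) * h
    om1 = config.omega1(t)
    eps2 = config.eps2(t)
    noise = rng.standard_normal((n, 4)) * math.sqrt(h)
    amps = np.asarray(config.noise_strengths)
    state = np.empty((n + 1, 4))
    # start on the attractor with random angles
    th1, th2 = rng.uniform(0, TWO_PI, size=2)
    state[0] = [math.cos(th1), math.sin(th1), math.cos(th2), math.sin(th2)]
    x1, y1, x2, y2 = state[0]
    eps1 = config.eps1
    om2 = config.omega2
    for k in range(n):
        r1 = x1 * x1 + y1 * y1 - 1.0
        r2 = x2 * x2 + y2 * y2 - 1.0
        dx1 = -r1 * x1 - om1[k] * y1 + eps1 * (x2 - x1)
        dy1 = -r1 * y1 + om1[k] * x1 + eps1 * (y2 - y1)
        dx2 = -r2 * x2 - om2 * y2 + eps2[k] * (x1 - x2)
        dy2 = -r2 * y2 + om2 * x2 + eps2[k] * (y1 - y2)
        x1 += dx1 * h + amps[0] * noise[k, 0]
        y1 += dy1 * h + amps[1] * noise[k, 1]
        x2 += dx2 * h + amps[2] * noise[k, 2]
        y2 += dy2 * h + amps[3] * noise[k, 3]
        state[k + 1] = (x1, y1, x2, y2)
    _check_finite(state, "Poincare state")
    phi1 = np.unwrap(np.arctan2(state[:, 1], state[:, 0]))
    phi2 = np.unwrap(np.arctan2(state[:, 3], state[:, 2]))
    return PhasePairSeries(
        time=t,
        phi1=phi1,
        phi2=phi2,
        h=h,
        ground_truth={"omega1": om1, "eps2": eps2, "state": state},
    )


def poincare_rhs(config: PoincareConfig):
    """Deterministic vector field of the Poincare pair, for reference integration."""

    def rhs(t, y):
        x1, y1_, x2, y2_ = y
        om1 = config.omega1_const - config.mod_omega * math.sin(TWO_PI * config.f1 * t)
        ep2 = config.eps2_const - config.mod_eps2 * math.sin(TWO_PI * config.f2 * t)
        r1 = x1 * x1 + y1_ * y1_ - 1.0
        r2 = x2 * x2 + y2_ * y2_ - 1.0
        return [
            -r1 * x1 - om1 * y1_ + config.eps1 * (x2 - x1),
            -r1 * y1_ + om1 * x1 + config.eps1 * (y2_ - y1_),
            -r2 * x2 - config.omega2 * y2_ + ep2 * (x1 - x2),
            -r2 * y2_ + config.omega2 * x2 + ep2 * (y1_ - y2_),
        ]

    return rhs


# --------------------------------------------------------------------------
# aperiodic (chaotic) frequency driver
# --------------------------------------------------------------------------

#: classic chaotic Lorenz parameters used for the aperiodic driver
LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0
#: time compression applied to the Lorenz system so its z-component drifts
#: on breathing-variability scales (hundreds of seconds)
LORENZ_TIMESCALE = 0.02


def aperiodic_driver(
    duration: float,
    h: float,
    seed: int = 0,
    band: tuple[float, float] = (0.1, 0.5),
) -> np.ndarray:
    """Chaotic scalar time-series usable as a slow frequency law.

    The z-component of a Lorenz system at the classic chaotic parameters
    (sigma=10, rho=28, beta=8/3), run on a compressed time scale, is
    rescaled affinely so its min/max span ``band`` (Hz by convention).
    """
    if duration <= 0 or h <= 0:
        raise ValueError("duration and h must be positive")
    rng = np.random.default_rng(seed)
    y0 = rng.normal([0.0, 0.0, 25.0], [5.0, 5.0, 5.0])

    def lorenz(t, y):
        x, yy, z = y
        return [
            LORENZ_SIGMA * (yy - x),
            x * (LORENZ_RHO - z) - yy,
            x * yy - LORENZ_BETA * z,
        ]

    # transient discard, then sample on the caller's grid (compressed time)
    t_burn = 20.0
    tau_end = t_burn + duration * LORENZ_TIMESCALE
    t_eval = t_burn + np.arange(int(round(duration / h)) + 1) * h * LORENZ_TIMESCALE
    sol = solve_ivp(
        lorenz,
        (0.0, tau_end),
        y0,
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-8,
        dense_output=False,
    )
    if not sol.success:
        raise FloatingPointError(f"Lorenz integration failed: {sol.message}")
    z = sol.y[2]
    lo, hi = band
    zmin, zmax = z.min(), z.max()
    return lo + (z - zmin) * (hi - lo) / (zmax - zmin)


# --------------------------------------------------------------------------
# raw-signal fixtures
# --------------------------------------------------------------------------


def make_fixture(
    kind: str,
    duration: float = 1200.0,
    h: float = 0.01,
    seed: int = 0,
    out: str | Path | None = None,
    sine_period: float = 560.0,
    free_variability: float = 0.03,
):
    """Raw two-signal fixture emulating a breathing-pattern experiment.

    ``kind`` selects the slow frequency law of the respiration-like signal:

    * ``"free"``   -- 0.25 Hz with mild smoothed random-walk variability of
      amplitude ``free_variability`` Hz (0 gives a constant frequency);
    * ``"sine"``   -- f(t) = 0.3 + 0.2 sin(2 pi t / sine_period) Hz;
    * ``"aperiodic"`` -- Lorenz-z law rescaled to [0.1, 0.5] Hz.

    The cardiac-like signal runs near 1.1 Hz and is phase-modulated by the
    respiratory phase, so the downstream pipeline has a coupling to find.
    Returns ``(time, signal1, signal2, truth)`` where ``truth`` maps
    ``"f1"`` to the instantaneous frequency law (Hz) on the same grid.  If
    ``out`` is given, writes the signals and a ``<out>.truth`` sidecar as
    tab-separated text.
    """
    n = int(round(duration / h))
    t = np.arange(n + 1) * h
    rng = np.random.default_rng(seed)
    if kind == "sine":
        f1 = 0.3 + 0.2 * np.sin(TWO_PI * t / sine_period)
    elif kind == "free":
        # slow bounded variability around 0.25 Hz (smoothed random walk)
        steps = rng.standard_normal(n + 1)
        walk = np.cumsum(steps) * math.sqrt(h)
        kernel = np.exp(-np.arange(0, 30.0, h) / 10.0)
        kernel /= kernel.sum()
        slow = np.convolve(walk, kernel, mode="same")
        slow = slow - slow.mean()
        span = max(np.abs(slow).max(), 1e-12)
        f1 = 0.25 + free_variability * slow / span
    elif kind == "aperiodic":
        f1 = aperiodic_driver(duration, h, seed=seed, band=(0.1, 0.5))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    phi1 = TWO_PI * np.concatenate([[0.0], np.cumsum(f1[:-1]) * h])
    # cardiac-like oscillator driven by the respiratory phase
    f_heart = 1.1
    coupling = 0.5
    dphi2 = TWO_PI * f_heart + coupling * np.sin(phi1)
    phi2 = rng.uniform(0, TWO_PI) + np.concatenate(
        [[0.0], np.cumsum(dphi2[:-1]) * h]
    )
    sig1 = np.cos(phi1) + 0.01 * rng.standard_normal(n + 1)
    sig2 = np.cos(phi2) + 0.01 * rng.standard_normal(n + 1)
    truth = {"f1": f1}
    if out is not None:
        from .io import write_series

        out = Path(out)
        write_series(out, t, {"sig1": sig1, "sig2": sig2})
        write_series(out.with_suffix(out.suffix + ".truth"), t, {"f1": f1})
    return t, sig1, sig2, truth
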