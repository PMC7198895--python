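"""From raw oscillatory signals to invariant phases.

Three steps, mirroring standard practice for respiration/ECG-derived
signals: (1) band-pass the signal with a linear-phase FIR filter applied
forward and backward (zero net phase lag); (2) take the angle of the
analytic signal (Hilbert transform) as a *protophase*; (3) map the
protophase to an invariant, observable-independent phase by the
distribution-flattening transformation (Fourier-series estimate of the
protophase density), so that the transformed phase grows uniformly on
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

__all__ = [
    "BandSpec",
    "bandpass_zero_phase",
    "protophase",
    "protophase_to_phase",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz for a signal sampled at ``sampling_rate`` Hz.

    Conventional cardiorespiratory bands are 0.145-0.6 Hz for respiration
    and 0.6-2 Hz for heart activity.
    """

    low: float
    high: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high < self.sampling_rate / 2):
            raise ValueError(
                "band must satisfy 0 < low < high < Nyquist "
                f"(got {self.low}-{self.high} Hz at fs={self.sampling_rate})"
            )

    def filter_order(self) -> int:
        """FIR length: ~3 periods of the low edge, capped by signal practice.

        A transition band a fraction of ``low`` needs an impulse response
        of a few ``1/low`` seconds; an odd tap count keeps the filter
        type-I (symmetric, exactly linear phase).
        """
        taps = int(round(3.0 * self.sampling_rate / self.low))
        return taps + 1 if taps % 2 == 0 else taps


def bandpass_zero_phase(signal: np.ndarray, band: BandSpec) -> np.ndarray:
    """Zero-phase FIR band-pass: ``filtfilt`` with a linear-phase kernel.

    Forward-backward application cancels the (already linear) phase
    response entirely, so oscillation timing is preserved; passband gain
    is ~1, stopband strongly attenuated.
    """
    signal = np.asarray(signal, dtype=float)
    taps = band.filter_order()
    if signal.size <= 3 * taps:
        raise ValueError(
            f"signal of {signal.size} samples too short for a {taps}-tap filter"
        )
    kernel = firwin(
        taps, [band.low, band.high], pass_zero=False, fs=band.sampling_rate
    )
    return filtfilt(kernel, [1.0], signal)


def protophase(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic-signal angle of a zero-mean band-limited signal.

    Returns ``(wrapped, unwrapped)``: the angle in [0, 2*pi) and its
    unwrapped (cumulative) version.  Raises on an (all-)zero signal whose
    angle is undefined.
    """
    signal = np.asarray(signal, dtype=float)
    if np.allclose(signal, 0.0):
        raise ValueError("protophase undefined for an all-zero signal")
    analytic = hilbert(signal - signal.mean())
    theta = np.angle(analytic)
    unwrapped = np.unwrap(theta)
    return np.mod(theta, TWO_PI), unwrapped


def protophase_to_phase(
    theta: np.ndarray,
    n_harmonics: int = 10,
    amplitude_threshold: float = 1e-4,
    min_cycles: int = 20,
) -> np.ndarray:
    """Map a protophase to the invariant phase that grows uniformly.

    The transformation is the cumulative distribution of the protophase,
    estimated through its Fourier coefficients ``S_n = <exp(-i n theta)>``:

        phi(theta) = theta + sum_{n!=0} S_n / (i n) * (exp(i n theta) - 1)

    It is 2*pi-periodic up to the identity (``phi(theta + 2*pi) =
    phi(theta) + 2*pi``), satisfies ``phi(0) = 0``, and is monotone for a
    positive density.  Harmonics with ``|S_n|`` below
    ``amplitude_threshold`` are dropped.  ``theta`` may be wrapped or
    unwrapped; the unwrapped input must cover at least ``min_cycles``
    cycles for a usable density estimate.
    """
    theta = np.asarray(theta, dtype=float)
    span = np.ptp(np.unwrap(theta) if np.ptp(theta) < TWO_PI * 1.5 else theta)
    if span < min_cycles * TWO_PI:
        raise ValueError(
            f"protophase covers only {span / TWO_PI:.1f} cycles; "
            f"at least {min_cycles} are needed -- provide a longer record"
        )
    phi = theta.astype(float).copy()
    for n in range(1, n_harmonics + 1):
        S_n = np.mean(np.exp(-1j * n * theta))
        if abs(S_n) < amplitude_threshold:
            continue
        term = (S_n / (1j * n)) * (np.exp(1j * n * theta) - 1.0)
        phi += 2.0 * term.real
    return phi
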