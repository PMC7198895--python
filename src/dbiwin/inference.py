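"""Sequential dynamical Bayesian inference for two coupled phase oscillators.

The observed phases are modelled as

    dphi_i/dt = sum_k c_k^i  Phi_{i,k}(phi_i, phi_j) + xi_i(t),   i = 1, 2

where the base functions ``Phi_{i,k}`` are a finite Fourier expansion on the
two-torus (constant term first, so ``c_0^i`` is the natural frequency
``omega_i``) and ``xi_i`` is white Gaussian noise with diagonal covariance
``E``.  The record is split into consecutive, non-overlapping blocks of
length ``t_w``; within each block the posterior over the parameter vector
``c`` is obtained by iterating the stationary-point equations of the
Gaussian posterior:

1. noise matrix from the residuals of the finite-difference phase
   velocities against the current model, scaled by the sampling step ``h``;
2. concentration (inverse covariance) matrix = prior concentration + data
   term ``(h / E_ii) * Phi^T Phi``;
3. parameter mean from the concentration-weighted normal equations,
   including the prior pull and the Ito drift correction
   ``-(h/2) * sum_n dPhi/dphi_i``.

Between blocks the posterior is propagated: means are carried forward
unchanged while the covariance is widened by a diagonal diffusion matrix
with entries ``(p_w * c_i)**2`` -- the propagation parameter ``p_w`` encodes
how much parameter variability the inference should be able to follow.

With a flat prior and vanishing noise the update collapses to ordinary
least squares of the finite-difference velocities on the basis, which is
the independent oracle the unit tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "FourierModel",
    "ModelState",
    "InferenceSettings",
    "InferenceRun",
    "SingularModelError",
    "evaluate_basis",
    "infer_block",
    "propagate_prior",
    "quadrature_covariance",
    "run_sequential",
]


#: blocks whose concentration matrix is conditioned worse than this are
#: rejected as singular: with reciprocal condition below sqrt(machine eps)
#: roughly half the mantissa is lost and the solved parameters are
#: numerically meaningless
RCOND_MIN = float(np.sqrt(np.finfo(float).eps))


class SingularModelError(RuntimeError):
    """Raised when a block's concentration matrix is singular.

    This is the failure mode of too-short blocks: the data term
    ``Phi^T Phi`` is rank-deficient (or numerically so) and the posterior
    cannot be formed.  The window optimizer uses this signal to find the
    smallest feasible block length.
    """


# --------------------------------------------------------------------------
# basis
# --------------------------------------------------------------------------


def _lattice(order: int) -> list[tuple[int, int]]:
    """Half-lattice of Fourier wavenumbers (k, s), excluding (0, 0).

    ``k`` multiplies the oscillator's own phase, ``s`` the partner's.  Only
    one of each +/- pair is kept (s > 0, or s == 0 and k > 0): the other is
    redundant for real sin/cos pairs.
    """
    pairs = []
    for s in range(0, order + 1):
        for k in range(-order, order + 1):
            if s > 0 or k > 0:
                pairs.append((k, s))
    return pairs


@dataclass(frozen=True)
class FourierModel:
    """Fourier basis descriptor shared by every inference operation.

    For oscillator ``i`` with own phase ``phi_i`` and partner phase
    ``phi_j`` the base functions are, in fixed order::

        1,  cos(k*phi_i + s*phi_j),  sin(k*phi_i + s*phi_j)   for (k, s)
        in the canonical half-lattice of order K.

    The constant term appears exactly once per oscillator and its
    coefficient is the oscillator's natural frequency.  Terms with
    ``s != 0`` depend on the partner's phase and form the *coupling
    subvector* used by :mod:`dbiwin.coupling_analysis`.
    """

    order: int = 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return _lattice(self.order)

    @property
    def n_params(self) -> int:
        """Number of base functions per oscillator (constant included)."""
        return 1 + 2 * len(self.pairs)

    @property
    def n_total(self) -> int:
        """Length of the joint parameter vector (both oscillators)."""
        return 2 * self.n_params

    def term_labels(self) -> list[str]:
        """Human-readable labels, one per base function of one oscillator."""
        labels = ["const"]
        for k, s in self.pairs:
            labels.append(f"cos({k}a{s:+d}b)")
            labels.append(f"sin({k}a{s:+d}b)")
        return labels

    def term_index(self, kind: str, k: int = 0, s: int = 0) -> int:
        """Index of a base function within one oscillator's subvector.

        ``kind`` is ``"const"``, ``"cos"`` or ``"sin"``; (k, s) are the
        wavenumbers on (own, partner) phase.  Sign-flipped pairs map to the
        stored representative (sin picks up the sign, cos does not -- the
        caller must fold it into the coefficient if needed).
        """
        if kind == "const":
            return 0
        if (k, s) not in self.pairs:
            if (-k, -s) in self.pairs:
                k, s = -k, -s
            else:
                raise KeyError(f"({k}, {s}) not in basis of order {self.order}")
        base = 1 + 2 * self.pairs.index((k, s))
        return base if kind == "cos" else base + 1

    def coupling_indices(self) -> np.ndarray:
        """Within-oscillator indices of terms that depend on the partner."""
        idx = []
        for n, (k, s) in enumerate(self.pairs):
            if s != 0:
                idx.extend([1 + 2 * n, 2 + 2 * n])
        return np.asarray(idx, dtype=int)

    def global_index(self, oscillator: int, local_index: int) -> int:
        """Map (oscillator in {1, 2}, within-oscillator index) to the joint vector."""
        if oscillator not in (1, 2):
            raise ValueError("oscillator must be 1 or 2")
        return (oscillator - 1) * self.n_params + local_index


def evaluate_basis(
    phi_own: np.ndarray, phi_partner: np.ndarray, model: FourierModel
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the base functions and their own-phase derivatives.

    Returns ``(Phi, dPhi)`` of shape (n, n_params): the design matrix and
    ``dPhi[:, l] = d Phi_l / d phi_own``, both needed by the block update
    (the derivative enters the Ito drift correction).  Phases may be
    wrapped or unwrapped; only their values mod 2*pi matter.
    """
    phi_own = np.asarray(phi_own, dtype=float)
    phi_partner = np.asarray(phi_partner, dtype=float)
    if phi_own.shape != phi_partner.shape:
        raise ValueError("phase arrays must have the same length")
    n = phi_own.shape[0]
    L = model.n_params
    Phi = np.empty((n, L))
    dPhi = np.zeros((n, L))
    Phi[:, 0] = 1.0
    for m, (k, s) in enumerate(model.pairs):
        arg = k * phi_own + s * phi_partner
        c, sn = np.cos(arg), np.sin(arg)
        j = 1 + 2 * m
        Phi[:, j] = c
        Phi[:, j + 1] = sn
        dPhi[:, j] = -k * sn
        dPhi[:, j + 1] = k * c
    return Phi, dPhi


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------


@dataclass
class ModelState:
    """Posterior (or prior) summary of one inference block.

    ``c`` concatenates both oscillators' parameter subvectors; ``E`` is the
    2x2 noise matrix (off-diagonals fixed at zero); ``Xi`` and ``Sigma``
    are the joint concentration and covariance matrices (block-diagonal
    across oscillators).  ``block_time`` is the block's mid-time in
    seconds.
    """

    c: np.ndarray
    E: np.ndarray
    Xi: np.ndarray
    Sigma: np.ndarray
    block_time: float = 0.0
    converged: bool = True

    def per_oscillator(self, model: FourierModel, oscillator: int) -> np.ndarray:
        """Parameter subvector of one oscillator (view)."""
        L = model.n_params
        lo = (oscillator - 1) * L
        return self.c[lo : lo + L]


@dataclass(frozen=True)
class InferenceSettings:
    """Knobs of the sequential inference.

    t_w : block length in seconds (sets the time resolution of c(t)).
    p_w : propagation parameter; each parameter's prior standard deviation
          is widened by ``p_w * c_i`` between blocks.
    order : Fourier order K of the basis (default 2).
    tol / max_iter : convergence of the within-block recursion (relative
          change of the parameter vector).
    prior_precision : concentration of the flat first-block prior.
    """

    t_w: float
    p_w: float
    order: int = 2
    tol: float = 1e-6
    max_iter: int = 100
    prior_precision: float = 1e-8

    def __post_init__(self) -> None:
        if self.t_w <= 0:
            raise ValueError("t_w must be positive")
        if self.p_w < 0:
            raise ValueError("p_w must be nonnegative")

    @property
    def model(self) -> FourierModel:
        return FourierModel(order=self.order)


@dataclass
class InferenceRun:
    """Result of a sequential inference: one ModelState per block."""

    states: list[ModelState]
    settings: InferenceSettings
    q_sigma: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def block_times(self) -> np.ndarray:
        return np.array([s.block_time for s in self.states])

    def parameter_series(self) -> np.ndarray:
        """Block-wise parameter matrix, shape (n_blocks, n_total)."""
        return np.array([s.c for s in self.states])

    def noise_series(self) -> np.ndarray:
        """Block-wise noise diagonal sqrt(E_ii), shape (n_blocks, 2)."""
        return np.array([np.sqrt(np.diag(s.E)) for s in self.states])


def flat_prior(model: FourierModel, precision: float = 1e-8) -> ModelState:
    """Non-informative prior: zero mean, tiny concentration."""
    n = model.n_total
    return ModelState(
        c=np.zeros(n),
        E=np.zeros((2, 2)),
        Xi=np.eye(n) * precision,
        Sigma=np.eye(n) / precision,
    )


def quadrature_covariance(Sigma: np.ndarray) -> float:
    """Quadrature covariance Q_Sigma = sum of squares of all elements.

    A scalar quality indicator of one block's inference: minimizing it
    minimizes the standard deviations of the inferred parameters.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise ValueError("Sigma must be a square matrix")
    return float(np.sum(Sigma**2))


# --------------------------------------------------------------------------
# block update
# --------------------------------------------------------------------------


def _spd_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(A), b)
    except (LinAlgError, ValueError) as exc:
        raise SingularModelError(f"singular concentration matrix: {exc}") from exc


def _spd_inverse(A: np.ndarray) -> np.ndarray:
    return _spd_solve(A, np.eye(A.shape[0]))


def infer_block(
    phases_block: tuple[np.ndarray, np.ndarray],
    prior: ModelState,
    settings: InferenceSettings,
    h: float,
    block_time: float = 0.0,
) -> ModelState:
    """One block of dynamical Bayesian inference.

    ``phases_block`` holds the two unwrapped phase arrays of the block
    (including the closing sample, so n samples give n-1 velocity points).
    The prior carries the previous block's propagated state; use
    :func:`flat_prior` for the first block.
    """
    phi1, phi2 = (np.asarray(p, dtype=float) for p in phases_block)
    if phi1.shape != phi2.shape or phi1.ndim != 1:
        raise ValueError("phases_block must be two equal-length 1-D arrays")
    model = settings.model
    L = model.n_params
    if phi1.size - 1 < 4 * L:
        raise SingularModelError(
            f"block of {phi1.size - 1} velocity samples is below the "
            f"singular-risk floor of 4 x {L} base functions"
        )
    dots = (np.diff(phi1) / h, np.diff(phi2) / h)
    mid1 = 0.5 * (phi1[1:] + phi1[:-1])
    mid2 = 0.5 * (phi2[1:] + phi2[:-1])
    designs = (
        evaluate_basis(mid1, mid2, model),
        evaluate_basis(mid2, mid1, model),
    )
    prep = []
    for (Phi, dPhi), dot in zip(designs, dots):
        prep.append(
            {
                "G": Phi.T @ Phi,
                "b": Phi.T @ dot,
                "v": 0.5 * h * dPhi.sum(axis=0),
                "Phi": Phi,
                "dot": dot,
            }
        )

    c = prior.c.copy()
    E = np.zeros((2, 2))
    Xi = np.zeros_like(prior.Xi)
    converged = False
    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(settings.max_iter):
            c_old = c.copy()
            for i, p in enumerate(prep):
                lo = i * L
                sl = slice(lo, lo + L)
                r = p["dot"] - p["Phi"] @ c[sl]
                Eii = h * float(np.mean(r * r))
                if not np.isfinite(Eii):
                    raise SingularModelError("noise estimate diverged")
                Eii = max(Eii, 1e-300)
                E[i, i] = Eii
                Xi_prior_i = prior.Xi[sl, sl]
                Xi_i = Xi_prior_i + (h / Eii) * p["G"]
                if it == 0:
                    ev = np.linalg.eigvalsh(Xi_i)
                    if ev[0] <= 0 or ev[0] / ev[-1] < RCOND_MIN:
                        raise SingularModelError(
                            "concentration matrix conditioned worse than "
                            f"{RCOND_MIN:.1e}: window too short for the basis"
                        )
                rhs = Xi_prior_i @ prior.c[sl] + (h / Eii) * p["b"] - p["v"]
                c[sl] = _spd_solve(Xi_i, rhs)
                Xi[sl, sl] = Xi_i
            if not np.all(np.isfinite(c)):
                raise SingularModelError("non-finite parameters in block update")
            delta = np.linalg.norm(c - c_old) / (np.linalg.norm(c_old) + 1e-12)
            if delta < settings.tol:
                converged = True
                break

    Sigma = np.zeros_like(Xi)
    for i in range(2):
        sl = slice(i * L, (i + 1) * L)
        Sigma[sl, sl] = _spd_inverse(Xi[sl, sl])
    return ModelState(
        c=c, E=E, Xi=Xi, Sigma=Sigma, block_time=block_time, converged=converged
    )


def propagate_prior(post: ModelState, settings: InferenceSettings) -> ModelState:
    """Turn a block posterior into the next block's prior.

    The parameter means are carried forward unchanged; the covariance is
    widened by the diagonal diffusion matrix ``diag((p_w * c_i)**2)``
    (uncorrelated parameter diffusion), and the concentration matrix is
    recomputed as its inverse.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        Sigma_prior = post.Sigma + np.diag((settings.p_w * post.c) ** 2)
    if not np.all(np.isfinite(Sigma_prior)):
        raise SingularModelError("propagated covariance diverged")
    model = settings.model
    L = model.n_params
    Xi_prior = np.zeros_like(Sigma_prior)
    for i in range(2):
        sl = slice(i * L, (i + 1) * L)
        Xi_prior[sl, sl] = _spd_inverse(Sigma_prior[sl, sl])
    return replace(post, Sigma=Sigma_prior, Xi=Xi_prior)


# --------------------------------------------------------------------------
# sequential driver
# --------------------------------------------------------------------------


def run_sequential(phases, settings: InferenceSettings) -> InferenceRun:
    """Chain block inference and prior propagation over a whole record.

    ``phases`` is a :class:`~dbiwin.simulators.PhasePairSeries` (or any
    object with ``time``, ``phi1``, ``phi2`` and ``h`` attributes).  The
    record is split into ``floor(duration / t_w)`` consecutive blocks; the
    posterior of each block, diffused by ``p_w``, seeds the next.  Block
    errors are re-raised with the block index for context.
    """
    h = float(phases.h)
    n_block = int(round(settings.t_w / h))
    if n_block < 1:
        raise ValueError("t_w shorter than one sampling step")
    n_vel = len(phases.phi1) - 1
    n_blocks = n_vel // n_block
    if n_blocks < 2:
        raise ValueError("series must cover at least two blocks of length t_w")
    model = settings.model
    prior = flat_prior(model, settings.prior_precision)
    states: list[ModelState] = []
    q = np.empty(n_blocks)
    t0 = float(phases.time[0])
    for b in range(n_blocks):
        lo = b * n_block
        sl = slice(lo, lo + n_block + 1)
        mid = t0 + (lo + 0.5 * n_block) * h
        try:
            post = infer_block(
                (phases.phi1[sl], phases.phi2[sl]),
                prior,
                settings,
                h,
                block_time=mid,
            )
        except SingularModelError as exc:
            raise SingularModelError(f"block {b}: {exc}") from exc
        states.append(post)
        q[b] = quadrature_covariance(post.Sigma)
        if b < n_blocks - 1:
            prior = propagate_prior(post, settings)
    return InferenceRun(states=states, settings=settings, q_sigma=q)
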