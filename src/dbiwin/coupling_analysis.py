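"""Post-inference coupling quantification.

From each block's parameter vector the *coupling subvector* -- the
coefficients of base functions that depend on the partner oscillator's
phase -- yields three quantities:

* the coupling function ``q_i(phi_i, phi_j)`` evaluated on a wrapped
  2*pi x 2*pi grid (:func:`coupling_surface`);
* the coupling strength ``CPL_i`` = Euclidean norm of the subvector
  (:func:`coupling_strength`);
* the similarity index ``rho`` = Pearson correlation between two coupling
  subvectors, which compares the *shape* of two coupling functions
  irrespective of their amplitude (:func:`similarity_index`).

:func:`time_resolved_similarity` applies these per block, comparing each
block's coupling function against the time-averaged one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FourierModel, InferenceRun, ModelState, evaluate_basis

__all__ = [
    "CouplingSurface",
    "CouplingTimeSeries",
    "coupling_surface",
    "coupling_strength",
    "similarity_index",
    "time_resolved_similarity",
    "coupling_subvector",
]

TWO_PI = 2.0 * np.pi


@dataclass
class CouplingSurface:
    """Coupling function values on a wrapped phase grid.

    ``values[m, n] = q_i(phi_own[m], phi_partner[n])``; both axes cover
    [0, 2*pi) so the surface is periodic across each seam.
    """

    phi_own: np.ndarray
    phi_partner: np.ndarray
    values: np.ndarray
    oscillator: int
    block_time: float = 0.0


@dataclass
class CouplingTimeSeries:
    """Block-wise coupling strength and shape similarity, per direction.

    ``rho_1`` compares each block's 2->1 coupling function with the
    time-averaged one; ``rho_2`` likewise for 1->2.
    """

    block_times: np.ndarray
    cpl_1: np.ndarray
    cpl_2: np.ndarray
    rho_1: np.ndarray
    rho_2: np.ndarray
    mean_coupling_1: np.ndarray
    mean_coupling_2: np.ndarray


def coupling_subvector(
    c: np.ndarray, model: FourierModel, oscillator: int
) -> np.ndarray:
    """Coefficients of the partner-dependent base functions of one oscillator."""
    L = model.n_params
    lo = (oscillator - 1) * L
    return np.asarray(c)[lo : lo + L][model.coupling_indices()]


def coupling_surface(
    state: ModelState,
    model: FourierModel,
    oscillator: int,
    resolution: int = 100,
) -> CouplingSurface:
    """Evaluate ``q_i`` from the coupling-related basis terms on a grid.

    Constant and self terms are excluded: the surface shows only the
    influence of the partner oscillator's phase.
    """
    if resolution < 8:
        raise ValueError("grid resolution below 8 is not meaningful")
    idx = model.coupling_indices()
    L = model.n_params
    c_full = state.c[(oscillator - 1) * L : oscillator * L]
    phi = np.arange(resolution) * TWO_PI / resolution
    own, partner = np.meshgrid(phi, phi, indexing="ij")
    Phi, _ = evaluate_basis(own.ravel(), partner.ravel(), model)
    values = (Phi[:, idx] @ c_full[idx]).reshape(resolution, resolution)
    return CouplingSurface(
        phi_own=phi,
        phi_partner=phi,
        values=values,
        oscillator=oscillator,
        block_time=state.block_time,
    )


def coupling_strength(
    state_or_c, model: FourierModel, oscillator: int
) -> float:
    """Euclidean norm of the coupling subvector (CPL_i)."""
    c = state_or_c.c if isinstance(state_or_c, ModelState) else state_or_c
    return float(np.linalg.norm(coupling_subvector(c, model, oscillator)))


def similarity_index(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two coupling-parameter vectors.

    Measures similarity of coupling-function *form*: invariant to positive
    rescaling of either vector.  A zero-variance vector has no defined
    shape, so it is rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coupling vectors must be 1-D and equally long")
    da = a - a.mean()
    db = b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("similarity undefined for a zero-variance vector")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def time_resolved_similarity(run: InferenceRun) -> CouplingTimeSeries:
    """CPL_i(t) and rho_i(t) against the time-averaged coupling function.

    The time-averaged coupling function is the mean coupling-parameter
    vector over all blocks (by linearity of the basis expansion this
    equals averaging the surfaces).  Each block's rho compares its
    coupling subvector with that mean, separately per direction.
    """
    if len(run.states) < 3:
        raise ValueError("need at least 3 blocks for a time-resolved similarity")
    model = run.settings.model
    C = run.parameter_series()
    times = run.block_times
    subs = {
        osc: np.array([coupling_subvector(c, model, osc) for c in C])
        for osc in (1, 2)
    }
    means = {osc: subs[osc].mean(axis=0) for osc in (1, 2)}
    cpl = {osc: np.linalg.norm(subs[osc], axis=1) for osc in (1, 2)}
    rho = {}
    for osc in (1, 2):
        rho[osc] = np.array(
            [similarity_index(v, means[osc]) for v in subs[osc]]
        )
    return CouplingTimeSeries(
        block_times=times,
        cpl_1=cpl[1],
        cpl_2=cpl[2],
        rho_1=rho[1],
        rho_2=rho[2],
        mean_coupling_1=means[1],
        mean_coupling_2=means[2],
    )
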