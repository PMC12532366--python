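"""Two-qubit state tomography from 16 coincidence projections.

A tomography set is 16 coincidence counts taken with the signal and
idler analyzers each set to one of the six polarization eigenstates
(H, V, D, A, R, L).  Any informationally complete list of 16 settings is
accepted; completeness is verified at runtime through the rank of the
flattened projector design matrix.  The canonical list is the product
{H, V, D, R} ⊗ {H, V, D, R}, which covers all three mutually unbiased
single-qubit bases.

Two reconstructions are provided:

``linear_inversion``
    Solves the linear Born-rule system counts_k = N·Tr(ρ P_k) exactly.
    Fast and unbiased, but with noisy counts the result may have
    (slightly) negative eigenvalues.

``mle_reconstruct``
    Maximum-likelihood refinement over the physical manifold
    ρ = T†T / Tr(T†T), with T lower-triangular (16 real parameters).
    The overall scale of T absorbs the unknown total flux, so the
    Poisson likelihood is optimized without a separate rate nuisance
    parameter.  Initialized from the eigenvalue-clipped linear
    inversion.  This is the default reconstruction in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize

from .states import ANALYZER_LABELS, projector

__all__ = [
    "AnalyzerSetting",
    "TomographyProjection",
    "TomographySet",
    "canonical_settings",
    "design_matrix",
    "linear_inversion",
    "mle_reconstruct",
    "MLEConvergenceError",
    "loglikelihood",
]

logger = logging.getLogger(__name__)


class AnalyzerSetting(NamedTuple):
    """One projective setting: (signal analyzer, idler analyzer)."""

    signal: str
    idler: str


@dataclass(frozen=True)
class TomographyProjection:
    """One measured projection: setting, coincidence counts, integration time."""

    setting: AnalyzerSetting
    counts: float
    integration_time: float = 1.0

    def __post_init__(self) -> None:
        sig, idl = self.setting
        if sig not in ANALYZER_LABELS or idl not in ANALYZER_LABELS:
            raise ValueError(f"invalid analyzer setting {self.setting}")
        if self.counts < 0:
            raise ValueError("counts must be nonnegative")
        if self.integration_time <= 0:
            raise ValueError("integration time must be positive")


@dataclass
class TomographySet:
    """An informationally complete set of 16 measured projections."""

    projections: Sequence[TomographyProjection]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.projections = list(self.projections)
        if len(self.projections) != 16:
            raise ValueError(
                f"tomography set needs exactly 16 projections, got {len(self.projections)}"
            )
        if np.linalg.matrix_rank(design_matrix(self.settings), tol=1e-8) != 16:
            raise ValueError(
                "settings are not informationally complete (design rank < 16)"
            )

    @property
    def settings(self) -> list[AnalyzerSetting]:
        return [p.setting for p in self.projections]

    @property
    def counts(self) -> np.ndarray:
        return np.array([p.counts for p in self.projections], dtype=float)

    @property
    def integration_times(self) -> np.ndarray:
        return np.array([p.integration_time for p in self.projections], dtype=float)


def canonical_settings() -> list[AnalyzerSetting]:
    """The default 16 analyzer settings: {H, V, D, R} ⊗ {H, V, D, R}."""
    return [AnalyzerSetting(s, i) for s, i in product("HVDR", repeat=2)]


_PROJECTOR_CACHE: dict[tuple, np.ndarray] = {}


def _projectors(settings: Sequence[AnalyzerSetting]) -> np.ndarray:
    key = tuple((s, i) for s, i in settings)
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = np.stack([projector(s, i) for s, i in settings])
    return _PROJECTOR_CACHE[key]


def design_matrix(settings: Sequence[AnalyzerSetting]) -> np.ndarray:
    """16×16 matrix A with A[k] = vec(P_kᵀ), so that A·vec(ρ) = Tr(ρ P_k)."""
    return _projectors(settings).transpose(0, 2, 1).reshape(len(settings), 16)


def _hermitize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.conj().T)


def linear_inversion(ts: TomographySet, subtract_accidentals_hz: float | None = None):
    """Linear (unconstrained) reconstruction of ρ from a tomography set.

    Solves counts_k = Tr(ρ̃ P_k) for the unnormalized ρ̃, then Hermitizes
    and normalizes the trace.  Exact on noiseless data; with counting
    noise the output may fail positive semidefiniteness (by design —
    pass it to :func:`mle_reconstruct` for a physical estimate).

    ``subtract_accidentals_hz`` optionally removes an accidental-rate
    background (rate × integration time, floored at zero counts) before
    inversion.
    """
    counts = ts.counts
    if subtract_accidentals_hz is not None:
        counts = np.maximum(counts - subtract_accidentals_hz * ts.integration_times, 0.0)
    if counts.sum() <= 0:
        raise ValueError("cannot invert an all-zero tomography set")
    A = design_matrix(ts.settings)
    rho_flat = np.linalg.solve(A, counts.astype(complex))
    rho = _hermitize(rho_flat.reshape(4, 4))
    tr = np.trace(rho).real
    if tr <= 0:
        raise ValueError("linear inversion produced a nonpositive trace")
    return rho / tr


def _clip_psd(rho: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Project onto the PSD cone by clipping eigenvalues, keeping trace 1.

    Degenerate eigenvalues keep their eigh ordering (ascending eigenvalue,
    then original index), making the projection deterministic.
    """
    vals, vecs = np.linalg.eigh(_hermitize(rho))
    vals = np.clip(vals, floor, None)
    s = vals.sum()
    if s <= 0:
        return np.eye(4) / 4.0
    vals = vals / s
    return (vecs * vals) @ vecs.conj().T


class MLEConvergenceError(RuntimeError):
    """MLE failed to converge; ``best_rho`` carries the best iterate found."""

    def __init__(self, message: str, best_rho: np.ndarray):
        super().__init__(message)
        self.best_rho = best_rho


def _t_to_matrix(params: np.ndarray) -> np.ndarray:
    """Map 16 real parameters to a lower-triangular complex 4×4 T."""
    T = np.zeros((4, 4), dtype=complex)
    T[np.diag_indices(4)] = params[:4]
    rows, cols = np.tril_indices(4, k=-1)
    T[rows, cols] = params[4:10] + 1j * params[10:16]
    return T


def _matrix_to_t_params(T: np.ndarray) -> np.ndarray:
    params = np.empty(16)
    params[:4] = T[np.diag_indices(4)].real
    rows, cols = np.tril_indices(4, k=-1)
    params[4:10] = T[rows, cols].real
    params[10:16] = T[rows, cols].imag
    return params


def _t_from_rho(rho: np.ndarray, scale: float) -> np.ndarray:
    """Lower-triangular T with T†T = scale·ρ (reverse-order Cholesky)."""
    R = np.eye(4)[::-1]
    Lr = np.linalg.cholesky(R @ (scale * rho) @ R)
    return (R @ Lr @ R).conj().T


def loglikelihood(
    rho: np.ndarray,
    ts: TomographySet,
    total: float | None = None,
    accidental_hz: float | None = None,
) -> float:
    """Poisson log-likelihood (up to the counts! constant) of ρ for a set.

    ``total`` is the expected number of pairs per projection window; when
    omitted it is profiled analytically from the data.
    """
    A = design_matrix(ts.settings)
    probs = np.maximum((A @ rho.reshape(16)).real, 1e-15)
    counts = ts.counts
    acc = (accidental_hz or 0.0) * ts.integration_times
    if total is None:
        total = counts.sum() / probs.sum()
    mu = np.maximum(total * probs + acc, 1e-15)
    return float(np.sum(counts * np.log(mu) - mu))


def mle_reconstruct(
    ts: TomographySet,
    init: np.ndarray | None = None,
    subtract_accidentals_hz: float | None = None,
    likelihood: str = "poisson",
    max_iter: int = 2000,
    gtol: float = 1e-8,
    ftol: float = 1e-12,
) -> np.ndarray:
    """Maximum-likelihood physical density matrix for a tomography set.

    Optimizes the Poisson count likelihood over ρ = T†T / Tr(T†T) with T
    lower-triangular; the free scale of T absorbs the total flux.  The
    returned matrix is Hermitian, unit trace and PSD up to round-off.

    Parameters
    ----------
    init
        Optional starting density matrix; defaults to the eigenvalue-
        clipped linear inversion of the same data.
    subtract_accidentals_hz
        Optional accidental-coincidence rate to subtract from the counts
        (floored at zero) before fitting; off by default.
    likelihood
        "poisson" (default) or "gaussian" (variance-weighted least
        squares approximation).

    Raises
    ------
    MLEConvergenceError
        If the optimizer stops without satisfying the gradient or
        relative-likelihood tolerance; the exception carries the best
        iterate as ``best_rho``.
    """
    if likelihood not in ("poisson", "gaussian"):
        raise ValueError("likelihood must be 'poisson' or 'gaussian'")
    counts = ts.counts
    if subtract_accidentals_hz is not None:
        counts = np.maximum(
            counts - subtract_accidentals_hz * ts.integration_times, 0.0
        )
    A = design_matrix(ts.settings)

    if init is None:
        init = _clip_psd(linear_inversion(ts, subtract_accidentals_hz), floor=1e-6)
    else:
        init = _clip_psd(init, floor=1e-6)
    total0 = max(counts.sum() / max((A @ init.reshape(16)).real.sum(), 1e-12), 1.0)
    x0 = _matrix_to_t_params(_t_from_rho(init, total0))

    w = 1.0 / np.maximum(counts, 1.0)  # gaussian weights
    P = _projectors(ts.settings)
    rows, cols = np.tril_indices(4, k=-1)
    diag = np.diag_indices(4)

    def objective(x: np.ndarray):
        T = _t_to_matrix(x)
        rho_un = T.conj().T @ T
        mu = np.maximum((A @ rho_un.reshape(16)).real, 1e-12)
        if likelihood == "poisson":
            f = float(np.sum(mu - counts * np.log(mu)))
            wk = 1.0 - counts / mu
        else:
            f = float(0.5 * np.sum(w * (mu - counts) ** 2))
            wk = w * (mu - counts)
        # Wirtinger gradient: d/dT̄ of Tr(T†T P_k) is T P_k
        G = T @ np.einsum("k,kab->ab", wk, P)
        grad = np.empty(16)
        grad[:4] = 2.0 * G[diag].real
        grad[4:10] = 2.0 * G[rows, cols].real
        grad[10:16] = 2.0 * G[rows, cols].imag
        return f, grad

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol, "maxfun": 10 * max_iter},
    )
    T = _t_to_matrix(res.x)
    rho_un = _hermitize(T.conj().T @ T)
    rho = rho_un / np.trace(rho_un).real
    grad_ok = np.max(np.abs(res.jac)) < 1e-4 if res.jac is not None else False
    converged = bool(res.success) or grad_ok
    logger.info(
        "MLE reconstruction: converged=%s nit=%d nll=%.6g", converged, res.nit, res.fun
    )
    if not converged:
        raise MLEConvergenceError(
            f"MLE did not converge after {res.nit} iterations: {res.message}", rho
        )
    return rho
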