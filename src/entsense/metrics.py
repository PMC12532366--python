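"""Entanglement metrics and the Werner tangle–entropy path.

For a two-qubit density matrix ρ the package reports:

concurrence
    C = max(0, λ₁ − λ₂ − λ₃ − λ₄) with λᵢ the square roots, in
    descending order, of the eigenvalues of ρ (σ_y⊗σ_y) ρ* (σ_y⊗σ_y).
tangle
    T = C².
linear entropy
    S_L = (4/3)(1 − Tr ρ²), normalized so S_L = 1 for the maximally
    mixed two-qubit state.
Werner probability estimate
    p̂ = clip((4F − 1)/3, 0, 1) with F the fidelity to the declared
    (or nearest) Bell state — exact inversion of F = (1 + 3p)/4 on the
    Werner family.

Along the Werner family these have closed forms
C(p) = max(0, (3p−1)/2), T(p) = C(p)², S_L(p) = 1 − p², which trace the
theoretical path in the (T, S) plane from (1, 0) at p = 1 to (0, 1) at
p = 0.  ``ts_deviation`` measures how far a measured (T, S) point falls
from that path (signed: positive above the curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .states import BELL_LABELS, fidelity, make_bell_state

__all__ = [
    "EntanglementSummary",
    "concurrence",
    "tangle",
    "linear_entropy",
    "purity",
    "werner_curve",
    "estimate_werner_p",
    "ts_deviation",
    "summarize",
]

_SY = np.array([[0.0, -1j], [1j, 0.0]])
_SYSY = np.kron(_SY, _SY)

#: eigenvalue floor before the square root in the concurrence (numerical
#: round-off only; far below count-noise scale)
_EIG_FLOOR = 1e-12


def _check_hermitian(rho: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    rho = np.asarray(rho, dtype=complex)
    if rho.shape != (4, 4):
        raise ValueError("expected a 4x4 density matrix")
    if np.max(np.abs(rho - rho.conj().T)) > atol:
        raise ValueError("density matrix is not Hermitian")
    return rho


def concurrence(rho: np.ndarray) -> float:
    """Wootters concurrence of a two-qubit density matrix, in [0, 1]."""
    rho = _check_hermitian(rho)
    m = rho @ _SYSY @ rho.conj() @ _SYSY
    vals = np.linalg.eigvals(m).real
    vals = np.sqrt(np.where(vals < _EIG_FLOOR, 0.0, vals))
    vals = np.sort(vals)[::-1]
    return float(max(0.0, vals[0] - vals[1] - vals[2] - vals[3]))


def tangle(rho: np.ndarray) -> float:
    """Tangle T = C² (square of the concurrence)."""
    return concurrence(rho) ** 2


def purity(rho: np.ndarray) -> float:
    """Tr ρ², in [1/4, 1] for a two-qubit state."""
    rho = _check_hermitian(rho)
    tr = np.trace(rho).real
    if abs(tr - 1.0) > 1e-6:
        raise ValueError(f"density matrix must have unit trace, got {tr}")
    return float(np.trace(rho @ rho).real)


def linear_entropy(rho: np.ndarray) -> float:
    """Linear entropy S_L = (4/3)(1 − Tr ρ²); 0 for pure, 1 for I/4."""
    return float(np.clip(4.0 / 3.0 * (1.0 - purity(rho)), 0.0, 1.0))


def _werner_ts(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = np.maximum(0.0, (3.0 * p - 1.0) / 2.0)
    return c**2, 1.0 - p**2


def werner_curve(p_grid) -> np.ndarray:
    """(T, S) pairs of the theoretical Werner path for the given p values.

    Returns an array of shape (n, 2) with columns (tangle, linear entropy).
    """
    p = np.atleast_1d(np.asarray(p_grid, dtype=float))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("Werner probabilities must lie in [0, 1]")
    t, s = _werner_ts(p)
    return np.column_stack([t, s])


def estimate_werner_p(rho: np.ndarray, bell: str | np.ndarray = "phi_plus",
                      nearest_bell: bool = False) -> float:
    """Estimate the Werner probability of a state.

    Inverts the Werner-family fidelity F = (1 + 3p)/4 against the
    declared target Bell state: p̂ = clip((4F − 1)/3, 0, 1).  With
    ``nearest_bell=True`` the fidelity is maximized over the four
    zero-phase Bell states instead of using the declaration.
    """
    if nearest_bell:
        f = max(fidelity(rho, make_bell_state(lbl)) for lbl in BELL_LABELS)
    else:
        target = make_bell_state(bell) if isinstance(bell, str) else np.asarray(bell)
        f = fidelity(rho, target)
    return float(np.clip((4.0 * f - 1.0) / 3.0, 0.0, 1.0))


def ts_deviation(t: float, s: float) -> float:
    """Signed Euclidean distance of a (T, S) point from the Werner path.

    Positive when the point lies above the curve (larger tangle than the
    Werner state of equal linear entropy), negative below.
    """
    if not (0.0 <= t <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError("tangle and linear entropy must lie in [0, 1]")

    def dist2(p: float) -> float:
        tc, sc = _werner_ts(np.asarray(p))
        return float((t - tc) ** 2 + (s - sc) ** 2)

    grid = np.linspace(0.0, 1.0, 401)
    tg, sg = _werner_ts(grid)
    d2 = (t - tg) ** 2 + (s - sg) ** 2
    i = int(np.argmin(d2))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 400)]
    res = minimize_scalar(
        dist2, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    # the bounded refinement can stall at an interior point when the
    # minimum sits on the curve endpoint; keep the best of all candidates
    d = float(np.sqrt(min(res.fun, d2[i], dist2(0.0), dist2(1.0))))
    # sign: compare tangle with the curve's tangle at equal linear entropy
    p_at_s = np.sqrt(max(0.0, 1.0 - s))
    t_curve = _werner_ts(np.asarray(p_at_s))[0]
    return d if t >= t_curve else -d


@dataclass(frozen=True)
class EntanglementSummary:
    """All metrics for one reconstructed density matrix."""

    concurrence: float
    tangle: float
    linear_entropy: float
    purity: float
    fidelity_to_bell: float
    werner_p_hat: float
    ts_deviation: float


def summarize(rho: np.ndarray, bell: str | np.ndarray = "phi_plus") -> EntanglementSummary:
    """Compute the full entanglement-metric panel for one state."""
    c = concurrence(rho)
    t = c**2
    s = linear_entropy(rho)
    target = make_bell_state(bell) if isinstance(bell, str) else np.asarray(bell)
    f = fidelity(rho, target)
    return EntanglementSummary(
        concurrence=c,
        tangle=t,
        linear_entropy=s,
        purity=purity(rho),
        fidelity_to_bell=f,
        werner_p_hat=float(np.clip((4.0 * f - 1.0) / 3.0, 0.0, 1.0)),
        ts_deviation=ts_deviation(t, s),
    )
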