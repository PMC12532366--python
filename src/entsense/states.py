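"""Two-qubit polarization states.

The photon-pair source produces polarization-entangled Bell states
(|Φ±⟩ on the {HH, VV} subspace, |Ψ±⟩ on {HV, VH}).  Transmission through
a scattering medium is modeled as a Werner channel: the pure Bell state
is mixed with white noise,

    ρ_W(p) = p |ϕ⟩⟨ϕ| + (1 − p) I/4,

where p ∈ [0, 1] is the Werner probability (p = 1: no decoherence,
p = 0: maximally mixed).  All two-qubit operators use the computational
basis order (HH, HV, VH, VV), signal qubit first.

Circular-polarization handedness is fixed once for the whole package:
R ≡ (H − iV)/√2 and L ≡ (H + iV)/√2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BELL_LABELS",
    "ANALYZER_LABELS",
    "BellState",
    "WernerParams",
    "make_bell_state",
    "analyzer_vector",
    "make_werner_state",
    "projection_probability",
    "projector",
    "fidelity",
]

BELL_LABELS = ("phi_plus", "phi_minus", "psi_plus", "psi_minus")
ANALYZER_LABELS = ("H", "V", "D", "A", "R", "L")

_H = np.array([1.0, 0.0], dtype=complex)
_V = np.array([0.0, 1.0], dtype=complex)

#: Single-qubit analyzer eigenstates, fixed handedness R=(H-iV)/√2, L=(H+iV)/√2.
_ANALYZER_VECTORS = {
    "H": _H,
    "V": _V,
    "D": (_H + _V) / np.sqrt(2.0),
    "A": (_H - _V) / np.sqrt(2.0),
    "R": (_H - 1j * _V) / np.sqrt(2.0),
    "L": (_H + 1j * _V) / np.sqrt(2.0),
}


@dataclass(frozen=True)
class BellState:
    """A Bell state of the photon pair, with a relative phase.

    ``label`` is one of :data:`BELL_LABELS`; ``phase_phi`` is the relative
    phase (radians) between the two amplitudes, so that e.g.
    phi_plus with phase π lies on the same ray as phi_minus.
    """

    label: str
    phase_phi: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in BELL_LABELS:
            raise ValueError(
                f"unknown Bell label {self.label!r}; expected one of {BELL_LABELS}"
            )

    @property
    def vector(self) -> np.ndarray:
        return make_bell_state(self.label, self.phase_phi)


@dataclass(frozen=True)
class WernerParams:
    """Werner channel parameters: probability ``p`` and the target Bell state."""

    p: float
    bell: BellState = field(default_factory=lambda: BellState("phi_plus"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"Werner probability must lie in [0, 1], got {self.p}")


def make_bell_state(label: str, phase_phi: float = 0.0) -> np.ndarray:
    """Return the Bell-state vector in the (HH, HV, VH, VV) basis.

    |Φ±⟩ = (|HH⟩ ± e^{iφ}|VV⟩)/√2 and |Ψ±⟩ = (|HV⟩ ± e^{iφ}|VH⟩)/√2,
    with φ the relative phase of the second amplitude.
    """
    if label not in BELL_LABELS:
        raise ValueError(
            f"unknown Bell label {label!r}; expected one of {BELL_LABELS}"
        )
    sign = 1.0 if label.endswith("plus") else -1.0
    amp = sign * np.exp(1j * phase_phi) / np.sqrt(2.0)
    vec = np.zeros(4, dtype=complex)
    if label.startswith("phi"):
        vec[0] = 1.0 / np.sqrt(2.0)  # HH
        vec[3] = amp  # VV
    else:
        vec[1] = 1.0 / np.sqrt(2.0)  # HV
        vec[2] = amp  # VH
    return vec


def analyzer_vector(label: str) -> np.ndarray:
    """Single-qubit state vector for one of the six analyzer eigenstates."""
    try:
        return _ANALYZER_VECTORS[label].copy()
    except KeyError:
        raise ValueError(
            f"unknown analyzer label {label!r}; expected one of {ANALYZER_LABELS}"
        ) from None


def _as_bell_vector(bell) -> np.ndarray:
    if isinstance(bell, BellState):
        return bell.vector
    if isinstance(bell, str):
        return make_bell_state(bell)
    vec = np.asarray(bell, dtype=complex)
    if vec.shape != (4,):
        raise ValueError("Bell state must be a label, BellState, or length-4 vector")
    norm = np.linalg.norm(vec)
    if not np.isclose(norm, 1.0, atol=1e-9):
        raise ValueError(f"Bell state vector must have unit norm, got {norm}")
    return vec


def make_werner_state(params_or_p, bell="phi_plus") -> np.ndarray:
    """Build the Werner density matrix ρ = p|ϕ⟩⟨ϕ| + (1−p) I/4.

    Accepts either a :class:`WernerParams` or a bare probability plus a
    Bell-state designation (label, :class:`BellState` or vector).
    """
    if isinstance(params_or_p, WernerParams):
        p = params_or_p.p
        vec = params_or_p.bell.vector
    else:
        p = float(params_or_p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"Werner probability must lie in [0, 1], got {p}")
        vec = _as_bell_vector(bell)
    return p * np.outer(vec, vec.conj()) + (1.0 - p) * np.eye(4) / 4.0


def projector(signal_label: str, idler_label: str) -> np.ndarray:
    """Two-qubit projector P_s ⊗ P_i for a pair of analyzer settings."""
    vs = analyzer_vector(signal_label)
    vi = analyzer_vector(idler_label)
    v = np.kron(vs, vi)
    return np.outer(v, v.conj())


def _check_density(rho: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    rho = np.asarray(rho, dtype=complex)
    if rho.shape != (4, 4):
        raise ValueError(f"density matrix must be 4x4, got shape {rho.shape}")
    tr = np.trace(rho).real
    if abs(tr - 1.0) > atol:
        raise ValueError(f"density matrix must have unit trace, got {tr}")
    return rho


def projection_probability(rho: np.ndarray, setting) -> float:
    """Born-rule probability Tr(ρ P_s ⊗ P_i) of a coincidence projection.

    ``setting`` is any pair of analyzer labels, e.g. ``("H", "V")`` or an
    :class:`~entsense.tomography.AnalyzerSetting`.
    """
    rho = _check_density(rho)
    signal, idler = setting
    p = float(np.trace(rho @ projector(signal, idler)).real)
    # clip numerical round-off just outside [0, 1]
    return min(max(p, 0.0), 1.0)


def fidelity(rho: np.ndarray, target: np.ndarray) -> float:
    """Fidelity ⟨ψ|ρ|ψ⟩ of a state ρ with a pure target |ψ⟩."""
    rho = _check_density(rho)
    target = np.asarray(target, dtype=complex)
    norm = np.linalg.norm(target)
    if not np.isclose(norm, 1.0, atol=1e-9):
        raise ValueError(f"target state must have unit norm, got {norm}")
    val = float(np.real(target.conj() @ rho @ target))
    return min(max(val, 0.0), 1.0)
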