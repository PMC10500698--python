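"""Minimal liquid-state spin-system simulation.

Generates a species' signature peak table from isotropic chemical shifts and
scalar J couplings, so field-dependent multiplets (first-order doublets and
quartets, strong-coupling "roof" patterns) can be produced at any
spectrometer frequency.

The Hamiltonian, in Hz in the rotating frame,

    H/2π = Σ_i ν_i I_z,i + Σ_{i<j} J_ij I_i·I_j,    ν_i = B0·δ_i,

is diagonalised densely in the 2^N product basis (N ≤ 10).  Single-quantum
transition frequencies are eigenvalue differences; intensities are
``|⟨b| Σ_i I⁻_i |a⟩|²``, normalised so they sum to the number of spins
(the sum rule Tr{I⁺I⁻} = N·2^{N−1}).  Relaxation is not part of the
Hamiltonian: one user-supplied decay rate α is attached to every transition.

Equivalent-spin groups are expanded literally (CH3 = three spins with equal
shifts), the simplest correct treatment at this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .signatures import Peak, Signature

__all__ = ["SpinSystem", "spin_signature"]

_SIGMA_Z = np.array([[0.5, 0.0], [0.0, -0.5]])
_SIGMA_P = np.array([[0.0, 1.0], [0.0, 0.0]])  # I+ = |α⟩⟨β| raises m by 1
_SIGMA_M = _SIGMA_P.T
_SIGMA_X = 0.5 * (_SIGMA_P + _SIGMA_M)
_SIGMA_Y = -0.5j * (_SIGMA_P - _SIGMA_M)


def _single_spin_op(op: np.ndarray, i: int, n: int) -> np.ndarray:
    """Embed a one-spin operator at position i in the 2^n product space."""
    mat = np.eye(1)
    for j in range(n):
        mat = np.kron(mat, op if j == i else np.eye(2))
    return mat


@dataclass(frozen=True)
class SpinSystem:
    """Isotropic shifts (ppm) and a symmetric J-coupling matrix (Hz)."""

    species_name: str
    shifts: np.ndarray
    couplings: np.ndarray

    def __post_init__(self) -> None:
        shifts = np.atleast_1d(np.asarray(self.shifts, dtype=float))
        J = np.asarray(self.couplings, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "couplings", J)
        n = shifts.size
        if n > 10:
            raise ValueError(
                f"{n} spins exceeds the dense-eigensolve bound of 10; reduce the "
                "system using composite/equivalent-spin groups"
            )
        if J.shape != (n, n):
            raise ValueError(f"coupling matrix shape {J.shape} does not match {n} spins")
        if not np.allclose(J, J.T, atol=0.0):
            raise ValueError("coupling matrix must be symmetric")

    @property
    def n_spins(self) -> int:
        return self.shifts.size

    @classmethod
    def from_json(cls, path) -> "SpinSystem":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["species"], np.asarray(d["shifts_ppm"]), np.asarray(d["J_Hz"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "species": self.species_name,
                    "shifts_ppm": self.shifts.tolist(),
                    "J_Hz": self.couplings.tolist(),
                },
                fh,
                indent=1,
            )


def spin_signature(
    sys: SpinSystem,
    B0: float,
    f0: float = 0.0,
    alpha: float = 1.0,
    prune: float = 1e-6,
) -> Signature:
    """Compute the single-quantum stick spectrum of a spin system.

    Parameters
    ----------
    sys : SpinSystem
    B0 : float
        Spectrometer frequency in MHz (sets ν_i = B0·δ_i, so multiplet
        patterns are field dependent).
    f0 : float
        Spectral offset in ppm; retained in the returned peak positions,
        which are expressed in absolute ppm.
    alpha : float
        Decay rate (s⁻¹) attached to every transition.
    prune : float
        Drop transitions weaker than this fraction of the strongest one.

    Returns
    -------
    Signature
        One Peak per allowed transition, ``Σ b_p`` = number of spins before
        pruning; ``proton_count`` set to the number of spins.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    n = sys.n_spins
    nu = B0 * sys.shifts  # Hz; absolute ppm recovered as f/B0
    dim = 2**n

    H = np.zeros((dim, dim), dtype=complex)
    Iz = [_single_spin_op(_SIGMA_Z, i, n) for i in range(n)]
    Ix = [_single_spin_op(_SIGMA_X, i, n) for i in range(n)]
    Iy = [_single_spin_op(_SIGMA_Y, i, n) for i in range(n)]
    for i in range(n):
        H += nu[i] * Iz[i]
        for j in range(i + 1, n):
            Jij = sys.couplings[i, j]
            if Jij != 0.0:
                H += Jij * (Ix[i] @ Ix[j] + Iy[i] @ Iy[j] + Iz[i] @ Iz[j])

    energies, states = np.linalg.eigh(H)
    I_minus = sum(_single_spin_op(_SIGMA_M, i, n) for i in range(n))
    # ⟨b| I⁻ |a⟩ in the eigenbasis; nonzero only for ΔM = −1 transitions
    M = states.conj().T @ I_minus @ states
    weights = np.abs(M) ** 2 / 2 ** (n - 1)  # sum rule: Σ = n

    b_idx, a_idx = np.nonzero(weights > 0.0)
    freqs_hz = energies[a_idx] - energies[b_idx]
    b = weights[b_idx, a_idx]

    keep = b > prune * b.max()
    freqs_hz, b = freqs_hz[keep], b[keep]
    order = np.argsort(freqs_hz)
    peaks = tuple(
        Peak(chemical_shift=float(f / B0), decay_rate=alpha, relative_intensity=float(w))
        for f, w in zip(freqs_hz[order], b[order])
    )
    return Signature(sys.species_name, peaks, proton_count=n)
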