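"""Vibronic basis and Hamiltonian of a single pigment.

The truncated basis contains, for each electronic state with vibrational
structure, products of the vibronic-coupling (VC) oscillator level n_VC
(0..max_quanta) with at most one intramolecular mode excited to its first
level.  Purely electronic states (By, Bx) contribute a single basis state.
Energies are measured relative to the Qy 0-0 transition; the ground-state
zero-point energy cancels out of every transition frequency and is dropped.

The VC oscillator is not displaced in any electronic state, so basis states
with n_VC > 0 carry no direct transition dipole from the ground state; they
acquire intensity only through the coordinate-linear Qy-Qx coupling
alpha * q_VC, whose matrix elements follow the harmonic ladder rule
alpha * <n|q|n+1> = alpha-tilde * sqrt((n+1)/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np

from .modes import MonomerParams, QY

__all__ = [
    "VibronicBasisState",
    "MonomerHamiltonian",
    "build_basis",
    "franck_condon_amplitude",
    "assemble_monomer",
    "effective_vc_huang_rhys",
]


@dataclass(frozen=True)
class VibronicBasisState:
    """One product basis state |electronic, n_VC, (mode_index, mode_quanta)>."""

    electronic: str
    vc_quanta: int = 0
    mode_index: int | None = None
    mode_quanta: int = 0

    @property
    def vibrationless(self) -> bool:
        """True for a pure 0-0 state (no VC or intramolecular quanta)."""
        return self.vc_quanta == 0 and self.mode_quanta == 0


def build_basis(params: MonomerParams) -> list[VibronicBasisState]:
    """Enumerate the truncated vibronic basis in deterministic order.

    Ordering: electronic states in the order given by ``params.states``; within
    a vibrational manifold, VC quanta ascending, then the intramolecular slot
    (no mode first, then modes in catalog order).
    """
    basis: list[VibronicBasisState] = []
    n_modes = len(params.modes)
    for st in params.states:
        if not st.has_vibrations:
            basis.append(VibronicBasisState(st.label))
            continue
        for n_vc in range(params.vc_mode.max_quanta + 1):
            basis.append(VibronicBasisState(st.label, n_vc, None, 0))
            for i in range(n_modes):
                basis.append(VibronicBasisState(st.label, n_vc, i, 1))
    return basis


def franck_condon_amplitude(huang_rhys: float, n: int) -> float:
    """Overlap <n|0~> of oscillator level n with the displaced ground state.

    amplitude^2 = exp(-S) S^n / n!  (Poisson intensity distribution).
    """
    if huang_rhys < 0:
        raise ValueError("Huang-Rhys factor must be non-negative")
    if n < 0:
        raise ValueError("quantum number must be non-negative")
    if huang_rhys == 0.0:
        return 1.0 if n == 0 else 0.0
    log_amp = -huang_rhys / 2.0 + 0.5 * (n * np.log(huang_rhys) - lgamma(n + 1))
    return float(np.exp(log_amp))


def _fc_from_ground(params: MonomerParams, state: VibronicBasisState) -> float:
    """Total Franck-Condon amplitude of a basis state from the global ground state.

    Product over all intramolecular modes of the per-mode overlap, times the
    VC-mode overlap, which is delta(n_VC, 0) because the VC oscillator is
    undisplaced.
    """
    st = params.state(state.electronic)
    if not st.has_vibrations:
        return 1.0
    if state.vc_quanta > 0:
        return 0.0
    amp = 1.0
    for i, mode in enumerate(params.modes):
        n = state.mode_quanta if state.mode_index == i else 0
        amp *= franck_condon_amplitude(mode.s(st.label), n)
    return amp


@dataclass
class MonomerHamiltonian:
    """Dense vibronic Hamiltonian of a single pigment.

    ``fc_amplitudes`` are the bare Franck-Condon amplitudes from the ground
    state; ``dipole_amplitudes`` additionally carry the electronic transition
    dipole magnitude sqrt(f) relative to Qy.
    """

    params: MonomerParams
    basis: list[VibronicBasisState]
    matrix: np.ndarray
    fc_amplitudes: np.ndarray
    dipole_amplitudes: np.ndarray

    @property
    def size(self) -> int:
        return len(self.basis)

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.linalg.eigh(self.matrix)

    def stick_spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigen-energies and dipole strengths of the diagonalized monomer."""
        evals, evecs = self.eigh()
        amps = evecs.T @ self.dipole_amplitudes
        return evals, amps**2

    def basis_table(self):
        """Basis states with diagonal energies and amplitudes (DataFrame)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "electronic": [b.electronic for b in self.basis],
                "vc_quanta": [b.vc_quanta for b in self.basis],
                "mode_index": [b.mode_index for b in self.basis],
                "mode_quanta": [b.mode_quanta for b in self.basis],
                "energy_cm1": np.diag(self.matrix),
                "fc_amplitude": self.fc_amplitudes,
                "dipole_amplitude": self.dipole_amplitudes,
            }
        )


def assemble_monomer(
    params: MonomerParams,
    basis: list[VibronicBasisState] | None = None,
    energy_shifts: dict[str, float] | None = None,
) -> MonomerHamiltonian:
    """Build the monomer Hamiltonian in the truncated vibronic basis.

    Diagonal: electronic 0-0 offset + n_VC * omega_VC + mode quanta * omega_i
    (optionally shifted per electronic state by ``energy_shifts``, used for
    site-energy disorder).  Off-diagonal: the vibronic coupling connects
    |Qy, n_VC, v> with |Qx, n_VC +- 1, v> for identical intramolecular
    excitation v.
    """
    if basis is None:
        basis = build_basis(params)
    n = len(basis)
    shifts = energy_shifts or {}
    h = np.zeros((n, n))
    fc = np.empty(n)
    dip = np.empty(n)

    coupled = [st.label for st in params.states if st.vibronically_coupled]
    for i, b in enumerate(basis):
        st = params.state(b.electronic)
        e = st.energy_offset + shifts.get(b.electronic, 0.0)
        e += b.vc_quanta * params.vc_mode.frequency
        if b.mode_index is not None and b.mode_quanta:
            e += b.mode_quanta * params.modes[b.mode_index].frequency
        h[i, i] = e
        fc[i] = _fc_from_ground(params, b)
        dip[i] = st.dipole_amplitude * fc[i]

    if len(coupled) == 2:
        s1, s2 = coupled
        index = {
            (b.electronic, b.vc_quanta, b.mode_index, b.mode_quanta): i
            for i, b in enumerate(basis)
        }
        for i, b in enumerate(basis):
            if b.electronic != s1:
                continue
            for dn in (-1, 1):
                key = (s2, b.vc_quanta + dn, b.mode_index, b.mode_quanta)
                j = index.get(key)
                if j is None:
                    continue
                n_low = min(b.vc_quanta, b.vc_quanta + dn)
                v = params.vc_mode.ladder_element(n_low)
                h[i, j] = v
                h[j, i] = v
    elif len(coupled) > 2:
        raise ValueError("the vibronic coupling connects exactly two states")

    return MonomerHamiltonian(params, basis, h, fc, dip)


def effective_vc_huang_rhys(
    ham: MonomerHamiltonian, character_threshold: float = 0.25
) -> float:
    """Diagnostic effective Huang-Rhys factor of the vibronic coupling mode.

    The coordinate-linear coupling produces an effective displacement of the
    VC oscillator on the lowest adiabatic surface.  Operationally this is
    estimated as in a Franck-Condon progression: the summed dipole strength of
    eigenstates carrying the first VC satellite of the lowest adiabat (those
    with dominant |Qy, n_VC = 1> character above ``character_threshold``)
    divided by the dipole strength of the 0-0 origin.  It is reported as a
    diagnostic only and enters no downstream observable.
    """
    evals, evecs = ham.eigh()
    weights = (evecs.T @ ham.dipole_amplitudes) ** 2

    def _char(mask: np.ndarray) -> np.ndarray:
        return (evecs[mask, :] ** 2).sum(axis=0)

    basis = ham.basis
    mask_00 = np.array(
        [b.electronic == QY and b.vibrationless for b in basis], dtype=bool
    )
    mask_01 = np.array(
        [
            b.electronic == QY and b.vc_quanta == 1 and b.mode_quanta == 0
            for b in basis
        ],
        dtype=bool,
    )
    char_00 = _char(mask_00)
    char_01 = _char(mask_01)
    i_00 = float(weights[char_00 >= character_threshold].sum())
    if i_00 <= 0:
        raise ValueError("vanishing 0-0 intensity; effective S is undefined")
    i_01 = float(weights[char_01 >= character_threshold].sum())
    return i_01 / i_00
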