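"""Excitonically coupled dimer in the one-particle approximation (OPA).

The dimer basis is the union of the two monomer vibronic bases: in each
basis state one pigment carries the (vibronically dressed) excitation while
the partner sits in its vibrational ground state.  Electronic inter-pigment
couplings J_mn multiply the Franck-Condon amplitudes of the two excited-side
vibronic states, since the de-excited partner contributes its ground-state
overlap.

Couplings are either evaluated in the point-dipole approximation or, in the
default pathway, scaled from a fitted Qy-Qy coupling via transition-dipole
ratios and orientation-factor ratios, which removes the absolute dipole
magnitudes and the vacuum/screening constant from the problem.

Circular dichroism uses magnetic transition dipoles m = i R x mu built from
the pigment center positions; the package stores the real vector R x mu and
carries the factor i implicitly (rotational strength R_alpha =
mu_exc . (R x mu)_exc, a real number).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import PigmentGeometry
from .modes import QY, STATE_LABELS
from .monomer import MonomerHamiltonian, VibronicBasisState
from .units import KAPPA_DIPOLE

__all__ = [
    "CouplingMatrix",
    "ExcitonSystem",
    "ExcitonDecomposition",
    "orientation_factor",
    "dipole_dipole_coupling",
    "scaled_couplings",
    "magnetic_dipoles",
    "assemble_dimer",
    "monomer_system",
    "diagonalize",
]


def orientation_factor(e_m: np.ndarray, e_n: np.ndarray, e_ab: np.ndarray) -> float:
    """Point-dipole orientation factor zeta = e_m.e_n - 3 (e_m.e_ab)(e_n.e_ab)."""
    return float(e_m @ e_n - 3.0 * (e_m @ e_ab) * (e_n @ e_ab))


def dipole_dipole_coupling(
    geom_a: PigmentGeometry,
    geom_b: PigmentGeometry,
    state_a: str,
    state_b: str,
    mu_a_debye: float,
    mu_b_debye: float,
) -> float:
    """Point-dipole coupling kappa * mu_a mu_b zeta / R^3 in cm^-1."""
    r_vec = geom_b.center - geom_a.center
    r = np.linalg.norm(r_vec)
    if r < 1e-9:
        raise ValueError("pigment centers coincide")
    zeta = orientation_factor(
        geom_a.direction(state_a), geom_b.direction(state_b), r_vec / r
    )
    return KAPPA_DIPOLE * mu_a_debye * mu_b_debye * zeta / r**3


@dataclass(frozen=True)
class CouplingMatrix:
    """Electronic couplings J[m, n] (cm^-1) between transitions m of pigment A
    and n of pigment B, indexed by state label."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("coupling matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    def get(self, m: str, n: str) -> float:
        return float(self.values[self.labels.index(m), self.labels.index(n)])

    @classmethod
    def zero(cls, labels: Sequence[str] = STATE_LABELS) -> "CouplingMatrix":
        labels = tuple(labels)
        return cls(labels, np.zeros((len(labels), len(labels))))


def scaled_couplings(
    geom_a: PigmentGeometry,
    geom_b: PigmentGeometry,
    dipole_ratio_sq: dict[str, float],
    j_qyqy: float = 83.0,
    labels: Sequence[str] = STATE_LABELS,
) -> CouplingMatrix:
    """Couplings anchored to a fitted Qy-Qy value.

    J_mn = J_QyQy * f_m * f_n * zeta_mn / zeta_QyQy, with f the transition
    dipole *amplitude* ratio sqrt(|mu_m|^2 / |mu_Qy|^2).
    """
    labels = tuple(labels)
    r_vec = geom_b.center - geom_a.center
    r = np.linalg.norm(r_vec)
    if r < 1e-9:
        raise ValueError("pigment centers coincide")
    e_ab = r_vec / r
    zeta_yy = orientation_factor(
        geom_a.direction(QY), geom_b.direction(QY), e_ab
    )
    if abs(zeta_yy) < 1e-9:
        raise ValueError("vanishing Qy-Qy orientation factor; cannot anchor couplings")
    values = np.empty((len(labels), len(labels)))
    for i, m in enumerate(labels):
        f_m = np.sqrt(dipole_ratio_sq.get(m, 1.0))
        for j, n in enumerate(labels):
            f_n = np.sqrt(dipole_ratio_sq.get(n, 1.0))
            zeta = orientation_factor(
                geom_a.direction(m), geom_b.direction(n), e_ab
            )
            values[i, j] = j_qyqy * f_m * f_n * zeta / zeta_yy
    return CouplingMatrix(labels, values)


def magnetic_dipoles(center: np.ndarray, electric_dipoles: np.ndarray) -> np.ndarray:
    """Magnetic transition dipoles m = i R x mu for transitions of one pigment.

    ``electric_dipoles`` is (n, 3); the returned array stores the real vectors
    R x mu (the factor i is implicit).  The proportionality constant is set to
    one, so circular dichroism is reported in relative units.  The intrinsic
    (one-pigment) CD is neglected: a localized state has mu . (R x mu) = 0.
    """
    return np.cross(center, np.atleast_2d(electric_dipoles))


@dataclass
class ExcitonSystem:
    """One- or two-pigment vibronic system ready for diagonalization."""

    hamiltonian: np.ndarray
    basis: list[VibronicBasisState]
    pigment_index: np.ndarray
    electric_dipoles: np.ndarray  # (n, 3), FC-weighted, relative units
    magnetic_dipoles: np.ndarray  # (n, 3), real part of m / i
    monomers: tuple[MonomerHamiltonian, ...]
    block_sizes: tuple[int, ...]

    @property
    def size(self) -> int:
        return self.hamiltonian.shape[0]

    @property
    def n_pigments(self) -> int:
        return len(self.block_sizes)

    def with_site_shifts(self, shifts: Sequence[dict[str, float]]) -> "ExcitonSystem":
        """Return a copy with per-pigment electronic energies shifted.

        ``shifts`` holds one mapping {state label: cm^-1} per pigment; the
        shift moves the whole vibronic ladder of that electronic state.
        """
        delta = np.array(
            [
                shifts[p].get(b.electronic, 0.0)
                for p, b in zip(self.pigment_index, self.basis)
            ]
        )
        h = self.hamiltonian + np.diag(delta)
        return ExcitonSystem(
            h, self.basis, self.pigment_index, self.electric_dipoles,
            self.magnetic_dipoles, self.monomers, self.block_sizes,
        )


def _coupling_allowed(
    b_a: VibronicBasisState, b_b: VibronicBasisState, mask: str
) -> bool:
    if mask == "all":
        return True
    if mask == "none":
        return False
    if mask == "zero-zero":
        # only transitions involving the lowest vibrational eigenfunctions
        return b_a.vibrationless and b_b.vibrationless
    raise ValueError(f"unknown coupling mask {mask!r}")


def monomer_system(
    monomer: MonomerHamiltonian, geometry: PigmentGeometry | None = None
) -> ExcitonSystem:
    """Wrap a single pigment as a one-block exciton system."""
    n = monomer.size
    if geometry is None:
        dipoles = np.zeros((n, 3))
        dipoles[:, 0] = monomer.dipole_amplitudes
        center = np.zeros(3)
    else:
        dirs = np.array([geometry.direction(b.electronic) for b in monomer.basis])
        dipoles = monomer.dipole_amplitudes[:, None] * dirs
        center = geometry.center
    return ExcitonSystem(
        hamiltonian=monomer.matrix.copy(),
        basis=list(monomer.basis),
        pigment_index=np.zeros(n, dtype=int),
        electric_dipoles=dipoles,
        magnetic_dipoles=magnetic_dipoles(center, dipoles),
        monomers=(monomer,),
        block_sizes=(n,),
    )


def assemble_dimer(
    monomer_a: MonomerHamiltonian,
    monomer_b: MonomerHamiltonian,
    geom_a: PigmentGeometry,
    geom_b: PigmentGeometry,
    couplings: CouplingMatrix,
    coupling_mask: str = "all",
) -> ExcitonSystem:
    """Build the OPA dimer Hamiltonian [[H_A, V], [V.T, H_B]].

    V[i, j] = J(m_i, n_j) * fc_i * fc_j: the electronic coupling between the
    transitions dressed by the Franck-Condon amplitudes of both excited-side
    vibronic states (the de-excited partner stays in its vibrational ground
    state).  ``coupling_mask`` in {"all", "zero-zero", "none"} restricts which
    vibronic transitions are excitonically coupled; "zero-zero" keeps only
    elements between states with no vibrational quanta on either side.
    """
    na, nb = monomer_a.size, monomer_b.size
    h = np.zeros((na + nb, na + nb))
    h[:na, :na] = monomer_a.matrix
    h[na:, na:] = monomer_b.matrix

    j_ab = np.array(
        [
            [couplings.get(ba.electronic, bb.electronic) for bb in monomer_b.basis]
            for ba in monomer_a.basis
        ]
    )
    allowed = np.array(
        [
            [_coupling_allowed(ba, bb, coupling_mask) for bb in monomer_b.basis]
            for ba in monomer_a.basis
        ]
    )
    v = j_ab * allowed * np.outer(monomer_a.fc_amplitudes, monomer_b.fc_amplitudes)
    h[:na, na:] = v
    h[na:, :na] = v.T

    dirs_a = np.array([geom_a.direction(b.electronic) for b in monomer_a.basis])
    dirs_b = np.array([geom_b.direction(b.electronic) for b in monomer_b.basis])
    mu = np.vstack(
        [
            monomer_a.dipole_amplitudes[:, None] * dirs_a,
            monomer_b.dipole_amplitudes[:, None] * dirs_b,
        ]
    )
    mag = np.vstack(
        [
            magnetic_dipoles(geom_a.center, mu[:na]),
            magnetic_dipoles(geom_b.center, mu[na:]),
        ]
    )
    return ExcitonSystem(
        hamiltonian=h,
        basis=list(monomer_a.basis) + list(monomer_b.basis),
        pigment_index=np.concatenate([np.zeros(na, int), np.ones(nb, int)]),
        electric_dipoles=mu,
        magnetic_dipoles=mag,
        monomers=(monomer_a, monomer_b),
        block_sizes=(na, nb),
    )


@dataclass
class ExcitonDecomposition:
    """Eigen-decomposition of an exciton system.

    ``coefficients`` has eigenvectors in columns (local basis x exciton).
    ``gamma`` is the exciton-bath weight matrix gamma[alpha, beta] =
    sum_pigments (sum_{m in pigment} A_m,alpha A_m,beta)^2; its diagonal is
    the inverse participation ratio of each exciton state over pigments.
    """

    system: ExcitonSystem
    energies: np.ndarray
    coefficients: np.ndarray
    mu_exc: np.ndarray
    m_exc: np.ndarray
    gamma: np.ndarray

    @property
    def dipole_strength(self) -> np.ndarray:
        return np.einsum("ij,ij->i", self.mu_exc, self.mu_exc)

    @property
    def rotational_strength(self) -> np.ndarray:
        """Im(mu . m) per exciton state (m carries an implicit factor i)."""
        return np.einsum("ij,ij->i", self.mu_exc, self.m_exc)


def _decompose(system: ExcitonSystem, energies, coeffs) -> ExcitonDecomposition:
    mu_exc = coeffs.T @ system.electric_dipoles
    m_exc = coeffs.T @ system.magnetic_dipoles
    n = system.size
    gamma = np.zeros((n, n))
    start = 0
    for size in system.block_sizes:
        block = coeffs[start : start + size, :]
        overlap = block.T @ block
        gamma += overlap**2
        start += size
    return ExcitonDecomposition(system, energies, coeffs, mu_exc, m_exc, gamma)


def diagonalize(system: ExcitonSystem) -> ExcitonDecomposition:
    """Diagonalize the system and transform dipoles to the exciton basis.

    When the inter-pigment block vanishes exactly (all couplings zero) the
    blocks are diagonalized separately, which keeps the degenerate eigenstates
    of identical uncoupled pigments localized -- the physically correct limit
    for independent system-bath coupling.
    """
    h = system.hamiltonian
    if not np.all(np.isfinite(h)):
        raise ValueError("Hamiltonian contains non-finite entries")
    n = system.size
    if system.n_pigments == 2:
        na = system.block_sizes[0]
        if not np.any(h[:na, na:]):
            ea, ca = np.linalg.eigh(h[:na, :na])
            eb, cb = np.linalg.eigh(h[na:, na:])
            energies = np.concatenate([ea, eb])
            coeffs = np.zeros((n, n))
            coeffs[:na, :na] = ca
            coeffs[na:, na:] = cb
            order = np.argsort(energies, kind="stable")
            return _decompose(system, energies[order], coeffs[:, order])
    energies, coeffs = np.linalg.eigh(h)
    return _decompose(system, energies, coeffs)
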