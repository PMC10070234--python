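"""Intramolecular mode catalog, electronic states, and monomer parameters.

The model treats a chlorophyll-like pigment with four singlet transitions
(Qy, Qx, By, Bx).  Qy and Qx carry Franck-Condon progressions in a small set
of effective high-frequency intramolecular modes, each characterised by a
frequency (cm^-1) and a state-dependent Huang-Rhys factor S.  Qy and Qx are
additionally mixed by a single vibronic coupling mode, linear in its
coordinate, analogous to the coupling mode of a conical intersection.  The
Soret transitions By and Bx are purely electronic.

Displacements are never stored: d = sqrt(2 S / omega) is derived on demand,
since every observable of the model depends on the modes only through S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

QY, QX, BY, BX = "Qy", "Qx", "By", "Bx"
STATE_LABELS = (QY, QX, BY, BX)


@dataclass(frozen=True)
class VibrationalMode:
    """One effective intramolecular mode: frequency and per-state Huang-Rhys factors."""

    frequency: float
    huang_rhys: Mapping[str, float]
    label: str = ""

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError(f"mode frequency must be positive, got {self.frequency}")
        if any(s < 0 for s in self.huang_rhys.values()):
            raise ValueError("Huang-Rhys factors must be non-negative")
        object.__setattr__(self, "huang_rhys", dict(self.huang_rhys))

    def s(self, state: str) -> float:
        return self.huang_rhys.get(state, 0.0)

    def displacement(self, state: str) -> float:
        """Dimensionless oscillator displacement d = sqrt(2 S / omega)."""
        return np.sqrt(2.0 * self.s(state) / self.frequency)


@dataclass(frozen=True)
class VibronicCouplingMode:
    """The Qy-Qx coupling mode.

    ``coupling_constant_scaled`` is the frequency-scaled constant
    alpha-tilde (cm^-1); the unscaled alpha = alpha-tilde * sqrt(omega).
    The oscillator is not displaced in any electronic state; it acts only
    through the off-diagonal, coordinate-linear coupling.
    """

    frequency: float = 1500.0
    coupling_constant_scaled: float = 750.0
    max_quanta: int = 4

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("vibronic coupling mode frequency must be positive")
        if self.max_quanta < 0:
            raise ValueError("max_quanta must be >= 0")

    @property
    def coupling_constant(self) -> float:
        """Unscaled alpha = alpha-tilde * sqrt(omega)."""
        return self.coupling_constant_scaled * np.sqrt(self.frequency)

    def ladder_element(self, n_low: int) -> float:
        """Coupling matrix element between VC levels n_low and n_low + 1.

        alpha * <n|q|n+1> = alpha-tilde * sqrt((n+1)/2), independent of omega.
        """
        return self.coupling_constant_scaled * np.sqrt((n_low + 1) / 2.0)


@dataclass(frozen=True)
class ElectronicState:
    """A singlet transition of the pigment.

    ``energy_offset``: 0-0 energy relative to Qy (cm^-1).
    ``dipole_ratio_sq``: ratio of transition dipole strengths f = |mu|^2/|mu_Qy|^2.
    """

    label: str
    energy_offset: float = 0.0
    dipole_ratio_sq: float = 1.0
    has_vibrations: bool = True
    vibronically_coupled: bool = False

    def __post_init__(self):
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.label == QY and self.energy_offset != 0.0:
            raise ValueError("Qy defines the energy origin; its offset must be 0")
        if self.label in (BY, BX) and self.has_vibrations:
            raise ValueError(f"{self.label} is purely electronic (no vibrations)")
        if self.vibronically_coupled and self.label not in (QY, QX):
            raise ValueError("only Qy and Qx participate in the vibronic coupling")
        if self.dipole_ratio_sq < 0:
            raise ValueError("dipole_ratio_sq must be non-negative")

    @property
    def dipole_amplitude(self) -> float:
        """Transition dipole magnitude relative to Qy: sqrt(f)."""
        return np.sqrt(self.dipole_ratio_sq)


class ModeCatalog:
    """Ordered collection of intramolecular modes."""

    def __init__(self, modes: Iterable[VibrationalMode]):
        self.modes: tuple[VibrationalMode, ...] = tuple(modes)

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i):
        return self.modes[i]

    def __eq__(self, other):
        if not isinstance(other, ModeCatalog):
            return NotImplemented
        return self.modes == other.modes

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.modes])

    def huang_rhys(self, state: str) -> np.ndarray:
        return np.array([m.s(state) for m in self.modes])

    def total_huang_rhys(self, state: str) -> float:
        return float(self.huang_rhys(state).sum())


def group_modes(
    modes: Sequence[VibrationalMode],
    group_sizes: Sequence[int],
    weight_state: str = QY,
) -> list[VibrationalMode]:
    """Coarse-grain a mode list by merging consecutive frequency-sorted groups.

    Each group is replaced by a single mode whose Huang-Rhys factor is the sum
    over the group (per electronic state) and whose frequency is the
    S-weighted mean of the group frequencies, with weights taken from
    ``weight_state``.  The total Huang-Rhys factor is conserved exactly.
    """
    if sum(group_sizes) != len(modes):
        raise ValueError(
            f"group sizes sum to {sum(group_sizes)} but there are {len(modes)} modes"
        )
    freqs = [m.frequency for m in modes]
    if any(b < a for a, b in zip(freqs, freqs[1:])):
        raise ValueError("modes must be sorted by ascending frequency")

    out: list[VibrationalMode] = []
    start = 0
    for gi, size in enumerate(group_sizes):
        if size <= 0:
            raise ValueError("group sizes must be positive")
        group = modes[start : start + size]
        start += size
        weights = np.array([m.s(weight_state) for m in group])
        s_group = weights.sum()
        if s_group <= 0:
            raise ValueError(
                f"group {gi} has zero total Huang-Rhys factor in state "
                f"{weight_state!r}; its weighted mean frequency is undefined"
            )
        omega = float(np.dot(weights / s_group, [m.frequency for m in group]))
        states = sorted({s for m in group for s in m.huang_rhys})
        merged = {st: float(sum(m.s(st) for m in group)) for st in states}
        out.append(VibrationalMode(omega, merged, label=f"group{gi + 1}"))
    return out


def rescale_qx_modes(
    catalog: ModeCatalog,
    mode_indices: Iterable[int],
    displacement_factor: float = 3.0,
) -> ModeCatalog:
    """Rescale the Qx displacement of selected modes by a constant factor.

    A displacement factor ``c`` multiplies the Qx Huang-Rhys factor by c^2
    (the canonical chlorophyll-a choice is c = 3, i.e. a factor of 9).
    Qy values are untouched.
    """
    if displacement_factor <= 0:
        raise ValueError("displacement factor must be positive")
    indices = set(mode_indices)
    for i in indices:
        if not 0 <= i < len(catalog):
            raise IndexError(f"mode index {i} out of range for {len(catalog)} modes")
    factor_sq = displacement_factor**2
    new_modes = []
    for i, m in enumerate(catalog):
        hr = dict(m.huang_rhys)
        base = hr.get(QX, hr.get(QY, 0.0))
        hr[QX] = base * factor_sq if i in indices else base
        new_modes.append(replace(m, huang_rhys=hr))
    return ModeCatalog(new_modes)


def reorganization_energy(catalog: ModeCatalog, state: str) -> float:
    """Intramolecular reorganization energy sum_i S_i(state) * omega_i in cm^-1."""
    return float(np.dot(catalog.huang_rhys(state), catalog.frequencies))


# ---------------------------------------------------------------------------
# Canonical chlorophyll-a parameterisation
# ---------------------------------------------------------------------------

#: Ten effective intramolecular modes of chlorophyll a: (frequency cm^-1,
#: Huang-Rhys factor of the Qy transition).  Obtained by coarse-graining a
#: 51-mode normal-mode set into groups of similar frequency; the total
#: Huang-Rhys factor is 0.278.
CHLA_MODE_TABLE: tuple[tuple[float, float], ...] = (
    (169.0, 0.0295),
    (345.0, 0.0222),
    (438.0, 0.0044),
    (572.0, 0.0103),
    (732.0, 0.0272),
    (843.0, 0.0182),
    (993.0, 0.0474),
    (1197.0, 0.0299),
    (1310.0, 0.0521),
    (1511.0, 0.0367),
)

#: Indices (0-based) of the low-frequency modes whose Qx displacement is
#: three times the Qy displacement.
CHLA_QX_RESCALED_MODES = (0, 1, 2)


def chla_mode_catalog(qx_displacement_factor: float = 3.0) -> ModeCatalog:
    """The canonical 10-mode chlorophyll-a catalog.

    Qx Huang-Rhys factors equal the Qy ones except for the three
    lowest-frequency modes, whose displacement is enlarged by
    ``qx_displacement_factor`` (Huang-Rhys scaled by its square).
    """
    base = ModeCatalog(
        VibrationalMode(w, {QY: s, QX: s}, label=f"mode{i + 1}")
        for i, (w, s) in enumerate(CHLA_MODE_TABLE)
    )
    return rescale_qx_modes(base, CHLA_QX_RESCALED_MODES, qx_displacement_factor)


def chla_states(
    include_b: bool = True,
    delta_qx: float = 1640.0,
    f_qx: float = 0.1,
    delta_by: float = 7570.0,
    f_by: float = 2.52,
    delta_bx: float = 8740.0,
    f_bx: float = 2.43,
) -> list[ElectronicState]:
    """Electronic-state ladder of chlorophyll a (energies relative to Qy 0-0)."""
    states = [
        ElectronicState(QY, 0.0, 1.0, has_vibrations=True, vibronically_coupled=True),
        ElectronicState(QX, delta_qx, f_qx, has_vibrations=True, vibronically_coupled=True),
    ]
    if include_b:
        states.append(ElectronicState(BY, delta_by, f_by, has_vibrations=False))
        states.append(ElectronicState(BX, delta_bx, f_bx, has_vibrations=False))
    return states


@dataclass(frozen=True)
class MonomerParams:
    """Complete parameter set of one pigment."""

    states: tuple[ElectronicState, ...]
    modes: ModeCatalog
    vc_mode: VibronicCouplingMode
    qy_energy_absolute: float = 0.0
    inhomogeneous_fwhm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate electronic state labels")
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "inhomogeneous_fwhm", dict(self.inhomogeneous_fwhm))
        for st in self.states:
            if st.has_vibrations:
                for m in self.modes:
                    if st.label not in m.huang_rhys:
                        raise ValueError(
                            f"mode {m.label!r} lacks a Huang-Rhys factor for state "
                            f"{st.label!r} which has vibrational structure"
                        )
        for label, fwhm in self.inhomogeneous_fwhm.items():
            if fwhm < 0:
                raise ValueError(f"negative inhomogeneous FWHM for {label}")

    def state(self, label: str) -> ElectronicState:
        for st in self.states:
            if st.label == label:
                return st
        raise KeyError(label)

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)
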