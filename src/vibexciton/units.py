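"""Physical constants and unit helpers.

Internal unit conventions used throughout the package:

* energies / frequencies: wavenumbers (cm^-1)
* time: centimetres, conjugate to cm^-1 under the kernel exp(2*pi*i*nu*t);
  physical time t_fs = t_cm / C_CM_PER_FS
* transition dipoles: relative units (the Qy amplitude of a pigment is 1);
  absolute Debye values enter only the optional raw dipole-dipole coupling
* distances: Angstrom
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in cm^-1 / K
KB_CM = 0.6950348004

#: speed of light in cm / fs (converts internal time in cm to femtoseconds)
C_CM_PER_FS = 2.99792458e-5

#: point-dipole coupling constant in cm^-1 * Angstrom^3 / Debye^2 (vacuum)
KAPPA_DIPOLE = 5034.0

#: FWHM of a Gaussian = FWHM_SIGMA * sigma
FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def wavenumber_to_nm(wavenumber: float) -> float:
    """Convert a transition energy in cm^-1 to a vacuum wavelength in nm."""
    wn = np.asarray(wavenumber, dtype=float)
    if np.any(wn <= 0):
        raise ValueError("wavenumber must be positive")
    out = 1.0e7 / wn
    return float(out) if out.ndim == 0 else out


def nm_to_wavenumber(wavelength_nm: float) -> float:
    """Convert a vacuum wavelength in nm to cm^-1."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1.0e7 / wavelength_nm


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return fwhm / FWHM_SIGMA


def time_cm_to_fs(t_cm: float) -> float:
    return t_cm / C_CM_PER_FS


def rate_cm_to_lifetime_fs(rate_cm: float) -> float:
    """Lifetime in fs for a decay rate given as a linewidth (HWHM) in cm^-1."""
    if rate_cm <= 0:
        return np.inf
    return 1.0 / (2.0 * np.pi * C_CM_PER_FS * rate_cm)
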