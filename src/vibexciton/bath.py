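"""Low-frequency bath: spectral density, correlation functions, line
broadening and lifetime broadening.

The protein/solvent environment is described by a two-term super-Ohmic
spectral density

    J(omega) = sum_k  s_k * omega^3 / (7! * 2 * omega_k^4)
               * exp(-sqrt(omega / omega_k)),

normalised such that the integral of J equals the total bath Huang-Rhys
factor s_1 + s_2 and the first moment (the bath reorganization energy) is
lambda = (9!/7!) * sum_k s_k omega_k = 72 * sum_k s_k omega_k.

The bath couples diagonally to the local electronic excitations, with an
independent but statistically identical bath per pigment.  In the exciton
basis this yields, per exciton pair (alpha, beta), the weight
gamma_{alpha beta beta alpha} computed by the dimer module.  The observable
quantities are:

* the line-broadening function G(t) (zero-phonon line plus phonon wing),
* renormalized exciton energies (reorganization and bath-induced shifts),
* inter-exciton relaxation rates Gamma = 2 gamma Re C(omega_{alpha beta})
  obeying detailed balance, which determine the dephasing times tau_alpha.

Internally time is measured in cm (conjugate to cm^-1 under
exp(2*pi*i*nu*t)); conversions to fs use the speed of light.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.integrate import quad

from .units import C_CM_PER_FS, KB_CM

__all__ = [
    "SpectralDensity",
    "BathCorrelation",
    "LineshapeTerms",
    "line_broadening_g",
    "lifetimes",
]

_NORM = 2.0 * factorial(7)  # 7! * 2


@dataclass(frozen=True)
class SpectralDensity:
    """Two-term super-Ohmic spectral density of the low-frequency bath."""

    s1: float = 0.402
    s2: float = 0.398
    omega1: float = 0.557
    omega2: float = 1.94

    def __post_init__(self):
        if min(self.s1, self.s2) < 0:
            raise ValueError("Huang-Rhys weights must be non-negative")
        if min(self.omega1, self.omega2) <= 0:
            raise ValueError("characteristic frequencies must be positive")

    def __call__(self, omega) -> np.ndarray:
        """J(omega) for omega >= 0 (units 1/cm^-1); zero at omega <= 0."""
        w = np.asarray(omega, dtype=float)
        out = np.zeros_like(w)
        pos = w > 0
        wp = w[pos]
        for s, wk in ((self.s1, self.omega1), (self.s2, self.omega2)):
            out[pos] += s * wp**3 / (_NORM * wk**4) * np.exp(-np.sqrt(wp / wk))
        return out if out.ndim else float(out)

    @property
    def total_huang_rhys(self) -> float:
        """Closed-form integral of J over positive frequencies."""
        return self.s1 + self.s2

    @property
    def reorganization_energy(self) -> float:
        """First moment of J: lambda = 72 (s1 w1 + s2 w2), in cm^-1."""
        return 72.0 * (self.s1 * self.omega1 + self.s2 * self.omega2)

    def total_huang_rhys_quadrature(self) -> float:
        """Numerical check of the J normalisation by adaptive quadrature."""
        val = 0.0
        for s, wk in ((self.s1, self.omega1), (self.s2, self.omega2)):
            f = lambda w, s=s, wk=wk: s * w**3 / (_NORM * wk**4) * np.exp(
                -np.sqrt(w / wk)
            )
            # split at the scale where each term peaks (omega = 36 omega_k)
            val += quad(f, 0.0, 36 * wk)[0] + quad(f, 36 * wk, np.inf)[0]
        return val

    def rescaled_total(self, target: float) -> "SpectralDensity":
        """Rescale (s1, s2) proportionally so that the J integral hits ``target``."""
        total = self.total_huang_rhys
        if total <= 0:
            raise ValueError("cannot rescale a zero spectral density")
        c = target / total
        return SpectralDensity(self.s1 * c, self.s2 * c, self.omega1, self.omega2)

    def support_cutoff(self, tol: float = 1e-12) -> float:
        """Frequency above which J is negligible relative to its peak."""
        wk = max(self.omega1, self.omega2)
        # solve exp(-sqrt(w/wk)) ~ tol ignoring the power prefactor
        return wk * np.log(1.0 / tol) ** 2


def _bose(omega: np.ndarray, temperature: float) -> np.ndarray:
    """Bose-Einstein occupation, safe at omega = 0 (where callers multiply by J ~ w^3)."""
    w = np.asarray(omega, dtype=float)
    kt = KB_CM * temperature
    out = np.zeros_like(w)
    nz = np.abs(w) > 1e-12
    with np.errstate(over="ignore"):
        out[nz] = 1.0 / np.expm1(w[nz] / kt)
    return out


class BathCorrelation:
    """Half-Fourier transform C(omega) of the bath correlation function.

    Re C(omega) = pi * omega^2 * (1 + n(omega)) * (J(omega) - J(-omega))
    satisfies detailed balance Re C(-w) = exp(-w/kT) Re C(w); the imaginary
    part follows from the Kramers-Kronig (principal-value) relation
    Im C(w) = (1/pi) PV int Re C(w') / (w - w') dw' and is tabulated once on a
    non-uniform grid, then interpolated.
    """

    def __init__(
        self,
        density: SpectralDensity,
        temperature: float,
        pv_grid_step: float = 0.25,
        query_max: float = 30000.0,
    ):
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.density = density
        self.temperature = temperature
        self._kt = KB_CM * temperature

        cutoff = max(2500.0, density.support_cutoff(1e-10))
        # thermally activated negative side decays as exp(w/kT); same cutoff is safe
        self._src = np.arange(-cutoff, cutoff + pv_grid_step, pv_grid_step)
        self._src_re = self.re(self._src)

        dense = np.arange(-3000.0, 3000.0 + 1.0, 1.0)
        outer = np.geomspace(3001.0, query_max, 160)
        self._query = np.concatenate([-outer[::-1], dense, outer])
        self._query_im = self._pv_transform(self._query)

    def re(self, omega) -> np.ndarray:
        """Real part of C(omega), in cm^-1 (closed form)."""
        w = np.atleast_1d(np.asarray(omega, dtype=float))
        j_diff = self.density(w) - self.density(-w)
        out = np.pi * w**2 * (1.0 + _bose(w, self.temperature)) * j_diff
        # at w = 0 the product has a finite limit of 0 (J ~ w^3)
        out = np.where(np.abs(w) < 1e-12, 0.0, out)
        return out if np.ndim(omega) else float(out[0])

    def _pv_transform(self, queries: np.ndarray) -> np.ndarray:
        """Im C via principal-value integral with singularity subtraction."""
        src, re_src = self._src, self._src_re
        dw = src[1] - src[0]
        out = np.empty_like(queries)
        lo, hi = src[0], src[-1]
        for k in range(0, len(queries), 256):
            q = queries[k : k + 256, None]
            diff = q - src[None, :]
            singular = np.abs(diff) < dw / 2
            inside = (q[:, 0] > lo) & (q[:, 0] < hi)
            re_q = np.where(inside, np.interp(q[:, 0], src, re_src), 0.0)
            integrand = (re_src[None, :] - re_q[:, None]) / np.where(singular, 1.0, diff)
            integrand[singular] = 0.0
            pv = integrand.sum(axis=1) * dw
            # analytic remainder of the subtracted constant over [lo, hi]
            with np.errstate(divide="ignore", invalid="ignore"):
                log_term = np.where(
                    inside, np.log(np.abs((q[:, 0] - lo) / (hi - q[:, 0]))), 0.0
                )
            out[k : k + 256] = (pv + re_q * log_term) / np.pi
        return out

    def im(self, omega) -> np.ndarray:
        """Imaginary part of C(omega), interpolated from the tabulated transform."""
        w = np.asarray(omega, dtype=float)
        out = np.interp(w, self._query, self._query_im)
        return out if w.ndim else float(out)


def line_broadening_g(
    tgrid: np.ndarray,
    density: SpectralDensity,
    temperature: float,
    n_quad: int | None = None,
) -> np.ndarray:
    """Line-broadening function G(t) for unit exciton-bath weight.

    G(t) = int_0^inf dw J(w) [ (1+n(w)) e^{-2 pi i w t} + n(w) e^{+2 pi i w t} ]

    with t in cm.  Per exciton state the lineshape factor is
    exp(gamma * (G(t) - G(0))); G(0) is the thermally (coth-) weighted total
    bath Huang-Rhys factor, so exp(-G(0)) at T -> 0 is the zero-phonon weight
    exp(-S_bath).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t = np.asarray(tgrid, dtype=float)
    # quadrature grid: dense where J has structure, extended over its support;
    # the relative error of G(0) against adaptive quadrature is ~1e-4
    cutoff = density.support_cutoff(1e-12)
    w = np.concatenate(
        [
            np.arange(0.025, 10.0, 0.05),
            np.arange(10.0, 100.0, 0.5),
            np.arange(100.0, cutoff, 2.0),
        ]
    )
    jw = density(w)
    n = _bose(w, temperature)
    a = jw * (1.0 + n)
    b = jw * n
    # trapezoid weights
    quad_w = np.empty_like(w)
    quad_w[1:-1] = 0.5 * (w[2:] - w[:-2])
    quad_w[0] = 0.5 * (w[1] - w[0]) + w[0]  # extend to 0 (integrand -> 0 as w^2)
    quad_w[-1] = 0.5 * (w[-1] - w[-2])
    aw = a * quad_w
    bw = b * quad_w
    out = np.empty(t.shape, dtype=complex)
    chunk = max(1, int(4e6 // len(w)))
    for k in range(0, len(t), chunk):
        phase = np.exp(-2j * np.pi * np.outer(t[k : k + chunk], w))
        out[k : k + chunk] = phase @ aw + np.conj(phase) @ bw
    return out


@dataclass
class LineshapeTerms:
    """Per-exciton-state lineshape ingredients.

    ``omega_renorm``: renormalized transition frequencies (cm^-1);
    ``gamma_ltb``: lifetime-broadening rate matrix (cm^-1);
    ``dephasing_hwhm``: 0.5 * sum_beta Gamma[alpha, beta], the Lorentzian
    half-width of each line (cm^-1); ``tau_fs`` the corresponding dephasing
    times in fs (capped at ``tau_max_fs``); ``gamma_diag`` the exciton-bath
    weights gamma_{alpha alpha alpha alpha} scaling G(t).
    """

    omega_renorm: np.ndarray
    gamma_ltb: np.ndarray
    dephasing_hwhm: np.ndarray
    tau_fs: np.ndarray
    gamma_diag: np.ndarray
    reorganization: float
    temperature: float


def lifetimes(
    energies: np.ndarray,
    gamma: np.ndarray,
    correlation: BathCorrelation,
    tau_max_fs: float = 3000.0,
) -> LineshapeTerms:
    """Renormalized energies, lifetime-broadening rates and dephasing times.

    omega~_alpha = omega_alpha - gamma_aa * lambda
                   + sum_{beta != alpha} gamma_ab Im C(omega_ab)
    Gamma_ab = 2 gamma_ab Re C(omega_ab);  tau_alpha = [1/2 sum_b Gamma_ab]^-1.

    The dephasing Lorentzian half-width is floored by ``tau_max_fs`` (states
    with no downhill relaxation would otherwise produce an undamped tail).
    """
    energies = np.asarray(energies, dtype=float)
    n = len(energies)
    omega_ab = energies[:, None] - energies[None, :]
    re_c = correlation.re(omega_ab.ravel()).reshape(n, n)
    im_c = correlation.im(omega_ab.ravel()).reshape(n, n)
    gamma_ltb = 2.0 * gamma * re_c
    np.fill_diagonal(gamma_ltb, 0.0)  # Re C(0) = 0: no pure dephasing term
    if np.any(gamma_ltb < -1e-10):
        raise ValueError("negative lifetime-broadening rate")
    gamma_ltb = np.clip(gamma_ltb, 0.0, None)

    lam = correlation.density.reorganization_energy
    gamma_diag = np.diag(gamma).copy()
    shift = (gamma * im_c).sum(axis=1) - np.diag(gamma * im_c)
    omega_renorm = energies - gamma_diag * lam + shift

    hwhm = 0.5 * gamma_ltb.sum(axis=1)
    hwhm_floor = 1.0 / (2.0 * np.pi * C_CM_PER_FS * tau_max_fs)
    hwhm = np.maximum(hwhm, hwhm_floor)
    tau_fs = 1.0 / (2.0 * np.pi * C_CM_PER_FS * hwhm)
    return LineshapeTerms(
        omega_renorm=omega_renorm,
        gamma_ltb=gamma_ltb,
        dephasing_hwhm=hwhm,
        tau_fs=tau_fs,
        gamma_diag=gamma_diag,
        reorganization=lam,
        temperature=correlation.temperature,
    )
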