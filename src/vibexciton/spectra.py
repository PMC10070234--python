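"""Absorption and circular-dichroism spectra.

For every exciton state alpha the optical correlation function is

    C_alpha(t) = exp(-2 pi i (omega~_alpha - center) t)
                 * exp(gamma_alpha (G(t) - G(0)))
                 * exp(-t / tau_alpha),

with t in cm (conjugate to cm^-1).  The absorption correlation function
weights C_alpha by |mu_exc,alpha|^2 and the CD one by the rotational
strength Im(mu . m) = mu_exc . (R x mu)_exc (times an implicit i); the
isotropic orientational average contributes a global factor 1/3.  One-sided
Fourier transforms give sigma_abs = Re FT and sigma_CD = Im FT.

Static (inhomogeneous) disorder is handled by Monte-Carlo sampling: the
electronic 0-0 energies of every pigment are shifted by independent Gaussian
draws, the vibronic system is re-diagonalized per realization (site-energy
shifts enter before the mixing, which is what localizes exciton states with
small Franck-Condon-scaled couplings), and the spectra are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bath import BathCorrelation, SpectralDensity, LineshapeTerms, lifetimes, line_broadening_g
from .dimer import ExcitonDecomposition, ExcitonSystem, diagonalize
from .units import C_CM_PER_FS, fwhm_to_sigma

__all__ = [
    "TimeGrid",
    "DisorderModel",
    "SpectrumResult",
    "SpectrumEngine",
    "fourier_spectrum",
    "correlation_functions",
    "disorder_average",
    "ablation_suite",
    "integrate_band",
    "cd_sideband_ratio",
    "rescale_to_positive_peak",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid in cm; the conjugate frequency step is 1/(n dt)."""

    n: int = 32768
    dt: float = 1.0 / 16384.0

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def freq_step(self) -> float:
        return 1.0 / (self.n * self.dt)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def frequencies(self) -> np.ndarray:
        """Frequency axis (fftshifted, ascending) relative to the rotating frame."""
        return np.fft.fftshift(np.fft.fftfreq(self.n, self.dt))


@dataclass(frozen=True)
class DisorderModel:
    """Gaussian static disorder of the pigment site energies.

    ``fwhm`` maps electronic state labels to the full width at half maximum of
    the Gaussian distribution (cm^-1).  Each pigment and, by default, each
    electronic state is drawn independently; ``correlated=True`` reuses the
    Qy draw (scaled by the FWHM ratio) for every state of a pigment.
    """

    fwhm: Mapping[str, float] = field(default_factory=dict)
    correlated: bool = False
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fwhm", dict(self.fwhm))
        if any(v < 0 for v in self.fwhm.values()):
            raise ValueError("disorder FWHM must be non-negative")
        if self.n_samples < 1:
            raise ValueError("sample count must be >= 1")

    def draw(self, rng: np.random.Generator, n_pigments: int) -> list[dict[str, float]]:
        shifts = []
        for _ in range(n_pigments):
            if self.correlated:
                u = rng.standard_normal()
                shifts.append(
                    {s: u * fwhm_to_sigma(f) for s, f in self.fwhm.items()}
                )
            else:
                shifts.append(
                    {
                        s: rng.standard_normal() * fwhm_to_sigma(f)
                        for s, f in self.fwhm.items()
                    }
                )
        return shifts


@dataclass
class SpectrumResult:
    """Frequency grid with paired absorption and CD intensities.

    Frequencies are in cm^-1 relative to the nominal Qy 0-0 energy.
    Absorption is in relative dipole-strength units, CD in relative
    rotational-strength units.
    """

    frequencies: np.ndarray
    absorption: np.ndarray
    cd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle = open(handle, "w")
            close = True
        try:
            handle.write("wavenumber_cm-1\tabsorption\tcd\n")
            for f, a, c in zip(self.frequencies, self.absorption, self.cd):
                handle.write(f"{f:.6f}\t{a:.8e}\t{c:.8e}\n")
        finally:
            if close:
                handle.close()

    def crop(self, lo: float, hi: float) -> "SpectrumResult":
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        return SpectrumResult(
            self.frequencies[sel], self.absorption[sel], self.cd[sel],
            dict(self.metadata),
        )


def correlation_functions(
    decomposition: ExcitonDecomposition,
    terms: LineshapeTerms,
    tgrid: TimeGrid,
    g_minus_g0: np.ndarray,
    center: float = 0.0,
    weight_floor: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-domain absorption and CD correlation functions.

    ``g_minus_g0`` is the unit-weight line-broadening trajectory G(t) - G(0)
    sampled on ``tgrid``.  States whose absorption and rotational weights are
    both negligible (relative floor ``weight_floor``) are skipped; the total
    dipole and rotational strengths are conserved to that accuracy.
    """
    w_abs = decomposition.dipole_strength / 3.0
    w_cd = decomposition.rotational_strength / 3.0
    scale_abs = w_abs.max() if w_abs.size else 0.0
    scale_cd = np.abs(w_cd).max() if w_cd.size else 0.0
    active = np.zeros(len(w_abs), dtype=bool)
    if scale_abs > 0:
        active |= w_abs > weight_floor * scale_abs
    if scale_cd > 0:
        active |= np.abs(w_cd) > weight_floor * scale_cd

    t = tgrid.t
    tau_cm = C_CM_PER_FS * terms.tau_fs
    omega = terms.omega_renorm - center
    if np.any(np.abs(omega[active]) > 0.98 * tgrid.nyquist):
        warnings.warn(
            "transition beyond the Nyquist range of the time grid; "
            "its line will alias", stacklevel=2,
        )

    c_abs = np.zeros(tgrid.n, dtype=complex)
    c_cd = np.zeros(tgrid.n, dtype=complex)
    idx = np.flatnonzero(active)
    z = -2j * np.pi * omega - 1.0 / tau_cm
    chunk = max(1, int(4e6 // tgrid.n))
    for k in range(0, len(idx), chunk):
        sel = idx[k : k + chunk]
        ampl = np.exp(
            np.outer(z[sel], t) + np.outer(terms.gamma_diag[sel], g_minus_g0)
        )
        c_abs += w_abs[sel] @ ampl
        c_cd += w_cd[sel] @ ampl
    # the magnetic dipole carries a factor i; restore it here so that the
    # printed Im-part selection of the CD Fourier transform applies
    return c_abs, 1j * c_cd


def fourier_spectrum(
    c_of_t: np.ndarray,
    tgrid: TimeGrid,
    kind: str,
    center: float = 0.0,
    tail_tol: float = 1e-4,
    tail_ref: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Fourier transform of a correlation function.

    Returns (frequencies, intensity) with sigma_abs = Re{int_0^inf e^{2 pi i
    nu t} C(t) dt} for kind="abs" and the imaginary part for kind="cd".  The
    first sample enters with trapezoid weight 1/2.  A warning is emitted when
    C(t) has not decayed at the end of the grid relative to ``tail_ref``
    (default: the peak of |C|; for CD the incoherent sum of |weights| is the
    meaningful reference, since the rotational strengths cancel at t = 0).
    """
    c_of_t = np.asarray(c_of_t)
    peak = np.abs(c_of_t).max() if tail_ref is None else tail_ref
    if peak > 0 and np.abs(c_of_t[-1]) > tail_tol * peak:
        warnings.warn(
            "correlation function not decayed at the end of the time grid "
            f"(|C(t_max)|/|C|_max = {np.abs(c_of_t[-1]) / peak:.2e})",
            stacklevel=2,
        )
    transform = tgrid.dt * (tgrid.n * np.fft.ifft(c_of_t) - 0.5 * c_of_t[0])
    transform = np.fft.fftshift(transform)
    if kind == "abs":
        intensity = transform.real
    elif kind == "cd":
        intensity = transform.imag
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    return tgrid.frequencies + center, intensity


# module-level caches for the expensive bath tabulations; keyed by the frozen
# dataclasses, so physically identical configurations share one computation
_CORRELATION_CACHE: dict = {}
_G_CACHE: dict = {}


class SpectrumEngine:
    """Caches the bath ingredients and turns exciton systems into spectra."""

    def __init__(
        self,
        density: SpectralDensity | None = None,
        temperature: float = 300.0,
        tgrid: TimeGrid | None = None,
        tau_max_fs: float = 3000.0,
        window: tuple[float, float] | None = None,
    ):
        self.density = density or SpectralDensity()
        self.temperature = temperature
        self.tgrid = tgrid or TimeGrid()
        self.tau_max_fs = tau_max_fs
        self.window = window
        self._correlation: BathCorrelation | None = None
        self._g_minus_g0: np.ndarray | None = None

    @property
    def correlation(self) -> BathCorrelation:
        if self._correlation is None:
            key = (self.density, self.temperature)
            if key not in _CORRELATION_CACHE:
                _CORRELATION_CACHE[key] = BathCorrelation(*key)
            self._correlation = _CORRELATION_CACHE[key]
        return self._correlation

    @property
    def g_minus_g0(self) -> np.ndarray:
        if self._g_minus_g0 is None:
            key = (self.density, self.temperature, self.tgrid)
            if key not in _G_CACHE:
                g = line_broadening_g(self.tgrid.t, self.density, self.temperature)
                _G_CACHE[key] = g - g[0]
            self._g_minus_g0 = _G_CACHE[key]
        return self._g_minus_g0

    def pick_center(self, system: ExcitonSystem) -> float:
        """Rotating-frame center from the undisordered transition range."""
        energies = np.linalg.eigvalsh(system.hamiltonian)
        return float(0.5 * (energies.min() + energies.max()))

    def lineshape_terms(self, decomposition: ExcitonDecomposition) -> LineshapeTerms:
        return lifetimes(
            decomposition.energies, decomposition.gamma, self.correlation,
            self.tau_max_fs,
        )

    def spectrum(
        self,
        system: ExcitonSystem,
        center: float | None = None,
        metadata: dict | None = None,
    ) -> SpectrumResult:
        """Homogeneous absorption/CD spectrum of one realization."""
        if center is None:
            center = self.pick_center(system)
        decomposition = diagonalize(system)
        terms = self.lineshape_terms(decomposition)
        c_abs, c_cd = correlation_functions(
            decomposition, terms, self.tgrid, self.g_minus_g0, center
        )
        freqs, sigma_abs = fourier_spectrum(c_abs, self.tgrid, "abs", center)
        scale_cd = float(np.abs(decomposition.rotational_strength).sum()) / 3.0
        _, sigma_cd = fourier_spectrum(
            c_cd, self.tgrid, "cd", center, tail_ref=scale_cd or None
        )
        result = SpectrumResult(freqs, sigma_abs, sigma_cd, metadata or {})
        if self.window is not None:
            result = result.crop(*self.window)
        return result


def disorder_average(
    engine: SpectrumEngine,
    system: ExcitonSystem,
    disorder: DisorderModel,
    n_samples: int | None = None,
    seed: int | None = None,
    metadata: dict | None = None,
) -> SpectrumResult:
    """Monte-Carlo average over Gaussian site-energy disorder.

    Each realization shifts every pigment's electronic 0-0 energies by
    independent Gaussian draws and recomputes the full spectrum (including
    re-diagonalization and lifetime broadening).  Deterministic for a fixed
    seed.
    """
    n_samples = disorder.n_samples if n_samples is None else n_samples
    seed = disorder.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    center = engine.pick_center(system)
    acc_abs = acc_cd = None
    freqs = None
    for _ in range(n_samples):
        shifts = disorder.draw(rng, system.n_pigments)
        result = engine.spectrum(system.with_site_shifts(shifts), center=center)
        if acc_abs is None:
            freqs = result.frequencies
            acc_abs = result.absorption.copy()
            acc_cd = result.cd.copy()
        else:
            acc_abs += result.absorption
            acc_cd += result.cd
    meta = dict(metadata or {})
    meta.update(n_samples=n_samples, seed=seed, fwhm=dict(disorder.fwhm))
    return SpectrumResult(freqs, acc_abs / n_samples, acc_cd / n_samples, meta)


# ---------------------------------------------------------------------------
# Analysis helpers
# ---------------------------------------------------------------------------


def integrate_band(
    result: SpectrumResult,
    lo: float,
    hi: float,
    signal: str = "absorption",
    absolute: bool = False,
) -> float:
    """Trapezoid integral of a spectrum over [lo, hi]."""
    y = result.absorption if signal == "absorption" else result.cd
    sel = (result.frequencies >= lo) & (result.frequencies <= hi)
    y = np.abs(y[sel]) if absolute else y[sel]
    return float(np.trapezoid(y, result.frequencies[sel]))


def cd_sideband_ratio(
    result: SpectrumResult,
    sideband_from: float = 500.0,
    origin_region: tuple[float, float] = (-500.0, 500.0),
) -> float:
    """Integrated |CD| in the sideband region divided by the 0-0 region."""
    hi = float(result.frequencies.max())
    side = integrate_band(result, sideband_from, hi, "cd", absolute=True)
    origin = integrate_band(result, *origin_region, "cd", absolute=True)
    if origin <= 0:
        raise ValueError("vanishing CD in the 0-0 region")
    return side / origin


def rescale_to_positive_peak(
    results: Sequence[SpectrumResult],
    window: tuple[float, float] | None = None,
) -> list[SpectrumResult]:
    """Rescale CD spectra so their positive peaks share a common amplitude."""
    out = []
    for r in results:
        cropped = r if window is None else r.crop(*window)
        peak = cropped.cd.max()
        if peak <= 0:
            raise ValueError("spectrum has no positive CD peak in the window")
        out.append(
            SpectrumResult(
                r.frequencies, r.absorption.copy(), r.cd / peak, dict(r.metadata)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ablation suite
# ---------------------------------------------------------------------------

#: model variants in the order of increasing completeness
ABLATION_VARIANTS = (
    "qy-electronic",      # Qy only, no intramolecular vibrations
    "qy-vibrations",      # Qy with its Franck-Condon progression
    "qy-qx",              # + Qx with vibrations, no vibronic coupling
    "vibronic",           # + Qy-Qx vibronic coupling
    "full",               # + By/Bx electronic states
    "vibronic-00",        # vibronic model, couplings between 0-0 only (dimer)
    "full-00",            # full model, couplings between 0-0 only (dimer)
)


def ablation_suite(
    config,
    variants: Sequence[str] | None = None,
    inhomogeneous: bool = True,
    n_samples: int | None = None,
    seed: int | None = None,
) -> dict[str, SpectrumResult]:
    """Run the step-by-step model ablations on a run configuration.

    Starts from a minimal Qy-only electronic model and successively enables
    intramolecular vibrations, the Qx state, the vibronic Qy-Qx coupling and
    the Soret (By/Bx) states; for dimers the additional ``*-00`` variants
    restrict the excitonic coupling to the 0-0 transitions.
    """
    from . import config as config_mod

    variants = tuple(variants) if variants is not None else ABLATION_VARIANTS
    results: dict[str, SpectrumResult] = {}
    for name in variants:
        if name not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {name!r}")
        if name.endswith("-00") and config.system == "monomer":
            continue
        variant_cfg = config_mod.apply_variant(config, name)
        engine = config_mod.build_engine(variant_cfg)
        system = config_mod.build_system(variant_cfg)
        meta = {"variant": name, "coupling_mask": variant_cfg.coupling.mask}
        if inhomogeneous:
            disorder = config_mod.build_disorder(variant_cfg)
            results[name] = disorder_average(
                engine, system, disorder, n_samples=n_samples, seed=seed,
                metadata=meta,
            )
        else:
            res = engine.spectrum(system, metadata=meta)
            results[name] = res
    return results
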