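"""Spectra: Fourier transforms, sum rules, disorder averaging, ablations."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.special import voigt_profile

import vibexciton as vx
from vibexciton.bath import SpectralDensity
from vibexciton.dimer import assemble_dimer, diagonalize, monomer_system
from vibexciton.spectra import (
    DisorderModel,
    SpectrumEngine,
    TimeGrid,
    ablation_suite,
    cd_sideband_ratio,
    disorder_average,
    integrate_band,
    rescale_to_positive_peak,
)
from vibexciton.units import C_CM_PER_FS, fwhm_to_sigma

from test_dimer import electronic_monomer, simple_geom

ZERO_BATH = SpectralDensity(0.0, 0.0, 0.557, 1.94)
SMALL_GRID = TimeGrid(8192, 1.0 / 4096.0)


def bare_engine(tau_max_fs=3000.0, tgrid=SMALL_GRID):
    """Engine with a switched-off bath: pure Lorentzian lines."""
    return SpectrumEngine(ZERO_BATH, 300.0, tgrid, tau_max_fs=tau_max_fs)


class TestFourierSpectrum:
    def test_single_state_is_lorentzian(self):
        engine = bare_engine()
        system = monomer_system(electronic_monomer())
        res = engine.spectrum(system)
        hwhm = 1.0 / (2.0 * np.pi * C_CM_PER_FS * 3000.0)
        span = engine.tgrid.n * engine.tgrid.freq_step

        def lorentz(nu):
            return (1.0 / 3.0) * hwhm / (2.0 * np.pi * (hwhm**2 + nu**2))

        # the discrete transform is periodic: include the aliased images
        expected = sum(lorentz(res.frequencies + k * span) for k in (-1, 0, 1))
        sel = np.abs(res.frequencies) < 500.0
        assert np.allclose(res.absorption[sel], expected[sel], rtol=2e-3)

    def test_parseval_identity(self):
        """Grid integral of sigma_abs equals C_abs(0) / 2 (one-sided FT)."""
        engine = bare_engine()
        system = monomer_system(electronic_monomer())
        res = engine.spectrum(system)
        total = res.absorption.sum() * engine.tgrid.freq_step
        c0 = (system.electric_dipoles**2).sum() / 3.0
        assert total == pytest.approx(c0 / 2.0, rel=1e-3)

    def test_real_weight_gives_zero_cd(self):
        """A state whose rotational strength vanishes contributes no CD."""
        engine = bare_engine()
        res = engine.spectrum(monomer_system(electronic_monomer()))
        assert np.allclose(res.cd, 0.0, atol=1e-15)


class TestSumRules:
    def test_absorption_integral_invariant_under_masks(self, wscp_config):
        totals = {}
        for mask in ("all", "zero-zero", "none"):
            data = wscp_config.model_dump()
            data["coupling"]["mask"] = mask
            cfg = vx.RunConfig.model_validate(data)
            engine = vx.build_engine(cfg)
            engine.window = None
            res = engine.spectrum(vx.build_system(cfg))
            totals[mask] = res.absorption.sum() * engine.tgrid.freq_step
        base = totals["all"]
        for mask, val in totals.items():
            assert val == pytest.approx(base, rel=5e-3), mask

    def test_cd_integrates_to_zero(self, wscp_hom_spectrum):
        """Conservative total CD: the signed integral vanishes relative to the
        integral of |CD|."""
        f = wscp_hom_spectrum.frequencies
        signed = np.trapezoid(wscp_hom_spectrum.cd, f)
        total = np.trapezoid(np.abs(wscp_hom_spectrum.cd), f)
        assert abs(signed) < 1e-3 * total

    def test_cd_vanishes_without_coupling(self, wscp_config):
        data = wscp_config.model_dump()
        data["coupling"]["mask"] = "none"
        cfg = vx.RunConfig.model_validate(data)
        res = vx.build_engine(cfg).spectrum(vx.build_system(cfg))
        assert np.allclose(res.cd, 0.0, atol=1e-15)

    def test_dimer_without_coupling_is_twice_the_monomer(self, wscp_config):
        """J = 0 reduces the dimer code to two independent monomers."""
        params = vx.build_monomer_params(wscp_config)
        from vibexciton.monomer import assemble_monomer

        mon = assemble_monomer(params)
        geom_a, geom_b = vx.build_geometry(wscp_config)
        dimer = assemble_dimer(
            mon, mon, geom_a, geom_b, vx.CouplingMatrix.zero(), "all"
        )
        engine = vx.build_engine(wscp_config)
        res_d = engine.spectrum(dimer)
        res_m = engine.spectrum(monomer_system(mon), center=engine.pick_center(dimer))
        peak = res_d.absorption.max()
        assert np.max(np.abs(res_d.absorption - 2.0 * res_m.absorption)) < 1e-6 * peak
        assert np.allclose(res_d.cd, 0.0, atol=1e-15)


class TestDisorderAverage:
    def test_zero_fwhm_equals_homogeneous(self, wscp_engine, wscp_system):
        disorder = DisorderModel(fwhm={}, n_samples=3, seed=0)
        hom = wscp_engine.spectrum(wscp_system)
        avg = disorder_average(wscp_engine, wscp_system, disorder)
        # identical realizations; only the (x+x+x)/3 averaging rounds
        assert np.allclose(hom.absorption, avg.absorption, rtol=1e-12, atol=0.0)
        assert np.allclose(hom.cd, avg.cd, rtol=1e-12, atol=0.0)

    def test_deterministic_for_fixed_seed(self, wscp_engine, wscp_system):
        disorder = DisorderModel(fwhm={"Qy": 170.0}, n_samples=5, seed=123)
        r1 = disorder_average(wscp_engine, wscp_system, disorder)
        r2 = disorder_average(wscp_engine, wscp_system, disorder)
        assert np.array_equal(r1.absorption, r2.absorption)
        assert np.array_equal(r1.cd, r2.cd)

    @pytest.mark.filterwarnings("ignore:correlation function not decayed")
    def test_gaussian_line_from_site_disorder(self):
        """A single transition with FWHM = 240 cm^-1 site disorder and
        negligible homogeneous width averages to a Gaussian of that FWHM.

        The Monte-Carlo average is compared pointwise against the analytic
        mean of Lorentzians centered at the very same Gaussian draws, and the
        fitted width against the nominal 240 cm^-1 within the statistical
        spread of the shape estimator at 5000 samples.
        """
        engine = bare_engine(tau_max_fs=10000.0)
        system = monomer_system(electronic_monomer())
        disorder = DisorderModel(fwhm={"Qy": 240.0}, n_samples=5000, seed=42)
        avg = disorder_average(engine, system, disorder)

        rng = np.random.default_rng(42)
        draws = fwhm_to_sigma(240.0) * rng.standard_normal(5000)
        hwhm = 1.0 / (2.0 * np.pi * C_CM_PER_FS * 10000.0)
        delta = avg.frequencies[None, :] - draws[:, None]
        reference = (
            (1.0 / 3.0) * hwhm / (2.0 * np.pi * (hwhm**2 + delta**2))
        ).mean(axis=0)
        peak = reference.max()
        assert np.max(np.abs(avg.absorption - reference)) < 3e-3 * peak

        def gauss(x, amp, x0, sigma):
            return amp * np.exp(-((x - x0) ** 2) / (2 * sigma**2))

        sel = np.abs(avg.frequencies) < 700.0
        p0 = (peak, 0.0, 100.0)
        popt, _ = curve_fit(gauss, avg.frequencies[sel], avg.absorption[sel], p0=p0)
        fwhm = abs(popt[2]) * 2 * np.sqrt(2 * np.log(2))
        assert fwhm == pytest.approx(240.0, abs=12.0)

    @pytest.mark.filterwarnings("ignore:correlation function not decayed")
    def test_monte_carlo_error_scales_as_inverse_sqrt_n(self):
        """The spread between independent averages shrinks as 1/sqrt(N)."""
        engine = bare_engine(tau_max_fs=10000.0)
        system = monomer_system(electronic_monomer())
        errors = {}
        for n in (250, 1000, 4000):
            runs = [
                disorder_average(
                    engine, system,
                    DisorderModel(fwhm={"Qy": 240.0}, n_samples=n, seed=seed),
                )
                for seed in (2 * n, 2 * n + 1)
            ]
            errors[n] = float(
                np.sqrt(np.mean((runs[0].absorption - runs[1].absorption) ** 2))
            )
        assert errors[250] / errors[1000] == pytest.approx(2.0, rel=0.5)
        assert errors[250] / errors[4000] == pytest.approx(4.0, rel=0.5)

    def test_correlated_disorder_shifts_states_together(self):
        model = DisorderModel(fwhm={"Qy": 100.0, "Qx": 200.0}, correlated=True,
                              n_samples=1, seed=1)
        rng = np.random.default_rng(0)
        shifts = model.draw(rng, 1)[0]
        assert shifts["Qx"] / shifts["Qy"] == pytest.approx(2.0)


class TestAnalysisHelpers:
    def test_integrate_band_absolute(self, wscp_hom_spectrum):
        full = integrate_band(wscp_hom_spectrum, -2000.0, 12000.0, "cd",
                              absolute=True)
        assert full > 0
        signed = integrate_band(wscp_hom_spectrum, -2000.0, 12000.0, "cd")
        assert abs(signed) < 1e-3 * full

    def test_rescale_to_positive_peak(self, wscp_hom_spectrum):
        out, = rescale_to_positive_peak([wscp_hom_spectrum], window=(-500.0, 500.0))
        assert out.crop(-500.0, 500.0).cd.max() == pytest.approx(1.0)

    def test_sideband_ratio_positive(self, wscp_hom_spectrum):
        assert cd_sideband_ratio(wscp_hom_spectrum) > 0


class TestAblationSuite:
    def test_minimal_monomer_is_single_line(self, ether_config):
        results = ablation_suite(
            ether_config, variants=("qy-electronic",), inhomogeneous=False
        )
        res = results["qy-electronic"]
        a = res.absorption
        above = a > 0.05 * a.max()
        # one contiguous band only
        edges = np.diff(above.astype(int))
        assert (edges == 1).sum() == 1

    def test_variant_ladder_monomer(self, ether_config):
        results = ablation_suite(
            ether_config,
            variants=("qy-vibrations", "vibronic"),
            inhomogeneous=False,
        )
        novc = results["qy-vibrations"]
        vc = results["vibronic"]
        # vibronic coupling moves intensity into the 1800-2600 region
        hi_vc = integrate_band(vc, 1800.0, 2600.0)
        hi_novc = integrate_band(novc, 1800.0, 2600.0)
        assert hi_vc > 2.0 * hi_novc

    def test_zero_zero_mask_variant_differs(self, wscp_config):
        results = ablation_suite(
            wscp_config, variants=("vibronic", "vibronic-00"), inhomogeneous=False
        )
        full = results["vibronic"]
        only00 = results["vibronic-00"]
        assert only00.metadata["coupling_mask"] == "zero-zero"
        assert not np.allclose(full.cd, only00.cd)
        # total absorption is conserved by the mask
        f = full.frequencies
        assert np.trapezoid(full.absorption, f) == pytest.approx(
            np.trapezoid(only00.absorption, f), rel=5e-3
        )

    def test_unknown_variant_rejected(self, wscp_config):
        with pytest.raises(ValueError, match="variant"):
            ablation_suite(wscp_config, variants=("everything-at-once",))
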