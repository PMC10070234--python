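"""Excitonic couplings, OPA dimer assembly, and the exciton decomposition."""

import numpy as np
import pytest

import vibexciton as vx
from vibexciton.dimer import (
    assemble_dimer,
    diagonalize,
    dipole_dipole_coupling,
    magnetic_dipoles,
    monomer_system,
    orientation_factor,
    scaled_couplings,
)
from vibexciton.geometry import PigmentGeometry
from vibexciton.modes import (
    ElectronicState,
    ModeCatalog,
    MonomerParams,
    VibrationalMode,
    VibronicCouplingMode,
)
from vibexciton.monomer import assemble_monomer
from vibexciton.units import KAPPA_DIPOLE

X, Y, Z = np.eye(3)


def simple_geom(center, qy=Y):
    qy = np.asarray(qy, float)
    qy = qy / np.linalg.norm(qy)
    return PigmentGeometry(center, {"Qy": qy, "Qx": X, "By": Y, "Bx": X})


def electronic_monomer(f=1.0):
    """A single-state pigment without vibrational structure."""
    params = MonomerParams(
        states=(ElectronicState("Qy", 0.0, f),),
        modes=ModeCatalog([]),
        vc_mode=VibronicCouplingMode(1500.0, 0.0, 0),
    )
    return assemble_monomer(params)


def vibrational_monomer(s=0.25, w=1200.0):
    params = MonomerParams(
        states=(ElectronicState("Qy", 0.0, 1.0),),
        modes=ModeCatalog([VibrationalMode(w, {"Qy": s})]),
        vc_mode=VibronicCouplingMode(1500.0, 0.0, 0),
    )
    return assemble_monomer(params)


class TestOrientationFactor:
    def test_parallel_perpendicular_to_axis(self):
        assert orientation_factor(Y, Y, Z) == pytest.approx(1.0)

    def test_collinear_head_to_tail(self):
        assert orientation_factor(Z, Z, Z) == pytest.approx(-2.0)

    def test_random_orientations_match_direct_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            e_m, e_n, e_ab = (v / np.linalg.norm(v) for v in rng.standard_normal((3, 3)))
            expected = e_m @ e_n - 3 * (e_m @ e_ab) * (e_n @ e_ab)
            assert orientation_factor(e_m, e_n, e_ab) == pytest.approx(expected)


class TestCouplings:
    def test_point_dipole_value(self):
        geom_a = simple_geom(np.zeros(3))
        geom_b = simple_geom(10.0 * Z)
        j = dipole_dipole_coupling(geom_a, geom_b, "Qy", "Qy", 4.6, 4.6)
        assert j == pytest.approx(KAPPA_DIPOLE * 4.6**2 / 1000.0)

    def test_coincident_centers_rejected(self):
        g = simple_geom(np.zeros(3))
        with pytest.raises(ValueError, match="coincide"):
            dipole_dipole_coupling(g, g, "Qy", "Qy", 1.0, 1.0)

    def test_scaled_identity_for_equal_ratios_and_geometry(self):
        geom_a = simple_geom(np.zeros(3))
        geom_b = simple_geom(10.0 * Z)
        j = scaled_couplings(geom_a, geom_b, {"Qy": 1.0, "By": 1.0},
                             j_qyqy=83.0, labels=("Qy", "By"))
        # all dipoles parallel and perpendicular to the axis: every J = J_QyQy
        assert np.allclose(j.values, 83.0)

    def test_vanishing_reference_zeta_rejected(self):
        # magic-angle arrangement: zeta_QyQy = 1 - 3 cos^2(theta) = 0
        c = np.sqrt(1.0 / 3.0)
        tilted = np.array([np.sqrt(1 - c * c), 0.0, c])
        geom_a = PigmentGeometry(np.zeros(3), {"Qy": tilted})
        geom_b = PigmentGeometry(10.0 * Z, {"Qy": tilted})
        with pytest.raises(ValueError, match="orientation factor"):
            scaled_couplings(geom_a, geom_b, {"Qy": 1.0}, labels=("Qy",))


class TestAssembleDimer:
    def test_zero_coupling_eigenvalues_are_union(self, wscp_config):
        params = vx.build_monomer_params(wscp_config)
        mon = assemble_monomer(params)
        geom_a, geom_b = vx.make_open_sandwich()
        system = assemble_dimer(
            mon, mon, geom_a, geom_b, vx.CouplingMatrix.zero(), "all"
        )
        dec = diagonalize(system)
        mono_evals = np.linalg.eigvalsh(mon.matrix)
        assert np.allclose(dec.energies, np.sort(np.tile(mono_evals, 2)), atol=1e-9)

    def test_textbook_splitting_two_level_dimer(self):
        mon = electronic_monomer()
        j = vx.CouplingMatrix(("Qy",), np.array([[83.0]]))
        system = assemble_dimer(
            mon, mon, simple_geom(np.zeros(3)), simple_geom(10.0 * Z), j, "all"
        )
        dec = diagonalize(system)
        assert dec.energies[1] - dec.energies[0] == pytest.approx(166.0, abs=1e-9)

    def test_cross_coupling_scales_with_fc_amplitude(self):
        """0-0 <-> 0-1 coupling carries sqrt(S) relative to 0-0 <-> 0-0."""
        s = 0.25
        mon = vibrational_monomer(s=s)
        j = vx.CouplingMatrix(("Qy",), np.array([[83.0]]))
        system = assemble_dimer(
            mon, mon, simple_geom(np.zeros(3)), simple_geom(10.0 * Z), j, "all"
        )
        na = mon.size
        i00 = mon.basis.index(vx.VibronicBasisState("Qy", 0, None, 0))
        i01 = mon.basis.index(vx.VibronicBasisState("Qy", 0, 0, 1))
        v = system.hamiltonian[:na, na:]
        assert v[i00, i01] / v[i00, i00] == pytest.approx(np.sqrt(s), rel=1e-12)

    def test_zero_zero_mask_keeps_only_origin_couplings(self):
        mon = vibrational_monomer()
        j = vx.CouplingMatrix(("Qy",), np.array([[83.0]]))
        args = (mon, mon, simple_geom(np.zeros(3)), simple_geom(10.0 * Z), j)
        v_all = assemble_dimer(*args, "all").hamiltonian[: mon.size, mon.size :]
        v_00 = assemble_dimer(*args, "zero-zero").hamiltonian[: mon.size, mon.size :]
        i00 = mon.basis.index(vx.VibronicBasisState("Qy", 0, None, 0))
        assert v_00[i00, i00] == v_all[i00, i00]
        v_00[i00, i00] = 0.0
        assert not np.any(v_00)
        assert np.count_nonzero(v_all) > 1

    def test_unknown_mask_rejected(self):
        mon = electronic_monomer()
        j = vx.CouplingMatrix(("Qy",), np.array([[83.0]]))
        with pytest.raises(ValueError, match="mask"):
            assemble_dimer(
                mon, mon, simple_geom(np.zeros(3)), simple_geom(10.0 * Z), j,
                "only-the-good-ones",
            )


class TestMagneticDipoles:
    def test_pigment_at_origin_has_no_magnetic_dipole(self):
        mu = np.array([[0.0, 1.0, 0.0]])
        assert np.allclose(magnetic_dipoles(np.zeros(3), mu), 0.0)

    def test_rotational_strengths_translation_invariant(self, wscp_system, wscp_config):
        """A global shift of both pigment centers changes no R_alpha."""
        geom_a, geom_b = vx.build_geometry(wscp_config)
        offset = np.array([123.0, -45.0, 67.0])
        params = vx.build_monomer_params(wscp_config)
        mon = assemble_monomer(params)
        couplings = vx.build_couplings(wscp_config)
        shifted = assemble_dimer(
            mon, mon, geom_a.translated(offset), geom_b.translated(offset),
            couplings, "all",
        )
        r0 = diagonalize(wscp_system).rotational_strength
        r1 = diagonalize(shifted).rotational_strength
        assert np.allclose(r0, r1, atol=1e-9 * np.abs(r0).max())

    def test_chiral_pair_gives_opposite_couplet(self):
        """Two perpendicular dipoles at +-R/2 form a chiral pair whose exciton
        rotational strengths are equal and opposite (closed form: -+ R mu^2 / 2
        in these units)."""
        mon = electronic_monomer()
        geom_a = simple_geom(np.array([0.0, 0.0, -5.0]), qy=X)
        geom_b = simple_geom(np.array([0.0, 0.0, 5.0]), qy=Y)
        j = vx.CouplingMatrix(("Qy",), np.array([[50.0]]))
        dec = diagonalize(assemble_dimer(mon, mon, geom_a, geom_b, j, "all"))
        r = dec.rotational_strength
        assert r[0] == pytest.approx(-r[1], rel=1e-12)
        assert abs(r[0]) == pytest.approx(5.0, rel=1e-12)

    def test_localized_states_have_zero_rotational_strength(self, wscp_config):
        """With all couplings off, CD vanishes state by state."""
        params = vx.build_monomer_params(wscp_config)
        mon = assemble_monomer(params)
        geom_a, geom_b = vx.make_open_sandwich()
        system = assemble_dimer(
            mon, mon, geom_a, geom_b, vx.build_couplings(wscp_config), "none"
        )
        dec = diagonalize(system)
        assert np.allclose(dec.rotational_strength, 0.0, atol=1e-12)


class TestDiagonalize:
    def test_identity_hamiltonian_keeps_local_dipoles(self):
        mon = electronic_monomer()
        system = monomer_system(mon)
        dec = diagonalize(system)
        assert np.allclose(dec.coefficients, np.eye(1))
        assert np.allclose(dec.mu_exc, system.electric_dipoles)

    def test_degenerate_homodimer_delocalizes(self):
        mon = electronic_monomer()
        j = vx.CouplingMatrix(("Qy",), np.array([[83.0]]))
        system = assemble_dimer(
            mon, mon, simple_geom(np.zeros(3)), simple_geom(10.0 * Z), j, "all"
        )
        dec = diagonalize(system)
        assert np.allclose(np.abs(dec.coefficients), 1.0 / np.sqrt(2.0))
        ds = dec.dipole_strength
        # parallel dipoles: one bright in-phase state, one dark state
        assert ds.max() == pytest.approx(2.0, rel=1e-12)
        assert ds.min() == pytest.approx(0.0, abs=1e-12)

    def test_total_dipole_strength_conserved(self, wscp_system):
        dec = diagonalize(wscp_system)
        assert dec.dipole_strength.sum() == pytest.approx(
            float((wscp_system.electric_dipoles**2).sum()), abs=1e-10
        )

    def test_rotational_strength_sum_rule(self, wscp_system):
        dec = diagonalize(wscp_system)
        total = np.abs(dec.rotational_strength).sum()
        assert abs(dec.rotational_strength.sum()) < 1e-12 * max(total, 1.0)

    def test_gamma_diagonal_is_participation_ratio(self, wscp_system):
        dec = diagonalize(wscp_system)
        gamma_diag = np.diag(dec.gamma)
        assert np.all(gamma_diag > 0.5 - 1e-12)
        assert np.all(gamma_diag <= 1.0 + 1e-12)
        # delocalized 0-0 pair of a homodimer: gamma ~ 1/2
        basis = wscp_system.basis
        mask00 = np.array([b.electronic == "Qy" and b.vibrationless for b in basis])
        char00 = (dec.coefficients[mask00, :] ** 2).sum(axis=0)
        pair = np.argsort(char00)[-2:]
        assert np.all(gamma_diag[pair] < 0.6)

    def test_non_finite_hamiltonian_rejected(self):
        system = monomer_system(electronic_monomer())
        system.hamiltonian[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            diagonalize(system)
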