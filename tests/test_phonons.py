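"""Phonons, vibrational free energy, EOS fitting, and the QHA scan."""

import math

import numpy as np
import pytest

from cspkit import (
    CrystalStructure,
    Lattice,
    Molecule,
    RelaxSettings,
    SpringCalculator,
    birch_murnaghan_energy,
    f_vib,
    fit_birch_murnaghan,
    gibbs_ha,
    heat_capacity,
    hessian,
    mesh_spectrum,
    phonon_frequencies,
    qha,
    relax,
)
from cspkit.constants import HBAR, K_B, OMEGA_SI, get_element
from cspkit.fixtures import (
    FixtureSpec,
    VolumeEnergyCalculator,
    make_eos_data,
    make_fixture,
)
from cspkit.phonons import EOSFitError, ImaginaryModeError, PhononSpectrum
from cspkit.potentials import CompositeCalculator

M_AR = get_element("Ar").mass


class TestHessian:
    def test_diatomic_spring_frequency(self):
        k = 5.0
        mol = Molecule(["Ar", "Ar"], [[0, 0, 0], [1.5, 0, 0]], bonds=[(0, 1)])
        calc = SpringCalculator(bond_springs=[(0, 1, (0, 0, 0), k, 1.5)])
        fc = hessian(mol, calc, method="analytic")
        freqs = phonon_frequencies(fc, (0, 0, 0))
        expected = math.sqrt(2 * k / M_AR) * OMEGA_SI
        assert freqs.max() == pytest.approx(expected, rel=1e-8)

    def test_analytic_vs_finite_displacement(self):
        # argon-stiffness LJ: the 0.005 Å central-difference truncation
        # error stays below 1e-4 eV/Å² (it scales with the curvature scale)
        fx = make_fixture(FixtureSpec(
            "lj_fcc", size={"epsilon": 0.0104, "sigma": 3.4}))
        res = relax(fx.structure, fx.calculator,
                    RelaxSettings(mode="variable_cell"))
        fa = hessian(res.structure, fx.calculator, "analytic",
                     min_supercell_length=8.0)
        fd = hessian(res.structure, fx.calculator, "finite_displacement",
                     min_supercell_length=8.0)
        assert np.abs(fa.matrix - fd.matrix).max() < 1e-4

    def test_analytic_vs_finite_displacement_spring(self):
        # springs are harmonic in bond length, not Cartesian components, so
        # transverse FD entries carry a small geometric-nonlinearity residue
        fx = make_fixture(FixtureSpec("one_d_chain"))
        fa = hessian(fx.structure, fx.calculator, "analytic",
                     min_supercell_length=10.0)
        fd = hessian(fx.structure, fx.calculator, "finite_displacement",
                     min_supercell_length=10.0)
        assert np.abs(fa.matrix - fd.matrix).max() < 1e-4

    def test_hessian_symmetry_before_symmetrization(self, lj_fcc):
        fx, clean, _ = lj_fcc
        from cspkit.phonons import build_supercell
        sup, _ = build_supercell(clean, (2, 2, 2))
        H = fx.calculator.hessian(sup)
        assert np.abs(H - H.T).max() < 1e-6

    def test_supercell_ceiling_arithmetic(self):
        s = CrystalStructure(Lattice(np.eye(3) * 3.0), ["Ar"], [[0, 0, 0]])
        calc = SpringCalculator(bond_springs=[(0, 0, (1, 0, 0), 1.0, 3.0)])
        fc = hessian(s, calc, min_supercell_length=10.0)
        assert fc.reps == (4, 4, 4)


class TestPhononFrequencies:
    def test_1d_chain_dispersion(self):
        fx = make_fixture(FixtureSpec("one_d_chain"))
        fc = hessian(fx.structure, fx.calculator, min_supercell_length=10.0)
        for q in np.linspace(0.025, 0.475, 20):
            got = phonon_frequencies(fc, (q, 0, 0)).max()
            assert got == pytest.approx(fx.reference["dispersion"](q),
                                        rel=1e-8)

    def test_gamma_acoustic_modes_vanish(self, lj_fcc):
        fx, clean, _ = lj_fcc
        fc = hessian(clean, fx.calculator, min_supercell_length=8.0)
        g = np.abs(phonon_frequencies(fc, (0, 0, 0)))[:3]
        assert g.max() < 2 * math.pi * 1e9  # below 1e-3 THz

    def test_einstein_crystal_flat_bands(self):
        fx = make_fixture(FixtureSpec("einstein_crystal"))
        fc = hessian(fx.structure, fx.calculator, min_supercell_length=8.0,
                     enforce_asr=False)
        w0 = fx.reference["omega0"]
        for q in [(0, 0, 0), (0.5, 0, 0), (0.25, 0.25, 0.25)]:
            freqs = phonon_frequencies(fc, q)
            assert np.abs(freqs / w0 - 1).max() < 1e-10


def _single_mode_spectrum(hw_ev):
    return PhononSpectrum(np.zeros((1, 3)), [1.0],
                          np.array([[hw_ev / HBAR]]))


class TestFVib:
    def test_single_mode_zpe(self):
        assert f_vib(_single_mode_spectrum(0.01), 0.0) == pytest.approx(0.005)

    def test_single_mode_room_temperature(self):
        # 0.005 + k_B·300·ln(1 − e^(−0.01/k_B·300))
        kt = K_B * 300.0
        expected = 0.005 + kt * math.log(1 - math.exp(-0.01 / kt))
        got = f_vib(_single_mode_spectrum(0.01), 300.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.02439, abs=1e-5)

    def test_stiff_mode_approaches_zpe(self):
        spec = _single_mode_spectrum(5.0)
        assert f_vib(spec, 300.0) == pytest.approx(2.5, rel=1e-12)

    def test_decreasing_in_temperature(self):
        spec = _single_mode_spectrum(0.02)
        vals = [f_vib(spec, t) for t in (50, 150, 300, 500)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_imaginary_mode_policies(self):
        spec = PhononSpectrum(np.zeros((1, 3)), [1.0],
                              np.array([[-1e13, 1e13]]))
        with pytest.raises(ImaginaryModeError):
            f_vib(spec, 300.0, imaginary_policy="strict")
        dropped = f_vib(spec, 0.0, imaginary_policy="drop")
        assert dropped == pytest.approx(0.5 * HBAR * 1e13)

    def test_einstein_closed_form(self):
        fx = make_fixture(FixtureSpec("einstein_crystal"))
        fc = hessian(fx.structure, fx.calculator, min_supercell_length=8.0,
                     enforce_asr=False)
        spec = mesh_spectrum(fc, (4, 4, 4))
        w0 = fx.reference["omega0"]
        n = fx.reference["n_atoms"]
        for T in (0.0, 150.0, 300.0):
            hw = HBAR * w0
            closed = 3 * n * (hw / 2 + (K_B * T * math.log(1 - math.exp(
                -hw / (K_B * T))) if T > 0 else 0.0))
            assert f_vib(spec, T) == pytest.approx(closed, abs=1e-10)

    def test_extensivity_doubled_cell(self, lj_fcc):
        fx, clean, e0 = lj_fcc
        cell2 = clean.lattice.cell.copy()
        cell2[0] *= 2
        frac2 = np.vstack([clean.frac_coords * [0.5, 1, 1],
                           clean.frac_coords * [0.5, 1, 1] + [0.5, 0, 0]])
        doubled = CrystalStructure(Lattice(cell2), list(clean.species) * 2,
                                   frac2)
        assert fx.calculator.energy(doubled) == pytest.approx(2 * e0, rel=1e-8)
        fc1 = hessian(clean, fx.calculator, min_supercell_length=8.0)
        fc2 = hessian(doubled, fx.calculator, min_supercell_length=8.0)
        # meshes commensurate with the force-constant supercell, so the
        # doubled cell's folded bands cover exactly the primitive q-set
        s1 = mesh_spectrum(fc1, (2, 2, 2))
        s2 = mesh_spectrum(fc2, (1, 2, 2))
        for T in (0.0, 300.0):
            assert f_vib(s2, T) == pytest.approx(2 * f_vib(s1, T), rel=1e-8)


class TestGibbsHA:
    def test_plain_sum(self):
        spec = _single_mode_spectrum(1.0)
        pt = gibbs_ha(-10.0, spec, 0.0, p=0.0, V=100.0)
        assert pt.G == pytest.approx(-10.0 + 0.5)

    def test_pressure_volume_work(self):
        spec = _single_mode_spectrum(1.0)
        g0 = gibbs_ha(-10.0, spec, 0.0, p=0.0, V=100.0).G
        g1 = gibbs_ha(-10.0, spec, 0.0, p=1e-9, V=100.0).G
        assert g1 - g0 == pytest.approx(1e-7, rel=1e-9)


class TestBirchMurnaghan:
    PARAMS = (-1.0, 100.0, 0.5, 4.0)

    def test_exact_roundtrip(self):
        V, F = make_eos_data(self.PARAMS, n_points=17)
        fit, rms = fit_birch_murnaghan(V, F)
        for got, ref in zip(fit, self.PARAMS):
            assert got == pytest.approx(ref, rel=1e-6)
        assert rms < 1e-10

    def test_v0_robust_to_noise_over_seeds(self):
        for seed in range(20):
            V, F = make_eos_data(self.PARAMS, 17, noise=1e-5, seed=seed)
            fit, _ = fit_birch_murnaghan(V, F)
            assert abs(fit[1] - 100.0) / 100.0 < 1e-3

    def test_too_few_points_rejected(self):
        V, F = make_eos_data(self.PARAMS, n_points=3)
        with pytest.raises(EOSFitError):
            fit_birch_murnaghan(V, F)

    def test_monotone_data_rejected(self):
        V = np.linspace(90, 110, 9)
        with pytest.raises(EOSFitError):
            fit_birch_murnaghan(V, -0.01 * V)


class TestHeatCapacity:
    def test_quadratic_g(self):
        T = np.linspace(10, 500, 50)
        a = 1e-6
        cp = heat_capacity(-a * T**2, T)
        assert np.abs(cp - 2 * a * T).max() < 1e-10

    def test_linear_g_zero_cp(self):
        T = np.linspace(10, 500, 30)
        assert np.abs(heat_capacity(-1e-4 * T, T)).max() < 1e-12

    def test_nonuniform_grid_rejected(self):
        T = np.array([0, 10, 30, 40, 50.0])
        with pytest.raises(ValueError, match="uniform"):
            heat_capacity(np.zeros(5), T)

    def test_dulong_petit_limit(self):
        """Einstein crystal Cp → 3n·k_B at k_BT = 10·ħω₀."""
        fx = make_fixture(FixtureSpec("einstein_crystal"))
        fc = hessian(fx.structure, fx.calculator, min_supercell_length=8.0,
                     enforce_asr=False)
        spec = mesh_spectrum(fc, (2, 2, 2))
        w0 = fx.reference["omega0"]
        n = fx.reference["n_atoms"]
        T_hot = 10 * HBAR * w0 / K_B
        T = np.arange(T_hot - 50, T_hot + 51, 10.0)
        G = np.array([f_vib(spec, t) for t in T])
        cp = heat_capacity(G, T)
        mid = len(T) // 2
        assert cp[mid] == pytest.approx(3 * n * K_B, rel=0.01)


class TestQHA:
    def test_lj_positive_thermal_expansion(self, lj_fcc):
        fx, clean, _ = lj_fcc
        curve = qha(clean, fx.calculator,
                    T_list=(0.0, 100.0, 200.0, 300.0, 400.0),
                    mesh=(3, 3, 3), min_supercell_length=8.0)
        assert curve.V_of_T[3] > curve.V_of_T[0]  # V(300 K) > V(0 K)
        assert np.all(np.diff(curve.G_of_T) < 0)  # G strictly decreasing

    def test_volume_independent_frequencies_no_expansion(self):
        fx = make_fixture(FixtureSpec("einstein_crystal"))
        v0 = fx.structure.lattice.volume
        calc = CompositeCalculator([
            VolumeEnergyCalculator(1e-3, v0),
            SpringCalculator(site_springs=(2.0, None)),
        ])
        curve = qha(fx.structure, calc, T_list=(0.0, 150.0, 300.0),
                    mesh=(2, 2, 2), min_supercell_length=8.0,
                    imaginary_policy="drop")
        # no thermal expansion: V(T) exactly constant across temperatures,
        # equal to V0 within the EOS-fit bias on quadratic data
        assert (curve.V_of_T.max() - curve.V_of_T.min()) / v0 < 1e-10
        assert np.abs(curve.V_of_T - v0).max() / v0 < 1e-3

    def test_too_few_surviving_volumes_error(self, lj_fcc):
        fx, clean, _ = lj_fcc
        with pytest.raises(EOSFitError):
            qha(clean, fx.calculator, volume_factors=(0.95, 1.0, 1.05),
                T_list=(0.0,), mesh=(2, 2, 2), min_supercell_length=8.0)
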