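"""Calculator conformance, Ewald oracle, dispersion, surrogate training."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cspkit import (
    CrystalStructure,
    DispersionParams,
    EwaldCalculator,
    EwaldSettings,
    LabeledSample,
    Lattice,
    LennardJonesCalculator,
    Molecule,
    RadialDescriptor,
    SpringCalculator,
    atm_three_body,
    dispersion_two_body,
    ensemble_predict,
    ewald_energy,
    train_ensemble,
    train_surrogate,
)
from cspkit.constants import COULOMB_EV_A
from cspkit.fixtures import FixtureSpec, make_fixture, rocksalt_madelung_direct


def _cluster(symbols, positions):
    m = Molecule.__new__(Molecule)
    m.symbols = list(symbols)
    m.positions = np.asarray(positions, dtype=float)
    m.bonds = []
    m.formal_charge = 0
    return m


LJ = LennardJonesCalculator({("Ar", "Ar"): (1.0, 1.0)}, cutoff=10.0)


class TestPairPotential:
    def test_lj_analytic_minimum(self):
        m = _cluster(["Ar", "Ar"], [[0, 0, 0], [2 ** (1 / 6), 0, 0]])
        e, f = LJ.energy_forces(m)
        assert e == pytest.approx(-1.0, abs=1e-12)
        assert np.abs(f).max() < 1e-8

    def test_lj_zero_at_sigma(self):
        m = _cluster(["Ar", "Ar"], [[0, 0, 0], [1.0, 0, 0]])
        assert LJ.energy(m) == pytest.approx(0.0, abs=1e-12)

    def test_forces_match_central_differences(self, rng):
        pos = rng.uniform(0, 5, (10, 3)) * 1.2
        m = _cluster(["Ar"] * 10, pos)
        _, f = LJ.energy_forces(m)
        h = 1e-6
        for i in range(10):
            for a in range(3):
                p1, p2 = pos.copy(), pos.copy()
                p1[i, a] += h
                p2[i, a] -= h
                fd = -(LJ.energy(_cluster(["Ar"] * 10, p1))
                       - LJ.energy(_cluster(["Ar"] * 10, p2))) / (2 * h)
                assert fd == pytest.approx(f[i, a], abs=1e-6)

    def test_missing_pair_parameters(self):
        m = _cluster(["Ar", "Kr"], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(KeyError, match="Kr"):
            LJ.energy(m)

    def test_bonded_pairs_use_harmonic_form(self):
        calc = LennardJonesCalculator({("N", "N"): (0.05, 3.1)}, cutoff=8.0,
                                      bonded={("N", "N"): (30.0, 1.1)})
        m = _cluster(["N", "N"], [[0, 0, 0], [1.1, 0, 0]])
        e, f = calc.energy_forces(m)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-10


class TestConformance:
    """Common Calculator contract on the LJ fcc toy."""

    def test_translation_invariance(self, lj_fcc):
        fx, s, e0 = lj_fcc
        shifted = s.copy()
        shifted.frac_coords = np.mod(s.frac_coords + [0.13, 0.41, 0.77], 1.0)
        assert fx.calculator.energy(shifted) == pytest.approx(e0, rel=1e-10)

    def test_extensivity_2x1x1(self, lj_fcc):
        fx, s, e0 = lj_fcc
        cell2 = s.lattice.cell.copy()
        cell2[0] *= 2
        frac2 = np.vstack([s.frac_coords * [0.5, 1, 1],
                           s.frac_coords * [0.5, 1, 1] + [0.5, 0, 0]])
        s2 = CrystalStructure(Lattice(cell2), list(s.species) * 2, frac2)
        assert fx.calculator.energy(s2) == pytest.approx(2 * e0, rel=1e-8)

    def test_stress_matches_strain_derivative(self, lj_fcc):
        fx, s, _ = lj_fcc
        stretched = s.copy()
        stretched.lattice = Lattice(s.lattice.cell * 1.02)
        analytic = fx.calculator.stress(stretched)
        from cspkit.potentials import Calculator
        numeric = Calculator.stress(fx.calculator, stretched, h=1e-6)
        assert np.abs(analytic - numeric).max() < 1e-8

    def test_spring_hessian_matches_finite_difference(self, rng):
        k = 4.0
        calc = SpringCalculator(bond_springs=[(0, 1, (0, 0, 0), k, 1.4)])
        m = _cluster(["Ar", "Ar"], [[0, 0, 0], [1.5, 0.2, -0.1]])
        from cspkit.potentials import Calculator
        analytic = calc.hessian(m)
        numeric = Calculator.hessian(calc, m, step=1e-4)
        assert np.abs(analytic - numeric).max() < 1e-5


@pytest.fixture(scope="module")
def rocksalt():
    return make_fixture(FixtureSpec("rocksalt_ions"))


class TestEwald:
    def test_madelung_vs_direct_sum_oracle(self, rocksalt):
        fx = rocksalt
        e = ewald_energy(fx.structure)
        per_pair = e / fx.reference["n_ion_pairs"]
        madelung = -per_pair * fx.reference["d_nn"] / COULOMB_EV_A
        oracle = rocksalt_madelung_direct(n_shells=30)
        assert madelung == pytest.approx(oracle, rel=1e-4)

    def test_cscl_vs_literature_constant(self):
        d = 3.5  # nearest-neighbor distance along the body diagonal
        a = 2 * d / math.sqrt(3)
        lat = Lattice(np.eye(3) * a)
        s = CrystalStructure(lat, ["Na", "Cl"],
                             [[0, 0, 0], [0.5, 0.5, 0.5]],
                             site_charges=np.array([1.0, -1.0]))
        e = ewald_energy(s)
        madelung = -e * d / COULOMB_EV_A
        assert madelung == pytest.approx(1.76267, rel=1e-4)

    def test_zero_charges_give_zero(self, rocksalt):
        s = rocksalt.structure.copy()
        assert ewald_energy(s, charges=np.zeros(len(s))) == 0.0

    def test_splitting_parameter_invariance(self, rocksalt):
        s = rocksalt.structure
        e1 = ewald_energy(s, settings=EwaldSettings(alpha=0.2))
        e2 = ewald_energy(s, settings=EwaldSettings(alpha=0.4))
        assert abs(e1 - e2) / abs(e1) < 1e-7

    def test_non_neutral_cell_rejected(self, rocksalt):
        s = rocksalt.structure.copy()
        q = s.site_charges.copy()
        q[0] = 2.0
        s.site_charges = q
        with pytest.raises(ValueError, match="net charge"):
            ewald_energy(s)

    def test_forces_match_central_differences(self, rocksalt):
        s = rocksalt.structure.copy()
        s.frac_coords = np.mod(
            s.frac_coords + np.random.default_rng(1).normal(0, 0.02, (8, 3)), 1)
        calc = EwaldCalculator()
        _, f = calc.energy_forces(s)
        h = 1e-5
        inv = np.linalg.inv(s.lattice.cell)
        for i in (0, 5):
            for a in range(3):
                c1 = s.cart_coords
                c1[i, a] += h
                s1 = s.copy()
                s1.frac_coords = np.mod(c1 @ inv, 1)
                c2 = s.cart_coords
                c2[i, a] -= h
                s2 = s.copy()
                s2.frac_coords = np.mod(c2 @ inv, 1)
                fd = -(calc.energy(s1) - calc.energy(s2)) / (2 * h)
                assert fd == pytest.approx(f[i, a], abs=1e-6)


class TestDispersion:
    def test_atm_equilateral_triangle(self):
        r = 2.0
        tri = _cluster(["Ar"] * 3, [[0, 0, 0], [r, 0, 0],
                                    [r / 2, r * math.sqrt(3) / 2, 0]])
        p = DispersionParams(c9=2.0, cutoff=10.0)
        # angular factor 3·(1/2)³ + 1 = 11/8
        assert atm_three_body(tri, p) == pytest.approx(
            1.375 * 2.0 / r**9, rel=1e-12)

    def test_atm_two_atoms_is_zero(self):
        two = _cluster(["Ar"] * 2, [[0, 0, 0], [2, 0, 0]])
        assert atm_three_body(two, DispersionParams(c9=5.0)) == 0.0

    def test_two_body_zero_c6(self):
        two = _cluster(["Ar"] * 2, [[0, 0, 0], [2, 0, 0]])
        assert dispersion_two_body(two, DispersionParams()) == 0.0

    def test_two_body_damped_value(self):
        r = 4.0
        two = _cluster(["Ar"] * 2, [[0, 0, 0], [r, 0, 0]])
        p = DispersionParams(c6={("Ar", "Ar"): 60.0}, r0=3.0, cutoff=10.0)
        fdamp = r**6 / (r**6 + 3.0**6)
        assert dispersion_two_body(two, p) == pytest.approx(
            -60.0 * fdamp / r**6, rel=1e-12)


class TestDescriptors:
    DESC = RadialDescriptor(("Ar",), cutoff=5.0)

    def test_isolated_atom_zero_features(self):
        m = _cluster(["Ar"], [[0, 0, 0]])
        assert np.all(self.DESC.features(m) == 0.0)

    def test_rotation_invariance(self, rng):
        pos = rng.uniform(0, 4, (6, 3))
        R = Rotation.random(random_state=7).as_matrix()
        f1 = self.DESC.features(_cluster(["Ar"] * 6, pos))
        f2 = self.DESC.features(_cluster(["Ar"] * 6, pos @ R.T))
        assert np.abs(f1 - f2).max() < 1e-12

    def test_permutation_invariance(self, rng):
        pos = rng.uniform(0, 4, (6, 3))
        perm = rng.permutation(6)
        f1 = self.DESC.features(_cluster(["Ar"] * 6, pos))
        f2 = self.DESC.features(_cluster(["Ar"] * 6, pos[perm]))
        assert np.abs(np.sort(f1, axis=0) - np.sort(f2, axis=0)).max() < 1e-12

    def test_cutoff_boundary_smooth(self):
        just_out = _cluster(["Ar", "Ar"], [[0, 0, 0], [5.001, 0, 0]])
        assert np.all(self.DESC.features(just_out) == 0.0)
        just_in = _cluster(["Ar", "Ar"], [[0, 0, 0], [4.999, 0, 0]])
        f = self.DESC.features(just_in)
        assert 0 < np.abs(f).max() < 1e-4  # cosine cutoff → smoothly small


def _dimer_curve_samples(calc, rng, distances):
    samples = []
    for r in distances:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        g = _cluster(["Ar", "Ar"], [[0, 0, 0], u * r])
        e, f = calc.energy_forces(g)
        samples.append(LabeledSample(g, e, f))
    return samples


class TestSurrogate:
    CALC = LennardJonesCalculator({("Ar", "Ar"): (0.01, 3.4)}, cutoff=8.0)

    def test_representable_labels_interpolated(self):
        # constant per-atom energies are exactly representable (bias term)
        g1 = _cluster(["Ar", "Ar"], [[0, 0, 0], [3.4, 0, 0]])
        g2 = _cluster(["Ar", "Ar", "Ar"], [[0, 0, 0], [3.4, 0, 0], [0, 3.4, 0]])
        samples = [LabeledSample(g1, 2 * 1.5), LabeledSample(g2, 3 * 1.5)]
        model = train_surrogate(samples, regularization=1e-12)
        assert model.predict_energy(g1) == pytest.approx(3.0, abs=1e-8)

    def test_duplicate_samples_do_not_shift_fit(self, rng):
        samples = _dimer_curve_samples(self.CALC, rng, np.linspace(3, 6, 20))
        m1 = train_surrogate(samples, regularization=1e-10)
        m2 = train_surrogate(samples + samples, regularization=1e-10)
        probe = _cluster(["Ar", "Ar"], [[0, 0, 0], [3.7, 0, 0]])
        assert m1.predict_energy(probe) == pytest.approx(
            m2.predict_energy(probe), abs=1e-8)

    def test_holdout_error_shrinks_with_training_size(self, rng):
        # probe within the 5 Å descriptor range where error is reducible
        hold = np.linspace(3.1, 4.7, 25)
        desc = RadialDescriptor(("Ar",), cutoff=5.0, n_basis=16)
        maes = []
        for n in (10, 30, 100):
            train = _dimer_curve_samples(
                self.CALC, rng, np.linspace(3.0, 4.8, n))
            model = train_surrogate(train, descriptor=desc)
            errs = [abs(model.predict_energy(
                _cluster(["Ar", "Ar"], [[0, 0, 0], [r, 0, 0]]))
                - self.CALC.energy(
                    _cluster(["Ar", "Ar"], [[0, 0, 0], [r, 0, 0]])))
                for r in hold]
            maes.append(np.mean(errs))
        assert maes[2] < maes[0]

    def test_forces_are_energy_gradient(self, rng):
        samples = _dimer_curve_samples(self.CALC, rng, np.linspace(3, 6, 30))
        model = train_surrogate(samples)
        g = _cluster(["Ar", "Ar"], [[0, 0, 0], [3.6, 0.4, 0.1]])
        _, f = model.predict_energy_forces(g)
        h = 1e-6
        for i in range(2):
            for a in range(3):
                p1, p2 = g.positions.copy(), g.positions.copy()
                p1[i, a] += h
                p2[i, a] -= h
                fd = -(model.predict_energy(_cluster(g.symbols, p1))
                       - model.predict_energy(_cluster(g.symbols, p2))) / (2 * h)
                assert fd == pytest.approx(f[i, a], abs=1e-8)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_surrogate([])

    def test_training_deterministic(self, rng):
        samples = _dimer_curve_samples(self.CALC, rng, np.linspace(3, 6, 15))
        w1 = train_surrogate(samples, seed=3).weights["Ar"]
        w2 = train_surrogate(samples, seed=3).weights["Ar"]
        assert np.array_equal(w1, w2)


class TestEnsemble:
    def test_identical_models_zero_std(self, rng):
        samples = _dimer_curve_samples(
            TestSurrogate.CALC, rng, np.linspace(3, 6, 20))
        model = train_surrogate(samples)
        probe = samples[0].geometry
        _, std, _ = ensemble_predict([model] * 4, probe)
        assert std == 0.0

    def test_hand_sample_std(self):
        # std of {1.0, 1.2, 0.8, 1.0} with ddof=1 is 0.1633
        class Stub:
            def __init__(self, e):
                self.e = e

            def predict_energy_forces(self, g):
                return self.e, np.zeros((1, 3))

        probe = _cluster(["Ar"], [[0, 0, 0]])
        _, std, _ = ensemble_predict(
            [Stub(1.0), Stub(1.2), Stub(0.8), Stub(1.0)], probe)
        assert std == pytest.approx(0.16329931618554516, rel=1e-9)

    def test_order_invariance(self, rng):
        samples = _dimer_curve_samples(
            TestSurrogate.CALC, rng, np.linspace(3, 6, 20))
        models = train_ensemble(samples, seed=5)
        probe = samples[3].geometry
        a = ensemble_predict(models, probe)
        b = ensemble_predict(models[::-1], probe)
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=1e-12)

    def test_single_model_rejected(self, rng):
        samples = _dimer_curve_samples(
            TestSurrogate.CALC, rng, np.linspace(3, 6, 10))
        model = train_surrogate(samples)
        with pytest.raises(ValueError):
            ensemble_predict([model], samples[0].geometry)

    def test_surrogate_rotation_invariance(self, rng):
        samples = _dimer_curve_samples(
            TestSurrogate.CALC, rng, np.linspace(3, 6, 20))
        model = train_surrogate(samples)
        pos = rng.uniform(0, 4, (4, 3))
        R = Rotation.random(random_state=11).as_matrix()
        e1 = model.predict_energy(_cluster(["Ar"] * 4, pos))
        e2 = model.predict_energy(_cluster(["Ar"] * 4, pos @ R.T))
        assert abs(e1 - e2) < 1e-10
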