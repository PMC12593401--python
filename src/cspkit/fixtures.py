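"""Seeded synthetic fixtures with known reference physics.

Each fixture ships with the toy calculator that generated it and with the
closed-form reference quantities its tests rely on (lattice constants,
frequency formulas, the Madelung constant).  The teacher/student split used
throughout the test suite is: teacher = classical pair potential (plus
Ewald for ionic toys), student = descriptor-regression surrogate ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import OMEGA_SI, get_element
from .potentials import (
    EwaldSettings,
    LennardJonesCalculator,
    SpringCalculator,
)
from .structures import CrystalStructure, Lattice, Molecule

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "make_eos_data",
           "rocksalt_madelung_direct", "VolumeEnergyCalculator"]

FIXTURE_KINDS = ("lj_fcc", "rigid_diatomic_crystal", "einstein_crystal",
                 "rocksalt_ions", "one_d_chain")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    noise: float = 0.0  # Å, random site displacement
    seed: int = 0
    size: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


@dataclass
class Fixture:
    structure: CrystalStructure
    calculator: object
    reference: dict


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build a toy crystal plus its calculator and reference metadata."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "lj_fcc":
        fx = _lj_fcc(spec)
    elif spec.kind == "rigid_diatomic_crystal":
        fx = _rigid_diatomic(spec)
    elif spec.kind == "einstein_crystal":
        fx = _einstein(spec)
    elif spec.kind == "rocksalt_ions":
        fx = _rocksalt(spec)
    elif spec.kind == "one_d_chain":
        fx = _one_d_chain(spec)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(spec.kind)
    if spec.noise > 0:
        s = fx.structure
        disp = rng.normal(0.0, spec.noise, size=(len(s), 3))
        cart = s.cart_coords + disp
        s.frac_coords = np.mod(cart @ np.linalg.inv(s.lattice.cell), 1.0)
    return fx


def _lj_fcc(spec: FixtureSpec) -> Fixture:
    # a deep 1 eV well keeps 300 K a moderate temperature for the toy solid
    eps = spec.size.get("epsilon", 1.0)
    sigma = spec.size.get("sigma", 3.4)
    cutoff = spec.size.get("cutoff", 8.5)
    a0 = spec.size.get("a", 1.5496 * sigma)  # near the LJ-fcc minimum
    frac = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    s = CrystalStructure(Lattice(np.eye(3) * a0), ["Ar"] * 4, frac)
    calc = LennardJonesCalculator({("Ar", "Ar"): (eps, sigma)}, cutoff=cutoff)
    return Fixture(s, calc, {"epsilon": eps, "sigma": sigma, "a0": a0,
                             "vdw_matched_sr": 0.8})


def _rigid_diatomic(spec: FixtureSpec) -> Fixture:
    """Two N₂-like rigid diatomics related by inversion in a P-1-style cell."""
    bond = spec.size.get("bond", 1.10)
    scale = spec.size.get("scale", 1.0)
    lat = Lattice(np.array([[5.8, 0.0, 0.0],
                            [0.9, 5.2, 0.0],
                            [0.4, 0.6, 4.9]]) * scale)
    axis = np.array([0.8, 0.5, 0.33])
    axis /= np.linalg.norm(axis)
    c1 = np.array([0.25, 0.25, 0.25]) @ lat.cell
    mol1 = np.array([c1 - axis * bond / 2, c1 + axis * bond / 2])
    mol2 = (np.array([0.5, 0.5, 0.5]) @ lat.cell) * 2 - mol1  # inversion image
    frac = np.vstack([mol1, mol2]) @ np.linalg.inv(lat.cell)
    s = CrystalStructure(lat, ["N"] * 4, frac, Z=2,
                         molecule_of_site=np.array([0, 0, 1, 1]))
    # nonbonded LJ between molecules; covalently close pairs fall back to a
    # stiff harmonic bond, so the diatomics stay intact under relaxation
    # and tethered dynamics
    calc = LennardJonesCalculator(
        {("N", "N"): (spec.size.get("epsilon", 0.05),
                      spec.size.get("sigma", 3.1))},
        cutoff=spec.size.get("cutoff", 8.0),
        bonded={("N", "N"): (spec.size.get("k_bond", 30.0), bond)})
    mol = Molecule(["N", "N"], mol1, bonds=[(0, 1)])
    return Fixture(s, calc, {"molecule": mol, "bond": bond})


def _einstein(spec: FixtureSpec) -> Fixture:
    k = spec.size.get("k", 2.0)  # eV/Å²
    a = spec.size.get("a", 4.0)
    n = spec.size.get("n_sites", 2)
    frac = np.array([[0, 0, 0], [0.5, 0.5, 0.5]])[:n]
    s = CrystalStructure(Lattice(np.eye(3) * a), ["Ar"] * n, frac)
    calc = SpringCalculator(site_springs=(k, s.cart_coords))
    m = get_element("Ar").mass
    omega0 = math.sqrt(k / m) * OMEGA_SI
    return Fixture(s, calc, {"k": k, "omega0": omega0, "n_atoms": n})


def _rocksalt(spec: FixtureSpec) -> Fixture:
    d = spec.size.get("d_nn", 2.82)
    charge = spec.size.get("charge", 1.0)
    lat = Lattice(np.eye(3) * 2 * d)
    frac, species, q = [], [], []
    for f3 in [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]:
        frac.append(f3)
        species.append("Na")
        q.append(charge)
        frac.append(((f3[0] + 0.5) % 1, f3[1], f3[2]))
        species.append("Cl")
        q.append(-charge)
    s = CrystalStructure(lat, species, np.array(frac),
                         site_charges=np.array(q))
    return Fixture(s, None, {"d_nn": d, "madelung": 1.7475645946,
                             "n_ion_pairs": 4,
                             "ewald_settings": EwaldSettings()})


def _one_d_chain(spec: FixtureSpec) -> Fixture:
    k = spec.size.get("k", 5.0)
    a = spec.size.get("a", 3.0)
    box = spec.size.get("box", 20.0)
    s = CrystalStructure(Lattice(np.diag([a, box, box])), ["Ar"], [[0, 0, 0]])
    calc = SpringCalculator(bond_springs=[(0, 0, (1, 0, 0), k, a)])
    m = get_element("Ar").mass
    return Fixture(s, calc, {
        "k": k, "a": a,
        # longitudinal branch: ω(q) = 2·sqrt(k/m)·|sin(π q)| (q fractional)
        "dispersion": lambda q: 2 * math.sqrt(k / m) * abs(
            math.sin(math.pi * q)) * OMEGA_SI,
    })


class VolumeEnergyCalculator:
    """Synthetic cell-energy term E = ½·a·(V − V₀)², independent of positions.

    Combined with the pinning-medium spring calculator this builds a rigid
    harmonic fixture whose phonon frequencies do not change with volume, so
    its quasi-harmonic volume scan must show zero thermal expansion.
    """

    capabilities = frozenset({"energy", "forces", "stress", "analytic_hessian"})

    def __init__(self, a: float, v0: float):
        self.a = float(a)
        self.v0 = float(v0)

    def energy_forces(self, obj):
        v = obj.lattice.volume
        return 0.5 * self.a * (v - self.v0) ** 2, np.zeros((len(obj), 3))

    def energy(self, obj):
        return self.energy_forces(obj)[0]

    def forces(self, obj):
        return self.energy_forces(obj)[1]

    def stress(self, crystal, h: float = 1e-6):
        v = crystal.lattice.volume
        return self.a * (v - self.v0) * np.eye(3)

    def hessian(self, obj, step: float = 0.005):
        n = len(obj)
        return np.zeros((3 * n, 3 * n))

    def for_supercell(self, primitive, supercell, reps):
        scale = reps[0] * reps[1] * reps[2]
        return VolumeEnergyCalculator(self.a / scale, self.v0 * scale)


def rocksalt_madelung_direct(n_shells: int = 40) -> float:
    """Madelung constant of rocksalt by an Evjen-weighted direct sum.

    Independent reference for the Ewald oracle tests: charges on the
    boundary of the summation cube are weighted by the fraction of the cube
    they occupy, giving rapid convergence of the conditionally convergent
    series.
    """
    total = 0.0
    n = n_shells
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for t in (i, j, k):
                    if abs(t) == n:
                        w *= 0.5
                r = math.sqrt(i * i + j * j + k * k)
                total += w * (-1.0) ** ((i + j + k) % 2) / r
    return -total


def make_eos_data(params=( -1.0, 100.0, 0.5, 4.0), n_points: int = 17,
                  noise: float = 0.0, seed: int = 0,
                  v_range: tuple[float, float] = (0.9, 1.2)):
    """Exact Birch–Murnaghan samples plus optional seeded Gaussian noise.

    Returns (volumes, free_energies); ``params`` is (F0, V0, B0, B0').
    """
    from .phonons import birch_murnaghan_energy
    f0, v0, b0, b0p = params
    V = np.linspace(v_range[0] * v0, v_range[1] * v0, n_points)
    F = birch_murnaghan_energy(V, f0, v0, b0, b0p)
    if noise > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise, size=len(F))
    return V, F
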