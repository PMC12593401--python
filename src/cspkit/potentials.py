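"""Energy models behind a common Calculator contract.

Implemented calculators:

* ``LennardJonesCalculator`` / ``BuckinghamCalculator`` — classical pair
  potentials with analytic forces, virial stress, and analytic Hessians;
  periodic sums run over all lattice images within the cutoff.
* ``SpringCalculator`` — harmonic bond and on-site springs, used by the
  closed-form phonon fixtures.
* ``EwaldCalculator`` — point-charge electrostatics via Ewald summation at a
  requested relative accuracy.
* ``DispersionCalculator`` — damped −C6/r⁶ two-body dispersion, with the
  Axilrod–Teller–Muto three-body term available as a post-optimization
  single-point correction.
* ``SurrogateCalculator`` — a deterministic linear regression over smooth
  radial descriptors of the 5 Å local atomic environment, trained on
  labelled clusters; ensembles of these provide the active-learning
  uncertainty signal.

Forces are the negative energy gradient and stress the cell-strain
derivative; both are validated numerically in the conformance test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_EV_A, get_element
from .structures import CrystalStructure, Molecule, NMer

__all__ = [
    "Calculator",
    "LennardJonesCalculator",
    "BuckinghamCalculator",
    "SpringCalculator",
    "EwaldSettings",
    "EwaldCalculator",
    "ewald_energy",
    "DispersionParams",
    "DispersionCalculator",
    "dispersion_two_body",
    "atm_three_body",
    "RadialDescriptor",
    "SurrogateModel",
    "SurrogateCalculator",
    "LabeledSample",
    "train_surrogate",
    "train_ensemble",
    "ensemble_predict",
    "CompositeCalculator",
    "neighbor_pairs",
]


# ------------------------------------------------------------------ utilities


def _geometry(obj):
    """Normalize input to (symbols, cart positions, lattice-or-None)."""
    if isinstance(obj, CrystalStructure):
        return list(obj.species), obj.cart_coords, obj.lattice
    if isinstance(obj, NMer):
        return obj.symbols, obj.positions, None
    if isinstance(obj, Molecule):
        return list(obj.symbols), obj.positions, None
    raise TypeError(f"unsupported geometry type {type(obj)!r}")


def neighbor_pairs(positions: np.ndarray, lattice, cutoff: float):
    """Yield (i, j, rvec) for each interacting pair within ``cutoff``.

    For periodic systems the sum runs over every lattice image within the
    cutoff (each physical pair counted once: i<j for the home image, and
    half of the nonzero image shifts for all i,j including i==j).
    """
    n = len(positions)
    if lattice is None:
        for i in range(n):
            d = positions[i + 1:] - positions[i]
            r = np.linalg.norm(d, axis=1)
            for k in np.flatnonzero(r <= cutoff):
                yield i, i + 1 + int(k), d[k]
        return
    cell = lattice.cell
    # number of image repeats per direction from interplanar spacings
    vol = lattice.volume
    reps = []
    for a in range(3):
        cross = np.cross(cell[(a + 1) % 3], cell[(a + 2) % 3])
        spacing = vol / np.linalg.norm(cross)
        reps.append(int(math.ceil(cutoff / spacing)) + 1)
    shifts = [s for s in itertools.product(*[range(-m, m + 1) for m in reps])]
    for s in shifts:
        if s < (0, 0, 0):
            continue  # keep lexicographically non-negative half + home cell
        svec = np.asarray(s, dtype=float) @ cell
        home = s == (0, 0, 0)
        for i in range(n):
            # home cell: i<j once; retained half of image shifts: all i,j
            rng = range(i + 1, n) if home else range(n)
            d = positions[list(rng)] - positions[i] + svec if len(rng) else None
            if d is None or len(d) == 0:
                continue
            r = np.linalg.norm(d, axis=1)
            for k in np.flatnonzero(r <= cutoff):
                yield i, list(rng)[int(k)], d[k]


class Calculator:
    """Energy/forces/stress/Hessian provider contract.

    Subclasses implement :meth:`energy_forces`; ``stress`` defaults to a
    central-difference strain derivative of the energy and ``hessian`` to
    finite differences of forces, both overridable with analytic forms.
    """

    capabilities = frozenset({"energy", "forces", "stress"})

    def energy_forces(self, obj) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy(self, obj) -> float:
        return self.energy_forces(obj)[0]

    def forces(self, obj) -> np.ndarray:
        return self.energy_forces(obj)[1]

    def stress(self, crystal: CrystalStructure, h: float = 1e-6) -> np.ndarray:
        """(1/V)·dE/dε for symmetric strain ε, by central differences."""
        if not isinstance(crystal, CrystalStructure):
            raise TypeError("stress requires a periodic structure")
        vol = crystal.lattice.volume
        sig = np.zeros((3, 3))
        for a in range(3):
            for b in range(a, 3):
                ep = np.zeros((3, 3))
                ep[a, b] = ep[b, a] = h
                e_plus = self.energy(_strained(crystal, ep))
                e_minus = self.energy(_strained(crystal, -ep))
                val = (e_plus - e_minus) / (2 * h)
                if a != b:
                    val /= 2.0  # two equal off-diagonal components varied
                sig[a, b] = sig[b, a] = val / vol
        return sig

    def for_supercell(self, primitive, supercell, reps):
        """Calculator to use on a supercell of ``primitive`` (default: self)."""
        return self

    def hessian(self, obj, step: float = 0.005) -> np.ndarray:
        """Finite-displacement Hessian (eV/Å²), central differences."""
        symbols, pos0, lattice = _geometry(obj)
        n = len(symbols)
        hess = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for a in range(3):
                fp = self.forces(_displaced(obj, i, a, step))
                fm = self.forces(_displaced(obj, i, a, -step))
                hess[3 * i + a] = -((fp - fm) / (2 * step)).reshape(-1)
        return 0.5 * (hess + hess.T)


def _strained(crystal: CrystalStructure, eps: np.ndarray) -> CrystalStructure:
    from .structures import Lattice
    out = crystal.copy()
    out.lattice = Lattice(crystal.lattice.cell @ (np.eye(3) + eps).T)
    return out


def _displaced(obj, i: int, axis: int, step: float):
    if isinstance(obj, CrystalStructure):
        out = obj.copy()
        cart = out.cart_coords
        cart[i, axis] += step
        # deliberately unwrapped: explicit-image interactions (e.g. offset
        # springs) must see the displaced atom in its original image
        out.frac_coords = cart @ np.linalg.inv(out.lattice.cell)
        return out
    symbols, pos, _ = _geometry(obj)
    pos = pos.copy()
    pos[i, axis] += step
    mol = Molecule.__new__(Molecule)
    mol.symbols = list(symbols)
    mol.positions = pos
    mol.bonds = []
    mol.formal_charge = 0
    return mol


# --------------------------------------------------------------- pair models


class _PairCalculator(Calculator):
    """Shared machinery for radially symmetric pair potentials.

    ``bonded`` optionally maps species pairs to harmonic bond parameters
    (k in eV/Å², r0 in Å): any pair closer than ``bond_scale`` times the
    summed covalent radii then interacts through ½k(r−r0)² instead of the
    nonbonded form, which keeps toy molecular teachers from crushing or
    exploding covalent bonds.
    """

    capabilities = frozenset({"energy", "forces", "stress", "analytic_hessian"})

    def __init__(self, cutoff: float, shift: bool = False,
                 bonded: dict | None = None, bond_scale: float = 1.2):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.cutoff = float(cutoff)
        self.shift = bool(shift)
        self.bonded = ({_pair_key(*k): (float(v[0]), float(v[1]))
                        for k, v in bonded.items()} if bonded else {})
        self.bond_scale = float(bond_scale)

    def _phi(self, s1: str, s2: str, r: np.ndarray):
        """Return (phi, dphi/dr, d2phi/dr2) for species pair at distances r."""
        raise NotImplementedError

    def _phi_select(self, s1: str, s2: str, r: float):
        if self.bonded:
            key = _pair_key(s1, s2)
            if key in self.bonded:
                rc = self.bond_scale * (get_element(s1).covalent_radius
                                        + get_element(s2).covalent_radius)
                if r <= rc:
                    k, r0 = self.bonded[key]
                    return 0.5 * k * (r - r0) ** 2, k * (r - r0), k
        e, de, d2e = self._phi(s1, s2, r)
        if self.shift:
            ec, _, _ = self._phi(s1, s2, self.cutoff)
            e -= ec
        return e, de, d2e

    def energy_forces(self, obj):
        symbols, pos, lattice = _geometry(obj)
        energy = 0.0
        forces = np.zeros_like(pos)
        for i, j, rv in neighbor_pairs(pos, lattice, self.cutoff):
            r = float(np.linalg.norm(rv))
            e, de, _ = self._phi_select(symbols[i], symbols[j], r)
            energy += e
            f = de / r * rv  # dE/dx_j
            forces[j] -= f
            forces[i] += f
        return energy, forces

    def stress(self, crystal: CrystalStructure, h: float = 1e-6) -> np.ndarray:
        symbols, pos, lattice = _geometry(crystal)
        if lattice is None:
            raise TypeError("stress requires a periodic structure")
        sig = np.zeros((3, 3))
        for i, j, rv in neighbor_pairs(pos, lattice, self.cutoff):
            r = float(np.linalg.norm(rv))
            _, de, _ = self._phi_select(symbols[i], symbols[j], r)
            sig += de / r * np.outer(rv, rv)
        return sig / lattice.volume

    def hessian(self, obj, step: float = 0.005) -> np.ndarray:
        symbols, pos, lattice = _geometry(obj)
        n = len(pos)
        hess = np.zeros((3 * n, 3 * n))
        eye = np.eye(3)
        for i, j, rv in neighbor_pairs(pos, lattice, self.cutoff):
            r = float(np.linalg.norm(rv))
            u = rv / r
            _, de, d2e = self._phi_select(symbols[i], symbols[j], r)
            blk = d2e * np.outer(u, u) + de / r * (eye - np.outer(u, u))
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            hess[si, si] += blk
            hess[sj, sj] += blk
            hess[si, sj] -= blk
            hess[sj, si] -= blk
        return hess


def _pair_key(s1: str, s2: str) -> tuple[str, str]:
    return (s1, s2) if s1 <= s2 else (s2, s1)


class LennardJonesCalculator(_PairCalculator):
    """12-6 Lennard-Jones: 4ε[(σ/r)¹² − (σ/r)⁶] per species pair."""

    def __init__(self, params: dict, cutoff: float = 10.0, shift: bool = False,
                 bonded: dict | None = None, bond_scale: float = 1.2):
        super().__init__(cutoff, shift, bonded, bond_scale)
        self.params = {_pair_key(*k): (float(v[0]), float(v[1]))
                       for k, v in params.items()}

    def _phi(self, s1, s2, r):
        key = _pair_key(s1, s2)
        if key not in self.params:
            raise KeyError(f"missing pair parameters for {key}")
        eps, sigma = self.params[key]
        sr6 = (sigma / r) ** 6
        sr12 = sr6 * sr6
        e = 4 * eps * (sr12 - sr6)
        de = 4 * eps * (-12 * sr12 + 6 * sr6) / r
        d2e = 4 * eps * (156 * sr12 - 42 * sr6) / r**2
        return e, de, d2e


class BuckinghamCalculator(_PairCalculator):
    """Buckingham A·exp(−r/ρ) − C/r⁶ per species pair."""

    def __init__(self, params: dict, cutoff: float = 10.0, shift: bool = False,
                 bonded: dict | None = None, bond_scale: float = 1.2):
        super().__init__(cutoff, shift, bonded, bond_scale)
        self.params = {_pair_key(*k): tuple(map(float, v))
                       for k, v in params.items()}

    def _phi(self, s1, s2, r):
        key = _pair_key(s1, s2)
        if key not in self.params:
            raise KeyError(f"missing pair parameters for {key}")
        A, rho, C = self.params[key]
        ex = A * math.exp(-r / rho)
        e = ex - C / r**6
        de = -ex / rho + 6 * C / r**7
        d2e = ex / rho**2 - 42 * C / r**8
        return e, de, d2e


class SpringCalculator(Calculator):
    """Harmonic springs: bonded pairs (optionally across cell images) plus
    optional on-site tethers.  The on-site form deliberately breaks
    translational invariance (Einstein-crystal fixture).

    ``bond_springs``: list of (i, j, offset, k, r0) with ``offset`` an integer
    lattice shift applied to atom j (ignored for clusters).
    ``site_springs``: (k_onsite, reference Cartesian positions).  A reference
    of ``None`` means an instantaneous pinning medium: zero energy and
    forces but a k·I curvature — the idealized Einstein solid whose
    frequencies are exactly volume-independent.
    """

    capabilities = frozenset({"energy", "forces", "stress", "analytic_hessian"})

    def __init__(self, bond_springs=(), site_springs=None):
        self.bond_springs = [(int(i), int(j), tuple(int(x) for x in off),
                              float(k), float(r0))
                             for i, j, off, k, r0 in bond_springs]
        self.site_springs = None
        if site_springs is not None:
            k, ref = site_springs
            self.site_springs = (float(k),
                                 None if ref is None
                                 else np.asarray(ref, dtype=float))

    def for_supercell(self, primitive, supercell, reps):
        """Remap springs onto a supercell (cell-major atom ordering)."""
        import itertools as _it
        n = len(primitive)
        cells = list(_it.product(*[range(m) for m in reps]))
        cell_index = {c: k for k, c in enumerate(cells)}
        bond = []
        for i, j, off, k, r0 in self.bond_springs:
            for c in cells:
                tgt = tuple((c[a] + off[a]) % reps[a] for a in range(3))
                wrap = tuple((c[a] + off[a]) // reps[a] for a in range(3))
                bond.append((cell_index[c] * n + i,
                             cell_index[tgt] * n + j, wrap, k, r0))
        site = None
        if self.site_springs is not None:
            k, ref = self.site_springs
            site = (k, None if ref is None else supercell.cart_coords)
        return SpringCalculator(bond, site)

    def _pairs(self, pos, lattice):
        for i, j, off, k, r0 in self.bond_springs:
            shift = (np.asarray(off, dtype=float) @ lattice.cell
                     if lattice is not None else 0.0)
            rv = pos[j] + shift - pos[i]
            yield i, j, rv, k, r0

    def energy_forces(self, obj):
        symbols, pos, lattice = _geometry(obj)
        energy = 0.0
        forces = np.zeros_like(pos)
        for i, j, rv, k, r0 in self._pairs(pos, lattice):
            r = float(np.linalg.norm(rv))
            energy += 0.5 * k * (r - r0) ** 2
            f = k * (r - r0) / r * rv
            forces[j] -= f
            forces[i] += f
        if self.site_springs is not None:
            k, ref = self.site_springs
            if ref is not None:
                d = pos - ref
                energy += 0.5 * k * np.sum(d * d)
                forces -= k * d
        return energy, forces

    def hessian(self, obj, step: float = 0.005) -> np.ndarray:
        symbols, pos, lattice = _geometry(obj)
        n = len(pos)
        hess = np.zeros((3 * n, 3 * n))
        eye = np.eye(3)
        for i, j, rv, k, r0 in self._pairs(pos, lattice):
            r = float(np.linalg.norm(rv))
            u = rv / r
            blk = k * np.outer(u, u) + k * (r - r0) / r * (eye - np.outer(u, u))
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            hess[si, si] += blk
            hess[sj, sj] += blk
            hess[si, sj] -= blk
            hess[sj, si] -= blk
        if self.site_springs is not None:
            k, _ = self.site_springs
            hess += k * np.eye(3 * n)
        return hess


# -------------------------------------------------------------------- Ewald


@dataclass(frozen=True)
class EwaldSettings:
    """Accuracy-driven Ewald summation settings.

    ``accuracy`` is the target relative error; the splitting parameter and
    reciprocal cutoff are derived from it unless ``alpha`` is given.
    """

    accuracy: float = 1e-8
    real_cutoff: float = 15.0  # Å
    alpha: float | None = None  # Å⁻¹

    def __post_init__(self):
        if not (0 < self.accuracy <= 1e-2):
            raise ValueError("accuracy must be in (0, 1e-2]")
        if self.real_cutoff <= 0:
            raise ValueError("real_cutoff must be positive")

    def derived_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        return math.sqrt(-math.log(self.accuracy)) / self.real_cutoff


class EwaldCalculator(Calculator):
    """Point-charge electrostatics for neutral periodic cells.

    Energy in eV with charges in e; the standard real/reciprocal/self split
    is used, with cutoffs set from the requested accuracy.
    """

    def __init__(self, settings: EwaldSettings = EwaldSettings()):
        self.settings = settings

    def _terms(self, crystal: CrystalStructure, grad: bool):
        q = crystal.site_charges
        if q is None:
            raise ValueError("structure carries no site charges")
        net = float(np.sum(q))
        if abs(net) > 1e-8:
            raise ValueError(f"Ewald requires a neutral cell; net charge {net:.6g} e")
        pos = crystal.cart_coords
        cell = crystal.lattice.cell
        vol = crystal.lattice.volume
        n = len(pos)
        alpha = self.settings.derived_alpha()
        acc = self.settings.accuracy
        # keep the real-space truncation error at the accuracy target even
        # when the user pins the splitting parameter
        rc = max(self.settings.real_cutoff, math.sqrt(-math.log(acc)) / alpha)

        energy = 0.0
        forces = np.zeros((n, 3))
        # real-space over images within rc
        for i, j, rv in neighbor_pairs(pos, crystal.lattice, rc):
            r = float(np.linalg.norm(rv))
            qq = q[i] * q[j]
            energy += COULOMB_EV_A * qq * erfc(alpha * r) / r
            if grad:
                de = -COULOMB_EV_A * qq * (
                    erfc(alpha * r) / r**2
                    + 2 * alpha / math.sqrt(math.pi) * math.exp(-(alpha * r) ** 2) / r
                )
                f = de / r * rv
                forces[j] -= f
                forces[i] += f
        # reciprocal space
        kmax = 2.0 * alpha * math.sqrt(-math.log(acc))
        rec = 2 * math.pi * np.linalg.inv(cell).T  # rows are b vectors
        nmax = [int(math.ceil(kmax / np.linalg.norm(rec[a]))) + 1 for a in range(3)]
        pref = COULOMB_EV_A * 2 * math.pi / vol
        for h in itertools.product(*[range(-m, m + 1) for m in nmax]):
            if h == (0, 0, 0):
                continue
            k = np.asarray(h, dtype=float) @ rec
            k2 = float(k @ k)
            if k2 > kmax * kmax:
                continue
            phase = pos @ k
            sk_re = float(np.sum(q * np.cos(phase)))
            sk_im = float(np.sum(q * np.sin(phase)))
            akk = math.exp(-k2 / (4 * alpha**2)) / k2
            energy += pref * akk * (sk_re**2 + sk_im**2)
            if grad:
                # dE/dx_i = pref·akk·2(S_re·(−q_i sinφ_i) + S_im·(q_i cosφ_i))·k
                coef = 2 * pref * akk * (
                    -sk_re * q * np.sin(phase) + sk_im * q * np.cos(phase)
                )
                forces -= coef[:, None] * k[None, :]
        # self energy
        energy -= COULOMB_EV_A * alpha / math.sqrt(math.pi) * float(np.sum(q * q))
        return energy, forces

    def energy_forces(self, obj):
        e, f = self._terms(obj, grad=True)
        return e, f

    def energy(self, obj):
        return self._terms(obj, grad=False)[0]


def ewald_energy(crystal: CrystalStructure, charges=None,
                 settings: EwaldSettings = EwaldSettings()) -> float:
    """Ewald electrostatic energy (eV) of a neutral periodic cell."""
    if charges is not None:
        crystal = crystal.copy()
        crystal.site_charges = np.asarray(charges, dtype=float)
    if crystal.site_charges is not None and np.allclose(crystal.site_charges, 0):
        return 0.0
    return EwaldCalculator(settings).energy(crystal)


# ---------------------------------------------------------------- dispersion


@dataclass
class DispersionParams:
    """Damped dispersion coefficients.

    ``c6``: per species-pair C6 in eV·Å⁶; ``r0``: Becke–Johnson-style damping
    radius (Å); ``c9``: uniform or per-element-triple C9 in eV·Å⁹ for the
    three-body Axilrod–Teller–Muto term.
    """

    c6: dict = field(default_factory=dict)
    r0: float = 3.0
    c9: float | dict = 0.0
    cutoff: float = 12.0

    def c6_for(self, s1: str, s2: str) -> float:
        key = _pair_key(s1, s2)
        v = self.c6.get(key, 0.0)
        if v < 0:
            raise ValueError("C6 must be non-negative")
        return v

    def c9_for(self, s1: str, s2: str, s3: str) -> float:
        if isinstance(self.c9, dict):
            key = tuple(sorted((s1, s2, s3)))
            return float(self.c9.get(key, 0.0))
        return float(self.c9)


def dispersion_two_body(obj, params: DispersionParams) -> float:
    """−Σ C6·f_damp(r)/r⁶ with rational damping f = r⁶/(r⁶ + r₀⁶)."""
    symbols, pos, lattice = _geometry(obj)
    e = 0.0
    for i, j, rv in neighbor_pairs(pos, lattice, params.cutoff):
        r6 = float(np.sum(rv * rv)) ** 3
        c6 = params.c6_for(symbols[i], symbols[j])
        e -= c6 * (r6 / (r6 + params.r0**6)) / r6
    return e


def atm_three_body(obj, params: DispersionParams) -> float:
    """Axilrod–Teller–Muto triple-dipole term on the final geometry.

    E₃ = Σ_{i<j<k} C9·(3·cosθ_i·cosθ_j·cosθ_k + 1)/(r_ij·r_jk·r_ki)³ over
    minimum-image triangles within the cutoff.  Evaluated as a single-point
    correction only — it never enters optimization.
    """
    symbols, pos, lattice = _geometry(obj)
    n = len(pos)
    if n < 3:
        return 0.0
    if lattice is not None:
        from .structures import min_image_vectors, cart_to_frac
        frac = cart_to_frac(lattice, pos)
        dfrac = frac[:, None, :] - frac[None, :, :]
        vec = min_image_vectors(lattice, dfrac)
    else:
        vec = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(vec, axis=-1)
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            rij = dist[i, j]
            if rij == 0 or rij > params.cutoff:
                continue
            for k in range(j + 1, n):
                rik, rjk = dist[i, k], dist[j, k]
                if rik > params.cutoff or rjk > params.cutoff or rik == 0 or rjk == 0:
                    continue
                c9 = params.c9_for(symbols[i], symbols[j], symbols[k])
                if c9 == 0.0:
                    continue
                cos_i = float(vec[i, j] @ vec[i, k]) / (rij * rik)
                cos_j = float(vec[j, i] @ vec[j, k]) / (rij * rjk)
                cos_k = float(vec[k, i] @ vec[k, j]) / (rik * rjk)
                e += c9 * (3 * cos_i * cos_j * cos_k + 1) / (rij * rjk * rik) ** 3
    return e


class DispersionCalculator(Calculator):
    """Two-body damped dispersion as a Calculator (forces by differences).

    Used additively with other models during optimization; the three-body
    term is applied separately on final geometries.
    """

    def __init__(self, params: DispersionParams):
        self.params = params

    def energy_forces(self, obj):
        e = dispersion_two_body(obj, self.params)
        symbols, pos, _ = _geometry(obj)
        n = len(pos)
        f = np.zeros((n, 3))
        h = 1e-5
        for i in range(n):
            for a in range(3):
                ep = dispersion_two_body(_displaced(obj, i, a, h), self.params)
                em = dispersion_two_body(_displaced(obj, i, a, -h), self.params)
                f[i, a] = -(ep - em) / (2 * h)
        return e, f


class CompositeCalculator(Calculator):
    """Sum of component calculators (e.g. surrogate + Ewald + dispersion)."""

    def __init__(self, components: list[Calculator]):
        self.components = list(components)

    def energy_forces(self, obj):
        e = 0.0
        f = None
        for c in self.components:
            ec, fc = c.energy_forces(obj)
            e += ec
            f = fc if f is None else f + fc
        return e, f

    def stress(self, crystal, h: float = 1e-6):
        return sum(c.stress(crystal, h) for c in self.components)

    def hessian(self, obj, step: float = 0.005):
        return sum(c.hessian(obj, step) for c in self.components)


# ------------------------------------------------------------- ML surrogate


@dataclass(frozen=True)
class RadialDescriptor:
    """Smooth radial-basis fingerprint of a local atomic environment.

    Per neighbor element, Gaussians of width ``width`` centred on a uniform
    grid in (0, cutoff], each multiplied by the cosine cutoff function
    f_c(r) = ½(cos(πr/r_c)+1).  The fingerprint is invariant to rotation,
    translation and neighbor permutation and vanishes for an isolated atom.
    """

    elements: tuple[str, ...]
    cutoff: float = 5.0
    n_basis: int = 8

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.8, self.cutoff, self.n_basis)

    @property
    def width(self) -> float:
        c = self.centers
        return float(c[1] - c[0]) if self.n_basis > 1 else self.cutoff / 2

    @property
    def n_features(self) -> int:
        return len(self.elements) * self.n_basis

    def _gfc(self, r: float) -> tuple[np.ndarray, np.ndarray]:
        """Basis values and radial derivatives at distance r."""
        mu, w = self.centers, self.width
        g = np.exp(-((r - mu) ** 2) / (2 * w * w))
        dg = g * (-(r - mu) / (w * w))
        fc = 0.5 * (math.cos(math.pi * r / self.cutoff) + 1.0)
        dfc = -0.5 * math.pi / self.cutoff * math.sin(math.pi * r / self.cutoff)
        return g * fc, dg * fc + g * dfc

    def features(self, obj) -> np.ndarray:
        """Per-atom feature matrix (n_atoms, n_features)."""
        symbols, pos, lattice = _geometry(obj)
        n = len(pos)
        eidx = {e: k for k, e in enumerate(self.elements)}
        feats = np.zeros((n, self.n_features))
        nb = self.n_basis
        for i, j, rv in neighbor_pairs(pos, lattice, self.cutoff):
            r = float(np.linalg.norm(rv))
            val, _ = self._gfc(r)
            if symbols[j] in eidx:
                feats[i, eidx[symbols[j]] * nb:(eidx[symbols[j]] + 1) * nb] += val
            if symbols[i] in eidx:
                feats[j, eidx[symbols[i]] * nb:(eidx[symbols[i]] + 1) * nb] += val
        return feats

    def features_and_gradients(self, obj):
        """Features plus per-pair radial derivative data for force rows."""
        symbols, pos, lattice = _geometry(obj)
        n = len(pos)
        eidx = {e: k for k, e in enumerate(self.elements)}
        nb = self.n_basis
        feats = np.zeros((n, self.n_features))
        pairs = []  # (i, j, unit vector, dval, slot_i, slot_j)
        for i, j, rv in neighbor_pairs(pos, lattice, self.cutoff):
            r = float(np.linalg.norm(rv))
            val, dval = self._gfc(r)
            u = rv / r
            slot_j = eidx.get(symbols[j])
            slot_i = eidx.get(symbols[i])
            if slot_j is not None:
                feats[i, slot_j * nb:(slot_j + 1) * nb] += val
            if slot_i is not None:
                feats[j, slot_i * nb:(slot_i + 1) * nb] += val
            pairs.append((i, j, u, dval, slot_i, slot_j))
        return feats, pairs


@dataclass
class LabeledSample:
    """Geometry with teacher labels (energy required, forces optional)."""

    geometry: object  # NMer | Molecule
    energy: float
    forces: np.ndarray | None = None
    partial_charges: np.ndarray | None = None
    dipole: np.ndarray | None = None
    teacher: str = "teacher"

    def __post_init__(self):
        symbols, pos, _ = _geometry(self.geometry)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != pos.shape:
                raise ValueError("forces shape does not match geometry")


@dataclass
class SurrogateModel:
    """Linear per-element regression over radial descriptors.

    Predicts the total energy as a sum of atomic contributions
    E = Σ_i (w[e_i]·f_i + b[e_i]); by construction the prediction is
    invariant to atom permutation, rigid rotation and translation.
    """

    descriptor: RadialDescriptor
    weights: dict  # element -> (n_basis·n_elem,) array
    biases: dict  # element -> float
    seed: int = 0
    n_train: int = 0

    def predict_energy(self, obj) -> float:
        symbols, _, _ = _geometry(obj)
        feats = self.descriptor.features(obj)
        e = 0.0
        for s, f in zip(symbols, feats):
            e += float(self.weights[s] @ f) + self.biases[s]
        return e

    def predict_energy_forces(self, obj):
        symbols, pos, _ = _geometry(obj)
        feats, pairs = self.descriptor.features_and_gradients(obj)
        e = 0.0
        for s, f in zip(symbols, feats):
            e += float(self.weights[s] @ f) + self.biases[s]
        n = len(pos)
        nb = self.descriptor.n_basis
        forces = np.zeros((n, 3))
        for i, j, u, dval, slot_i, slot_j in pairs:
            coef = 0.0
            if slot_j is not None:
                coef += float(self.weights[symbols[i]]
                              [slot_j * nb:(slot_j + 1) * nb] @ dval)
            if slot_i is not None:
                coef += float(self.weights[symbols[j]]
                              [slot_i * nb:(slot_i + 1) * nb] @ dval)
            # dE/dx_j = coef·u, dE/dx_i = −coef·u
            forces[j] -= coef * u
            forces[i] += coef * u
        return e, forces


class SurrogateCalculator(Calculator):
    """Calculator facade over one surrogate (or the mean of an ensemble)."""

    def __init__(self, models: SurrogateModel | list[SurrogateModel]):
        self.models = models if isinstance(models, list) else [models]

    def energy_forces(self, obj):
        es, fs = [], []
        for m in self.models:
            e, f = m.predict_energy_forces(obj)
            es.append(e)
            fs.append(f)
        return float(np.mean(es)), np.mean(fs, axis=0)


def train_surrogate(samples: list[LabeledSample], seed: int = 0,
                    regularization: float = 1e-8,
                    descriptor: RadialDescriptor | None = None,
                    force_weight: float = 0.1) -> SurrogateModel:
    """Fit one surrogate by (deterministic) regularized least squares.

    The loss combines per-atom energy residuals with force residuals
    (weight ``force_weight``); the solve is a closed-form normal-equation
    solution, so the result is deterministic given (samples, seed).
    """
    if not samples:
        raise ValueError("empty training set")
    if descriptor is None:
        elems = sorted({s for smp in samples
                        for s in _geometry(smp.geometry)[0]})
        descriptor = RadialDescriptor(tuple(elems))
    elems = descriptor.elements
    nf = descriptor.n_features
    npar = len(elems) * (nf + 1)  # weights + bias per element
    eoff = {e: k * (nf + 1) for k, e in enumerate(elems)}

    rows, targets, wts = [], [], []
    for smp in samples:
        symbols, pos, _ = _geometry(smp.geometry)
        natoms = len(symbols)
        feats, pairs = descriptor.features_and_gradients(smp.geometry)
        row = np.zeros(npar)
        for s, f in zip(symbols, feats):
            off = eoff[s]
            row[off:off + nf] += f
            row[off + nf] += 1.0
        rows.append(row / natoms)
        targets.append(smp.energy / natoms)
        wts.append(1.0)
        if smp.forces is not None and force_weight > 0:
            nb = descriptor.n_basis
            frows = np.zeros((natoms, 3, npar))
            for i, j, u, dval, slot_i, slot_j in pairs:
                if slot_j is not None:
                    off = eoff[symbols[i]] + slot_j * nb
                    frows[j, :, off:off + nb] += np.outer(u, dval)
                    frows[i, :, off:off + nb] -= np.outer(u, dval)
                if slot_i is not None:
                    off = eoff[symbols[j]] + slot_i * nb
                    frows[j, :, off:off + nb] += np.outer(u, dval)
                    frows[i, :, off:off + nb] -= np.outer(u, dval)
            # F = −dE/dx
            for r, t in zip((-frows).reshape(-1, npar), smp.forces.reshape(-1)):
                rows.append(r)
                targets.append(t)
                wts.append(force_weight)

    A = np.asarray(rows)
    y = np.asarray(targets)
    w = np.sqrt(np.asarray(wts))
    A = A * w[:, None]
    y = y * w
    # normalize by the row count so duplicating the sample set leaves the
    # regularized solution exactly unchanged
    nr = len(y)
    ata = A.T @ A / nr + regularization * np.eye(npar)
    theta = np.linalg.solve(ata, A.T @ y / nr)

    weights = {e: theta[eoff[e]:eoff[e] + nf] for e in elems}
    biases = {e: float(theta[eoff[e] + nf]) for e in elems}
    return SurrogateModel(descriptor, weights, biases, seed=seed,
                          n_train=len(samples))


def train_ensemble(samples: list[LabeledSample], seed: int = 0,
                   n_models: int = 4, subset_fraction: float = 0.8,
                   regularization: float = 1e-8,
                   descriptor: RadialDescriptor | None = None,
                   force_weight: float = 0.1) -> list[SurrogateModel]:
    """Train an ensemble on distinct seeded random subsets of the samples."""
    if descriptor is None:
        elems = sorted({s for smp in samples
                        for s in _geometry(smp.geometry)[0]})
        descriptor = RadialDescriptor(tuple(elems))
    rng = np.random.default_rng(seed)
    models = []
    n = len(samples)
    k = max(1, int(round(subset_fraction * n)))
    for m in range(n_models):
        idx = sorted(rng.choice(n, size=k, replace=False))
        models.append(train_surrogate([samples[i] for i in idx],
                                      seed=seed + m,
                                      regularization=regularization,
                                      descriptor=descriptor,
                                      force_weight=force_weight))
    return models


def ensemble_predict(models: list[SurrogateModel], geometry):
    """Ensemble mean energy, sample std (ddof=1), and mean forces."""
    if len(models) < 2:
        raise ValueError("ensemble standard deviation requires >= 2 models")
    es, fs = [], []
    for m in models:
        e, f = m.predict_energy_forces(geometry)
        es.append(e)
        fs.append(f)
    return (float(np.mean(es)), float(np.std(es, ddof=1)),
            np.mean(fs, axis=0))
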