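"""Harmonic phonons and (quasi-)harmonic free energies.

Force constants come from a supercell Hessian — analytic when the
calculator provides one, otherwise by central finite displacements of
0.005 Å — with symmetrization and the acoustic sum rule applied.  The
dynamical matrix is diagonalized on a Γ-centered q-mesh; the vibrational
free energy per cell is

    F_vib = (1/N_q) Σ_{i,q} [ ħω/2 + k_B·T·ln(1 − e^(−ħω/k_BT)) ],

whose first term is the zero-point energy and whose second is the Kirchhoff
term.  Within the harmonic approximation G = E_latt + F_vib + pV at the
fixed relaxed volume; the quasi-harmonic treatment repeats the harmonic
calculation on a volume scan (default 0.95–1.15 of equilibrium in steps of
0.0125), fits each isotherm to the third-order Birch–Murnaghan equation of
state, and minimizes over volume to capture thermal expansion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .constants import HBAR, K_B, OMEGA_SI
from .structures import CrystalStructure, Lattice, Molecule
from .optimization import RelaxSettings, relax

__all__ = [
    "ForceConstants",
    "PhononSpectrum",
    "ThermoPoint",
    "ThermoCurve",
    "EOSFitError",
    "ImaginaryModeError",
    "build_supercell",
    "hessian",
    "phonon_frequencies",
    "mesh_spectrum",
    "f_vib",
    "zero_point_energy",
    "gibbs_ha",
    "birch_murnaghan_energy",
    "fit_birch_murnaghan",
    "qha",
    "heat_capacity",
]

GAMMA_ACOUSTIC_TOL = 2 * math.pi * 1e9  # rad/s ≈ 1e-3 THz


class EOSFitError(RuntimeError):
    """Equation-of-state fit could not bracket an interior minimum."""


class ImaginaryModeError(RuntimeError):
    """Imaginary phonon modes present under the strict policy."""


def build_supercell(structure: CrystalStructure, reps: tuple[int, int, int]):
    """Replicate a crystal; atoms ordered cell-major, primitive-minor.

    Returns (supercell, cell_indices) where ``cell_indices[c]`` is the
    integer lattice translation of block c.
    """
    m1, m2, m3 = reps
    cells = list(itertools.product(range(m1), range(m2), range(m3)))
    n = len(structure)
    frac = []
    species = []
    for t in cells:
        f = (structure.frac_coords + np.array(t)) / np.array(reps)
        frac.append(f)
        species.extend(structure.species)
    cell = (np.diag(reps) @ structure.lattice.cell)
    sup = CrystalStructure(Lattice(cell), species, np.vstack(frac))
    return sup, cells


@dataclass
class ForceConstants:
    """Second derivatives of the energy on a supercell.

    ``matrix`` has shape (n_prim, 3, n_cells, n_prim, 3): derivative pairs
    between reference-cell atoms and every supercell atom, in eV/Å².
    """

    structure: CrystalStructure
    reps: tuple[int, int, int]
    cells: list[tuple[int, int, int]]
    matrix: np.ndarray
    method: str
    masses: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.structure) if isinstance(self.structure,
                                                 CrystalStructure) \
            else len(self.structure.symbols)


def _supercell_reps(lattice: Lattice, min_length: float) -> tuple[int, int, int]:
    return tuple(int(math.ceil(min_length / L)) for L in lattice.lengths)


def hessian(structure, calculator, method: str = "analytic",
            min_supercell_length: float = 10.0,
            displacement: float = 0.005,
            enforce_asr: bool = True,
            force_tol_warn: float = 0.001) -> ForceConstants:
    """Force constants of a crystal (via supercell) or a finite molecule.

    ``method`` is "analytic" (calculator-provided Hessian) or
    "finite_displacement" (±0.005 Å central differences of forces).  The
    supercell multiplicities are the smallest integers making every lattice
    vector at least ``min_supercell_length``.  The matrix is symmetrized and
    the acoustic sum rule enforced on the self terms (skip for deliberately
    pinned models such as an Einstein crystal via ``enforce_asr=False``).
    """
    periodic = isinstance(structure, CrystalStructure)
    if periodic:
        reps = _supercell_reps(structure.lattice, min_supercell_length)
        sup, cells = build_supercell(structure, reps)
        calc = (calculator.for_supercell(structure, sup, reps)
                if hasattr(calculator, "for_supercell") else calculator)
        target = sup
        n = len(structure)
        masses = structure.masses
    else:
        reps = (1, 1, 1)
        cells = [(0, 0, 0)]
        calc = calculator
        target = structure
        n = len(structure.symbols)
        masses = structure.masses

    f0 = calc.forces(target)
    if np.sqrt(np.mean(f0**2)) > force_tol_warn:
        import warnings
        warnings.warn("structure not relaxed below the force tolerance; "
                      "force constants may be unreliable", stacklevel=2)

    n_sup = len(target.species) if periodic else n
    if method == "analytic":
        if "analytic_hessian" not in getattr(calc, "capabilities", ()):  # fall back
            method = "finite_displacement"
    if method == "analytic":
        full = calc.hessian(target)
        rows = full[: 3 * n, :]
    elif method == "finite_displacement":
        rows = np.zeros((3 * n, 3 * n_sup))
        from .potentials import _displaced
        for i in range(n):
            for a in range(3):
                fp = calc.forces(_displaced(target, i, a, displacement))
                fm = calc.forces(_displaced(target, i, a, -displacement))
                rows[3 * i + a] = -((fp - fm) / (2 * displacement)).reshape(-1)
    else:
        raise ValueError(f"unknown Hessian method {method!r}")

    fc = rows.reshape(n, 3, len(cells), n, 3)
    # symmetrize within the reference-cell block
    home = cells.index((0, 0, 0))
    blk = fc[:, :, home, :, :].reshape(3 * n, 3 * n)
    fc[:, :, home, :, :] = (0.5 * (blk + blk.T)).reshape(n, 3, n, 3)
    if enforce_asr:
        # row sums over all partners vanish: adjust self interaction
        sums = fc.sum(axis=(2, 3))  # (n, 3, 3)
        for i in range(n):
            fc[i, :, home, i, :] -= sums[i]
    return ForceConstants(structure, reps, cells, fc, method, masses)


def phonon_frequencies(fc: ForceConstants, qpoint) -> np.ndarray:
    """Frequencies (rad/s, ascending) at a fractional q of the primitive cell.

    Negative dynamical-matrix eigenvalues are reported as negative
    frequencies (imaginary modes of magnitude |ω|).
    """
    n = fc.n_atoms
    q = np.asarray(qpoint, dtype=float)
    # wrap cell translations to the minimum image of the supercell so the
    # Fourier interpolation uses the physical (shortest) pair vectors
    cells = np.array(fc.cells, dtype=float)
    reps = np.array(fc.reps, dtype=float)
    cells = cells - reps * np.floor(cells / reps + 0.5)
    phases = np.exp(2j * math.pi * (cells @ q))  # (n_cells,)
    dyn = np.tensordot(fc.matrix, phases, axes=([2], [0]))  # (n,3,n,3)
    m = fc.masses
    inv_sqrt_m = 1.0 / np.sqrt(m)
    dyn = dyn * inv_sqrt_m[:, None, None, None] * inv_sqrt_m[None, None, :, None]
    D = dyn.transpose(0, 1, 2, 3).reshape(3 * n, 3 * n)
    D = 0.5 * (D + D.conj().T)
    evals = np.linalg.eigvalsh(D)
    return np.sign(evals) * np.sqrt(np.abs(evals)) * OMEGA_SI


@dataclass
class PhononSpectrum:
    """Frequencies ω_{i,q} (rad/s) over weighted q-points."""

    qpoints: np.ndarray
    weights: np.ndarray
    frequencies: np.ndarray  # (n_q, 3n)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not math.isclose(self.weights.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("q-point weights must sum to 1")

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < -GAMMA_ACOUSTIC_TOL))

    def imaginary_magnitudes(self) -> np.ndarray:
        w = self.frequencies[self.frequencies < -GAMMA_ACOUSTIC_TOL]
        return -w


def mesh_spectrum(fc: ForceConstants, mesh=(8, 8, 8)) -> PhononSpectrum:
    """Γ-centered uniform q-mesh spectrum with equal weights."""
    pts = np.array([(i / mesh[0], j / mesh[1], k / mesh[2])
                    for i in range(mesh[0])
                    for j in range(mesh[1])
                    for k in range(mesh[2])])
    freqs = np.array([phonon_frequencies(fc, q) for q in pts])
    w = np.full(len(pts), 1.0 / len(pts))
    return PhononSpectrum(pts, w, freqs)


def f_vib(spectrum: PhononSpectrum, T: float,
          imaginary_policy: str = "strict") -> float:
    """Vibrational Helmholtz free energy per cell (eV).

    Modes with |ω| below the acoustic tolerance contribute nothing;
    imaginary modes raise ``ImaginaryModeError`` under the "strict" policy
    or are excluded under "drop".
    """
    if spectrum.n_imaginary:
        if imaginary_policy == "strict":
            mags = spectrum.imaginary_magnitudes()
            raise ImaginaryModeError(
                f"{len(mags)} imaginary modes, |ω| up to {mags.max():.3e} rad/s")
        if imaginary_policy != "drop":
            raise ValueError(f"unknown imaginary-mode policy {imaginary_policy!r}")
    total = 0.0
    for w, freqs in zip(spectrum.weights, spectrum.frequencies):
        omega = freqs[freqs > GAMMA_ACOUSTIC_TOL]
        hw = HBAR * omega
        zpe = 0.5 * np.sum(hw)
        if T > 0:
            kirchhoff = K_B * T * np.sum(np.log1p(-np.exp(-hw / (K_B * T))))
        else:
            kirchhoff = 0.0
        total += w * (zpe + kirchhoff)
    return float(total)


def zero_point_energy(spectrum: PhononSpectrum) -> float:
    return f_vib(spectrum, 0.0, imaginary_policy="drop")


@dataclass
class ThermoPoint:
    """G = E_latt + F_vib + pV at one (T, p, V)."""

    E_latt: float
    F_vib: float
    T: float
    p: float
    V: float

    @property
    def G(self) -> float:
        return self.E_latt + self.F_vib + self.p * self.V


def gibbs_ha(E_latt: float, spectrum: PhononSpectrum, T: float,
             p: float = 0.0, V: float = 0.0,
             imaginary_policy: str = "strict") -> ThermoPoint:
    """Harmonic-approximation Gibbs energy at the fixed relaxed volume."""
    return ThermoPoint(E_latt, f_vib(spectrum, T, imaginary_policy), T, p, V)


# ----------------------------------------------------------------- EOS + QHA


def birch_murnaghan_energy(V, F0, V0, B0, B0p):
    """Third-order Birch–Murnaghan F(V)."""
    V = np.asarray(V, dtype=float)
    eta2 = (V0 / V) ** (2.0 / 3.0)
    return F0 + 9.0 * V0 * B0 / 16.0 * (
        (eta2 - 1.0) ** 3 * B0p + (eta2 - 1.0) ** 2 * (6.0 - 4.0 * eta2))


def fit_birch_murnaghan(volumes, free_energies):
    """Fit (F₀, V₀, B₀, B₀′) of the third-order Birch–Murnaghan form.

    Requires at least 5 points bracketing an interior minimum; raises
    ``EOSFitError`` otherwise.  Returns (params, rms_residual).
    """
    V = np.asarray(volumes, dtype=float)
    F = np.asarray(free_energies, dtype=float)
    if len(V) < 5:
        raise EOSFitError("need at least 5 (V, F) points")
    order = np.argsort(V)
    V, F = V[order], F[order]
    imin = int(np.argmin(F))
    if imin in (0, len(F) - 1):
        raise EOSFitError("no interior minimum in the sampled volume range")
    # initial guess from a local quadratic
    c2, c1, c0 = np.polyfit(V[imin - 1:imin + 2], F[imin - 1:imin + 2], 2)
    v0 = -c1 / (2 * c2)
    b0 = max(2 * c2 * v0, 1e-6)
    p0 = [F[imin], v0, b0, 4.0]
    try:
        popt, _ = curve_fit(birch_murnaghan_energy, V, F, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise EOSFitError(f"Birch–Murnaghan fit failed: {exc}") from exc
    if not (V.min() <= popt[1] <= V.max()):
        raise EOSFitError("fitted V0 outside the scanned volume range")
    resid = birch_murnaghan_energy(V, *popt) - F
    rms = float(np.sqrt(np.mean(resid**2)))
    return tuple(float(x) for x in popt), rms


DEFAULT_VOLUME_FACTORS = tuple(np.round(np.arange(0.95, 1.15 + 1e-9, 0.0125), 6))


@dataclass
class ThermoCurve:
    """Quasi-harmonic result: F(V) isotherms, EOS fits, G(T), V(T)."""

    temperatures: np.ndarray
    volumes: np.ndarray  # surviving scan volumes (Å³)
    F_at_V: np.ndarray  # (n_T, n_V) eV
    U_at_V: np.ndarray  # static energies (n_V,)
    eos_params: list[tuple]  # per T: (F0, V0, B0, B0')
    G_of_T: np.ndarray
    V_of_T: np.ndarray
    pressure: float
    dropped_volumes: list[float] = field(default_factory=list)


def qha(structure: CrystalStructure, calculator,
        volume_factors=DEFAULT_VOLUME_FACTORS,
        T_list=(0.0, 300.0), p: float = 0.0,
        mesh=(8, 8, 8), min_supercell_length: float = 10.0,
        hessian_method: str = "analytic",
        relax_settings: RelaxSettings | None = None,
        imaginary_policy: str = "drop") -> ThermoCurve:
    """Quasi-harmonic free-energy scan of a pre-relaxed crystal.

    For every volume factor the cell is isotropically scaled, re-relaxed at
    fixed volume (variable cell shape and positions), its force constants
    and q-mesh spectrum computed, and F(T, V) = U(V) + F_vib(T, V) stored.
    Each isotherm is fitted with the Birch–Murnaghan form; G(T, p) is the
    minimum of the fitted curve (+pV) and V(T) its argmin.  Volume points
    with imaginary modes are dropped and logged under the default policy;
    fewer than 5 surviving points is an error.
    """
    base = relax_settings or RelaxSettings(mode="fixed_volume_variable_cell")
    v_eq = structure.lattice.volume
    vols, U, spectra = [], [], []
    dropped = []
    for fac in volume_factors:
        s = structure.copy()
        s.lattice = Lattice(structure.lattice.cell * float(fac) ** (1.0 / 3.0))
        res = relax(s, calculator, base)
        fc = hessian(res.structure, calculator, method=hessian_method,
                     min_supercell_length=min_supercell_length)
        spec = mesh_spectrum(fc, mesh)
        if spec.n_imaginary:
            if imaginary_policy == "strict":
                raise ImaginaryModeError(
                    f"imaginary modes at volume factor {fac}")
            dropped.append(float(fac * v_eq))
            continue
        vols.append(res.structure.lattice.volume)
        U.append(res.energy)
        spectra.append(spec)
    if len(vols) < 5:
        raise EOSFitError(
            f"only {len(vols)} usable volume points (≥5 required)")
    vols = np.asarray(vols)
    U = np.asarray(U)

    T_arr = np.asarray(T_list, dtype=float)
    F_at_V = np.zeros((len(T_arr), len(vols)))
    eos, G, Vmin = [], [], []
    for it, T in enumerate(T_arr):
        F_at_V[it] = U + np.array([f_vib(sp, T) for sp in spectra])
        params, _ = fit_birch_murnaghan(vols, F_at_V[it])
        eos.append(params)
        if p == 0.0:
            G.append(params[0])
            Vmin.append(params[1])
        else:
            res = minimize_scalar(
                lambda v: birch_murnaghan_energy(v, *params) + p * v,
                bounds=(vols.min(), vols.max()), method="bounded")
            G.append(float(res.fun))
            Vmin.append(float(res.x))
    return ThermoCurve(T_arr, vols, F_at_V, U, eos, np.asarray(G),
                       np.asarray(Vmin), p, dropped)


def heat_capacity(G_of_T, T_grid) -> np.ndarray:
    """Cp(T) = −T·∂²G/∂T² on a uniform temperature grid (≥ 5 points)."""
    G = np.asarray(G_of_T, dtype=float)
    T = np.asarray(T_grid, dtype=float)
    if len(T) < 5:
        raise ValueError("need at least 5 temperature points")
    dT = np.diff(T)
    if not np.allclose(dT, dT[0], rtol=1e-8):
        raise ValueError("temperature grid must be uniform")
    h = float(dT[0])
    d2 = np.empty_like(G)
    d2[1:-1] = (G[2:] - 2 * G[1:-1] + G[:-2]) / h**2
    d2[0] = (G[2] - 2 * G[1] + G[0]) / h**2  # one-sided (forward) at the ends
    d2[-1] = (G[-1] - 2 * G[-2] + G[-3]) / h**2
    return -T * d2
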