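"""Molecular shells, n-mer extraction, and tethered finite-T sampling.

A molecular shell collects every whole molecule (including distinct
periodic images) having any atom within a cutoff of any atom of a chosen
central molecule.  n-mers (n = 1–8) combine the central molecule with
shell members — nearest neighbors first, then seeded random combinations.
Tethered Langevin dynamics diversifies the clusters with out-of-equilibrium
conformations while a per-atom harmonic tether keeps them near the lattice
geometry; bond constraints are never applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import K_B
from .structures import CrystalStructure, Molecule, NMer, unwrap_molecules

__all__ = [
    "ShellSpec",
    "TetherSettings",
    "molecular_shell",
    "enumerate_nmers",
    "tethered_sampling",
]

# 1 eV/Å per amu in Å/fs²
ACC_CONV = 9.64853329e-3


@dataclass(frozen=True)
class ShellSpec:
    center_molecule: int = 0
    cutoff: float = 6.0  # Å

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def molecular_shell(crystal: CrystalStructure, spec: ShellSpec,
                    bond_scale: float = 1.2) -> list[Molecule]:
    """Whole unwrapped molecules with any atom within cutoff of the center.

    Distinct periodic images of the same molecule count as distinct shell
    members.  The central molecule is always first.
    """
    mols = unwrap_molecules(crystal, bond_scale)
    if not (0 <= spec.center_molecule < len(mols)):
        raise ValueError(f"invalid center molecule id {spec.center_molecule}")
    center = mols[spec.center_molecule]
    cell = crystal.lattice.cell
    # image range: shell cutoff plus molecular extent, per lattice direction
    extent = max(float(np.linalg.norm(m.positions - m.centroid, axis=1).max(),
                       ) for m in mols)
    vol = crystal.lattice.volume
    reps = []
    for a in range(3):
        cross = np.cross(cell[(a + 1) % 3], cell[(a + 2) % 3])
        spacing = vol / np.linalg.norm(cross)
        reps.append(int(math.ceil((spec.cutoff + 2 * extent) / spacing)) + 1)
    shell = [center]
    for mol_id, mol in enumerate(mols):
        for shift in itertools.product(*[range(-m, m + 1) for m in reps]):
            if mol_id == spec.center_molecule and shift == (0, 0, 0):
                continue
            offset = np.asarray(shift, dtype=float) @ cell
            pos = mol.positions + offset
            dmin = np.min(np.linalg.norm(
                pos[:, None, :] - center.positions[None, :, :], axis=-1))
            if dmin <= spec.cutoff:
                shell.append(replace(mol, positions=pos))
    return shell


def _min_intermolecular_distance(a: Molecule, b: Molecule) -> float:
    d = a.positions[:, None, :] - b.positions[None, :, :]
    return float(np.linalg.norm(d, axis=-1).min())


def enumerate_nmers(crystal: CrystalStructure, n_max: int,
                    per_order_counts: int | dict = 5, seed: int = 0,
                    shell: ShellSpec = ShellSpec(),
                    total_charge: int = 0) -> list[NMer]:
    """n-mers for orders 1..n_max around the central molecule.

    For each order n the first n-mer is the central molecule plus its n−1
    nearest shell members (by minimum intermolecular atom–atom distance);
    further member sets are drawn at random (seeded, without duplicates) up
    to the per-order count.  Orders exceeding the shell size yield fewer
    n-mers and are flagged via the returned list's ``short_orders``
    attribute access pattern: the function simply emits what exists.
    """
    if not (1 <= n_max <= 8):
        raise ValueError("n_max must be in 1..8")
    members = molecular_shell(crystal, shell)
    center, neighbors = members[0], members[1:]
    order_idx = np.argsort([
        _min_intermolecular_distance(center, m) for m in neighbors])
    neighbors = [neighbors[i] for i in order_idx]
    rng = np.random.default_rng(seed)
    out: list[NMer] = [NMer([center], total_charge)]
    for n in range(2, n_max + 1):
        want = per_order_counts.get(n) if isinstance(per_order_counts, dict) \
            else per_order_counts
        if want is None or want < 1:
            continue
        k = n - 1
        if k > len(neighbors):
            continue  # shell too small for this order; emit nothing
        chosen: list[tuple[int, ...]] = [tuple(range(k))]  # nearest set first
        n_comb = math.comb(len(neighbors), k)
        attempts = 0
        while len(chosen) < min(want, n_comb) and attempts < 100 * want:
            cand = tuple(sorted(rng.choice(len(neighbors), size=k,
                                           replace=False).tolist()))
            if cand not in chosen:
                chosen.append(cand)
            attempts += 1
        for sel in chosen:
            out.append(NMer([center] + [neighbors[i] for i in sel],
                            total_charge))
    return out


@dataclass(frozen=True)
class TetherSettings:
    """Langevin dynamics with per-atom harmonic tethers.

    The tether adds k_tether·|x − x₀|² per atom (x₀ the starting
    positions); no bond constraints are applied.
    """

    k_tether: float = 0.005  # eV/Å²
    temperature: float = 300.0  # K
    n_steps: int = 5000
    timestep: float = 1.0  # fs
    friction: float = 0.01  # fs⁻¹
    stride: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.k_tether < 0 or self.temperature < 0:
            raise ValueError("k_tether and temperature must be non-negative")


def tethered_sampling(nmer: NMer | Molecule, calculator,
                      settings: TetherSettings = TetherSettings()
                      ) -> list[np.ndarray]:
    """Sample perturbed geometries by tethered Langevin dynamics.

    BAOAB-split Langevin integration at ``settings.temperature``; frames are
    collected every ``stride`` steps.  Deterministic for a fixed seed.
    Raises on non-finite forces.
    """
    geom = nmer.as_molecule_graph() if isinstance(nmer, NMer) else nmer
    x0 = geom.positions.copy()
    x = x0.copy()
    m = geom.masses[:, None]
    rng = np.random.default_rng(settings.seed)
    dt = settings.timestep
    # keep the integrator stable for stiff tethers: resolve the fastest
    # tether oscillation with at least ~30 substeps per period
    if settings.k_tether > 0:
        omega_t = math.sqrt(2.0 * settings.k_tether * ACC_CONV / float(m.min()))
        n_sub = max(1, int(math.ceil(dt * omega_t / 0.2)))
    else:
        n_sub = 1
    dt = dt / n_sub
    c1 = math.exp(-settings.friction * dt)
    kT = K_B * settings.temperature
    sigma_v = np.sqrt(kT * ACC_CONV / m)  # Å/fs per component
    v = rng.normal(size=x.shape) * sigma_v if settings.temperature > 0 \
        else np.zeros_like(x)

    def total_force(pos):
        work = replace(geom, positions=pos) if not geom.bonds else None
        if work is None:
            work = Molecule.__new__(Molecule)
            work.symbols = geom.symbols
            work.positions = pos
            work.bonds = geom.bonds
            work.formal_charge = geom.formal_charge
        f = calculator.forces(work)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite forces during tethered sampling")
        return f - 2.0 * settings.k_tether * (pos - x0)

    frames = []
    f = total_force(x)
    for step in range(1, settings.n_steps + 1):
        for _ in range(n_sub):
            v = v + 0.5 * dt * ACC_CONV * f / m
            x = x + 0.5 * dt * v
            if settings.temperature > 0:
                v = c1 * v + math.sqrt(1 - c1 * c1) * sigma_v \
                    * rng.normal(size=x.shape)
            else:
                v = c1 * v
            x = x + 0.5 * dt * v
            f = total_force(x)
            v = v + 0.5 * dt * ACC_CONV * f / m
        if step % settings.stride == 0:
            frames.append(x.copy())
    return frames
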