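"""Random molecular-crystal generation with physical close-contact constraints.

A candidate is built by sampling a unit cell inside a volume window around a
van-der-Waals-sphere volume estimate, placing the first molecule at a random
position and orientation, and replicating it with the space-group operators
(general positions only).  Candidates violating the intermolecular contact
criterion d_AB > s_r·(r_A + r_B) are rejected and re-sampled.  A rigid-body
compression stage ("rigid press") then densifies loosely packed cells while
keeping every molecule's internal geometry frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .constants import get_element
from .structures import (
    CrystalStructure,
    Lattice,
    Molecule,
    cart_to_frac,
    frac_to_cart,
    identify_molecules,
    unwrap_molecules,
)
from .potentials import neighbor_pairs

__all__ = [
    "ContactCriterion",
    "GenerationConfig",
    "GenerationFailure",
    "SPACE_GROUP_WHITELIST",
    "estimate_volume",
    "contact_violations",
    "generate_candidate",
    "rigid_press",
]

# supported groups: symbol -> (IT number, lattice system)
SPACE_GROUP_WHITELIST = {
    "P1": (1, "triclinic"),
    "P-1": (2, "triclinic"),
    "P21": (4, "monoclinic"),
    "P21/c": (14, "monoclinic"),
    "C2/c": (15, "monoclinic"),
    "P212121": (19, "orthorhombic"),
    "Pna21": (33, "orthorhombic"),
    "Pbca": (61, "orthorhombic"),
}


@dataclass(frozen=True)
class ContactCriterion:
    """Specific-radius-ratio contact rule: allowed iff d > s_r·(r_A + r_B)."""

    s_r: float = 0.8

    def __post_init__(self):
        if not (0 < self.s_r <= 1.5):
            raise ValueError("s_r must be in (0, 1.5]")


@dataclass
class GenerationConfig:
    space_groups: list[str] = field(default_factory=lambda: ["P1", "P-1"])
    Z_values: list[int] = field(default_factory=lambda: [2])
    volume_window: float = 0.15  # fractional ± around the volume estimate
    packing_factor: float = 0.55
    max_attempts: int = 2000
    seed: int = 0

    def __post_init__(self):
        for sg in self.space_groups:
            if sg not in SPACE_GROUP_WHITELIST:
                raise ValueError(f"unsupported space group {sg!r}")
        if any(z < 1 for z in self.Z_values):
            raise ValueError("Z must be >= 1")


class GenerationFailure(RuntimeError):
    """Raised when no valid candidate is found within the attempt budget."""

    def __init__(self, attempts: int, message: str = ""):
        self.attempts = attempts
        super().__init__(message or f"generation failed after {attempts} attempts")


def estimate_volume(molecule: Molecule, Z: int, packing_factor: float = 0.55
                    ) -> float:
    """Unit-cell volume estimate: Z·(Σ 4/3·π·r_vdW³)/packing_factor (Å³)."""
    vol = sum(4.0 / 3.0 * math.pi * get_element(s).vdw_radius ** 3
              for s in molecule.symbols)
    return Z * vol / packing_factor


def contact_violations(crystal: CrystalStructure,
                       criterion: ContactCriterion = ContactCriterion(),
                       bond_scale: float = 1.2) -> list[tuple]:
    """Intermolecular close contacts violating d > s_r·(r_A + r_B).

    Returns (site_i, site_j, d, threshold) for every intermolecular pair —
    including contacts between a molecule and its own periodic images —
    whose minimum-image distance is at or below the threshold.  Pairs inside
    one molecule (at the image realizing its bond graph) are never reported.
    """
    if crystal.molecule_of_site is None:
        crystal = identify_molecules(crystal, bond_scale)
    labels = crystal.molecule_of_site
    rv_vdw = np.array([get_element(s).vdw_radius for s in crystal.species])
    max_thr = criterion.s_r * 2 * float(rv_vdw.max())

    # internal (unwrapped) displacement per same-molecule pair, to tell the
    # bonded image apart from genuine image-image contacts
    mols = unwrap_molecules(crystal, bond_scale)
    site_order = []
    for mol_id in range(int(labels.max()) + 1):
        site_order.append(np.flatnonzero(labels == mol_id))
    internal_pos = np.zeros((len(crystal), 3))
    for mol, sites in zip(mols, site_order):
        internal_pos[sites] = mol.positions

    pos = crystal.cart_coords
    out = []
    for i, j, rvec in neighbor_pairs(pos, crystal.lattice, max_thr):
        d = float(np.linalg.norm(rvec))
        thr = criterion.s_r * (rv_vdw[i] + rv_vdw[j])
        if d > thr:
            continue
        if labels[i] == labels[j]:
            v_int = internal_pos[j] - internal_pos[i]
            if np.linalg.norm(rvec - v_int) < 1e-6:
                continue  # the intramolecular image of this pair
        out.append((int(i), int(j), d, float(thr)))
    return out


# ------------------------------------------------------------ cell sampling


def _sample_cell(rng: np.random.Generator, system: str, volume: float) -> Lattice:
    ratios = np.exp(rng.normal(0.0, 0.25, size=3))
    if system == "triclinic":
        angles = rng.uniform(60.0, 120.0, size=3)
    elif system == "monoclinic":
        angles = np.array([90.0, rng.uniform(60.0, 120.0), 90.0])
    else:  # orthorhombic
        angles = np.array([90.0, 90.0, 90.0])
    for _ in range(50):
        try:
            lat = Lattice.from_parameters(*ratios, *angles)
            break
        except ValueError:
            angles = rng.uniform(75.0, 105.0, size=3) if system == "triclinic" \
                else angles
    scale = (volume / lat.volume) ** (1.0 / 3.0)
    return Lattice(lat.cell * scale)


def _op_matrices(op: gemmi.Op, cell: np.ndarray):
    """Cartesian rotation (row-vector convention) and translation for an op."""
    W = np.array(op.rot, dtype=float) / op.DEN
    w = np.array(op.tran, dtype=float) / op.DEN
    inv = np.linalg.inv(cell)
    M = inv @ W.T @ cell  # cart' = cart @ M + w·cell
    return M, w @ cell


def generate_candidate(molecules: list[Molecule] | Molecule, space_group: str,
                       Z: int, criterion: ContactCriterion,
                       config: GenerationConfig, seed: int
                       ) -> CrystalStructure:
    """Generate one symmetry-constrained candidate crystal.

    ``molecules`` is a conformer pool; a member is drawn uniformly at random
    for each placed molecule.  Z must be divisible by the group's
    general-position multiplicity; the quotient gives the number of
    independently placed molecules.
    """
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    if space_group not in SPACE_GROUP_WHITELIST:
        raise ValueError(f"unsupported space group {space_group!r}")
    sg_number, system = SPACE_GROUP_WHITELIST[space_group]
    ops = list(gemmi.SpaceGroup(sg_number).operations())
    mult = len(ops)
    if Z % mult != 0:
        raise ValueError(
            f"Z={Z} not divisible by general-position multiplicity {mult} "
            f"of {space_group}")
    n_indep = Z // mult
    rng = np.random.default_rng(seed)

    v_est = estimate_volume(molecules[0], Z, config.packing_factor)
    for attempt in range(1, config.max_attempts + 1):
        volume = v_est * rng.uniform(1 - config.volume_window,
                                     1 + config.volume_window)
        lattice = _sample_cell(rng, system, volume)
        species: list[str] = []
        frac: list[np.ndarray] = []
        mol_ids: list[int] = []
        mol_count = 0
        for _ in range(n_indep):
            mol = molecules[rng.integers(len(molecules))]
            quat = rng.normal(size=4)
            quat /= np.linalg.norm(quat)
            R = Rotation.from_quat(quat).as_matrix()
            body = (mol.positions - mol.centroid) @ R.T
            centroid_frac = rng.uniform(0, 1, size=3)
            base_cart = body + frac_to_cart(lattice, centroid_frac)
            for op in ops:
                M, t = _op_matrices(op, lattice.cell)
                cart = base_cart @ M + t
                species.extend(mol.symbols)
                frac.extend(cart_to_frac(lattice, cart))
                mol_ids.extend([mol_count] * len(mol))
                mol_count += 1
        cand = CrystalStructure(lattice, species, np.array(frac), Z=mol_count,
                                space_group=sg_number,
                                molecule_of_site=np.array(mol_ids))
        if not contact_violations(cand, criterion):
            return cand
    raise GenerationFailure(config.max_attempts)


# -------------------------------------------------------------- rigid press


def _overlap_penalty(pos_by_mol, lattice, rv_vdw_by_mol, s_r):
    """Σ max(0, thr − d)² over intermolecular minimum-image contacts."""
    pos = np.vstack(pos_by_mol)
    rv = np.concatenate(rv_vdw_by_mol)
    labels = np.concatenate([np.full(len(p), k)
                             for k, p in enumerate(pos_by_mol)])
    pen = 0.0
    max_thr = s_r * 2 * float(rv.max())
    for i, j, rvec in neighbor_pairs(pos, lattice, max_thr):
        d = float(np.linalg.norm(rvec))
        thr = s_r * (rv[i] + rv[j])
        if d >= thr:
            continue
        if labels[i] == labels[j]:
            v_int = pos[j] - pos[i]
            if np.linalg.norm(rvec - v_int) < 1e-6:
                continue
        pen += (thr - d) ** 2
    return pen


def rigid_press(crystal: CrystalStructure,
                criterion: ContactCriterion = ContactCriterion(),
                expansion_factor: float = 1.6,
                max_outer: int = 60,
                shrink_step: float = 0.04) -> CrystalStructure:
    """Compress a crystal of rigid molecules toward close packing.

    The cell volume is first expanded by ``expansion_factor``; the algorithm
    then repeatedly shrinks the cell isotropically and re-minimizes a smooth
    pairwise overlap penalty over cell strain plus per-molecule rigid-body
    translations and rotations, accepting a shrink only when the penalty can
    be driven back to zero.  Stops when the accepted volume step falls below
    0.1 %.  Space-group symmetry of the input is not preserved.

    Internal molecular geometry is exactly rigid by construction.  A
    ``rigid_press_converged`` flag in the returned structure's ``__dict__``
    records whether the stop criterion (rather than the iteration cap) ended
    the run.
    """
    mols = unwrap_molecules(crystal)
    bodies = [m.positions - m.centroid for m in mols]
    rv_by_mol = [np.array([get_element(s).vdw_radius for s in m.symbols])
                 for m in mols]
    cell0 = crystal.lattice.cell * expansion_factor ** (1.0 / 3.0)
    centroids_frac = [cart_to_frac(Lattice(cell0), m.centroid)
                      for m in mols]
    nmol = len(mols)

    def unpack(x, cell_base):
        eps = np.zeros((3, 3))
        eps[np.diag_indices(3)] = x[:3]
        eps[0, 1] = eps[1, 0] = x[3]
        eps[0, 2] = eps[2, 0] = x[4]
        eps[1, 2] = eps[2, 1] = x[5]
        cell = cell_base @ (np.eye(3) + eps).T
        lat = Lattice(cell)
        pos_by_mol = []
        for k in range(nmol):
            t = x[6 + 6 * k:9 + 6 * k]
            rotvec = x[9 + 6 * k:12 + 6 * k]
            R = Rotation.from_rotvec(rotvec).as_matrix()
            cart = bodies[k] @ R.T + frac_to_cart(lat, centroids_frac[k]) + t
            pos_by_mol.append(cart)
        return lat, pos_by_mol

    def objective(x, cell_base):
        lat, pos_by_mol = unpack(x, cell_base)
        return _overlap_penalty(pos_by_mol, lat, rv_by_mol, criterion.s_r)

    cell_base = cell0
    x = np.zeros(6 + 6 * nmol)
    best = None
    converged = False
    step = shrink_step
    for _ in range(max_outer):
        scale = (1.0 - step) ** (1.0 / 3.0)
        trial_base = cell_base * scale
        res = minimize(objective, x, args=(trial_base,), method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-12})
        vol_before = abs(np.linalg.det(cell_base))
        vol_after = abs(np.linalg.det(unpack(res.x, trial_base)[0].cell))
        if res.fun <= 1e-12 and vol_after < vol_before * (1 - 1e-6):
            # accept the shrink; refold state into the new base
            lat, pos_by_mol = unpack(res.x, trial_base)
            cell_base = lat.cell
            centroids_frac[:] = [cart_to_frac(lat, p.mean(axis=0))
                                 for p in pos_by_mol]
            for k, p in enumerate(pos_by_mol):
                com = p.mean(axis=0)
                bodies[k] = p - com
            x = np.zeros_like(x)
            best = (lat, pos_by_mol)
        else:
            step *= 0.5
            if step < 1e-3:
                converged = True
                break
    if best is None:
        lat, pos_by_mol = unpack(np.zeros_like(x), cell0)
        best = (lat, pos_by_mol)
    lat, pos_by_mol = best
    species = [s for m in mols for s in m.symbols]
    frac = np.vstack([cart_to_frac(lat, p) for p in pos_by_mol])
    mol_ids = np.concatenate([np.full(len(m), k) for k, m in enumerate(mols)])
    out = CrystalStructure(lat, species, frac, Z=nmol,
                           molecule_of_site=mol_ids)
    out.__dict__["rigid_press_converged"] = converged
    return out
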