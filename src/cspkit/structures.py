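"""Core data model: periodic crystals, finite molecules, n-mers, and I/O.

Crystals carry a lattice (3 row vectors, Å), per-site species and fractional
coordinates; molecules are finite Cartesian fragments with explicit bonds.
CIF is read/written through gemmi's CIF layer (write: P1 with explicit
sites); extended XYZ with a ``Lattice=`` header serves periodic structures
and plain XYZ serves molecules and clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from gemmi import cif as gcif
import gemmi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import AMU_G, get_element

__all__ = [
    "Lattice",
    "Molecule",
    "CrystalStructure",
    "NMer",
    "frac_to_cart",
    "cart_to_frac",
    "min_image_vectors",
    "min_image_distance",
    "identify_molecules",
    "unwrap_molecules",
    "density",
    "read_cif",
    "write_cif",
    "read_extxyz",
    "write_extxyz",
    "read_xyz",
    "write_xyz",
]

# shifts searched for the minimum image: a 5×5×5 block around the wrapped
# difference, enough for the moderately skewed cells this toolkit produces
_SHIFTS = np.array(list(itertools.product(range(-2, 3), repeat=3)), dtype=float)


@dataclass(frozen=True)
class Lattice:
    """Right-handed periodic cell given as 3 row vectors in Å."""

    cell: np.ndarray

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        object.__setattr__(self, "cell", cell)
        if not np.all(np.isfinite(cell)):
            raise ValueError("lattice vectors must be finite")
        if np.linalg.det(cell) <= 0:
            raise ValueError("cell determinant must be positive (right-handed)")

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.cell))

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.cell, axis=1)

    @property
    def angles(self) -> np.ndarray:
        """Cell angles (α, β, γ) in degrees."""
        a, b, c = self.cell
        alpha = _angle(b, c)
        beta = _angle(a, c)
        gamma = _angle(a, b)
        return np.array([alpha, beta, gamma])

    @classmethod
    def from_parameters(cls, a, b, c, alpha, beta, gamma) -> "Lattice":
        """Build the conventional row-vector cell from lengths/angles (deg)."""
        al, be, ga = np.radians([alpha, beta, gamma])
        v1 = [a, 0.0, 0.0]
        v2 = [b * math.cos(ga), b * math.sin(ga), 0.0]
        cx = c * math.cos(be)
        cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz2 = c * c - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("degenerate cell parameters")
        v3 = [cx, cy, math.sqrt(cz2)]
        return cls(np.array([v1, v2, v3]))


def _angle(u, v) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def frac_to_cart(lattice: Lattice, frac: np.ndarray) -> np.ndarray:
    return np.asarray(frac, dtype=float) @ lattice.cell


def cart_to_frac(lattice: Lattice, cart: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(lattice.cell)
    return np.asarray(cart, dtype=float) @ inv


def min_image_vectors(lattice: Lattice, dfrac: np.ndarray) -> np.ndarray:
    """Minimum-image Cartesian vectors for fractional differences.

    Accepts an (..., 3) array; the difference is first wrapped to
    [-0.5, 0.5) and then refined over a 5×5×5 block of lattice images.
    """
    dfrac = np.asarray(dfrac, dtype=float)
    wrapped = dfrac - np.round(dfrac)
    cand = wrapped[..., None, :] + _SHIFTS  # (..., 125, 3)
    cart = cand @ lattice.cell
    d2 = np.sum(cart * cart, axis=-1)
    idx = np.argmin(d2, axis=-1)
    return np.take_along_axis(cart, idx[..., None, None], axis=-2).squeeze(-2)


def min_image_distance(lattice: Lattice, p1_frac, p2_frac) -> float:
    """Shortest distance between two fractional points over periodic images."""
    vec = min_image_vectors(lattice, np.asarray(p2_frac) - np.asarray(p1_frac))
    return float(np.linalg.norm(vec))


@dataclass
class Molecule:
    """Finite molecule: element symbols, Cartesian positions (Å), bonds.

    Bonds are unordered index pairs; the bond graph must form a single
    connected component.
    """

    symbols: list[str]
    positions: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.positions):
            raise ValueError("symbols/positions length mismatch")
        for s in self.symbols:
            get_element(s)
        n = len(self.symbols)
        self.bonds = [tuple(sorted(map(int, b))) for b in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
        if n > 1 and self.bonds:
            if _n_components(n, self.bonds) != 1:
                raise ValueError("molecule bond graph is not connected")

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_geometry(cls, symbols, positions, bond_scale: float = 1.2,
                      formal_charge: int = 0) -> "Molecule":
        """Perceive bonds from covalent radii: d ≤ bond_scale·(r_i + r_j)."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        rc = np.array([get_element(s).covalent_radius for s in symbols])
        bonds = []
        for i in range(len(symbols)):
            for j in range(i + 1, len(symbols)):
                d = np.linalg.norm(positions[i] - positions[j])
                if d <= bond_scale * (rc[i] + rc[j]):
                    bonds.append((i, j))
        return cls(list(symbols), positions, bonds, formal_charge)

    @property
    def masses(self) -> np.ndarray:
        return np.array([get_element(s).mass for s in self.symbols])

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, vec) -> "Molecule":
        return replace(self, positions=self.positions + np.asarray(vec))

    def distance_matrix(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)


def _n_components(n: int, edges: list[tuple[int, int]]) -> int:
    if not edges:
        return n
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


@dataclass
class CrystalStructure:
    """Periodic crystal: lattice + per-site species + fractional coordinates.

    ``molecule_of_site`` (filled by :func:`identify_molecules`) partitions
    sites into whole molecules; ``Z`` counts molecules per cell.  Optional
    per-site charges support point-charge electrostatics.
    """

    lattice: Lattice
    species: list[str]
    frac_coords: np.ndarray
    Z: int | None = None
    space_group: int | None = None
    molecule_of_site: np.ndarray | None = None
    total_charge: int = 0
    site_charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frac_coords = np.mod(
            np.asarray(self.frac_coords, dtype=float).reshape(-1, 3), 1.0
        )
        if len(self.species) != len(self.frac_coords):
            raise ValueError("species/frac_coords length mismatch")
        for s in self.species:
            get_element(s)
        if self.Z is not None and self.Z < 1:
            raise ValueError("Z must be >= 1")
        if self.space_group is not None and not (1 <= self.space_group <= 230):
            raise ValueError("space group number must be in 1..230")
        if self.molecule_of_site is not None:
            mos = np.asarray(self.molecule_of_site, dtype=int)
            if len(mos) != len(self.species):
                raise ValueError("molecule_of_site length mismatch")
            ids = np.unique(mos)
            if not np.array_equal(ids, np.arange(len(ids))):
                raise ValueError("molecule ids must be 0..n_mol-1 and cover all sites")
            self.molecule_of_site = mos
        if self.site_charges is not None:
            self.site_charges = np.asarray(self.site_charges, dtype=float)
            if len(self.site_charges) != len(self.species):
                raise ValueError("site_charges length mismatch")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def cart_coords(self) -> np.ndarray:
        return frac_to_cart(self.lattice, self.frac_coords)

    @property
    def masses(self) -> np.ndarray:
        return np.array([get_element(s).mass for s in self.species])

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            Lattice(self.lattice.cell.copy()),
            list(self.species),
            self.frac_coords.copy(),
            Z=self.Z,
            space_group=self.space_group,
            molecule_of_site=(None if self.molecule_of_site is None
                              else self.molecule_of_site.copy()),
            total_charge=self.total_charge,
            site_charges=(None if self.site_charges is None
                          else self.site_charges.copy()),
        )


@dataclass
class NMer:
    """Finite cluster of n whole molecules (n = 1–8) used as training geometry."""

    molecules: list[Molecule]
    total_charge: int = 0

    def __post_init__(self) -> None:
        if not (1 <= len(self.molecules) <= 8):
            raise ValueError("n-mer order must be between 1 and 8")

    @property
    def order(self) -> int:
        return len(self.molecules)

    @property
    def symbols(self) -> list[str]:
        return [s for m in self.molecules for s in m.symbols]

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([m.positions for m in self.molecules])

    @property
    def n_atoms(self) -> int:
        return sum(len(m) for m in self.molecules)

    def as_molecule_graph(self) -> Molecule:
        """All atoms concatenated; intermolecular bonds never added."""
        offs = np.cumsum([0] + [len(m) for m in self.molecules[:-1]])
        bonds = []
        for off, m in zip(offs, self.molecules):
            bonds.extend((int(off) + i, int(off) + j) for i, j in m.bonds)
        mol = Molecule.__new__(Molecule)
        mol.symbols = self.symbols
        mol.positions = self.positions
        mol.bonds = bonds
        mol.formal_charge = self.total_charge
        return mol


# ---------------------------------------------------------------- geometry ops


def identify_molecules(crystal: CrystalStructure, bond_scale: float = 1.2
                       ) -> CrystalStructure:
    """Partition sites into molecules by covalent-radius bond detection.

    Sites i, j are bonded iff their minimum-image distance is at most
    ``bond_scale × (r_cov,i + r_cov,j)``; molecules are the connected
    components of that graph (bonds across periodic boundaries honored).
    Returns a copy with ``molecule_of_site`` and ``Z`` filled.
    """
    n = len(crystal)
    rc = np.array([get_element(s).covalent_radius for s in crystal.species])
    dfrac = crystal.frac_coords[:, None, :] - crystal.frac_coords[None, :, :]
    vecs = min_image_vectors(crystal.lattice, dfrac)
    dist = np.linalg.norm(vecs, axis=-1)
    thresh = bond_scale * (rc[:, None] + rc[None, :])
    adj = (dist <= thresh) & ~np.eye(n, dtype=bool)
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    # renumber by first occurrence so labelling is order-stable
    order = {}
    for lab in labels:
        order.setdefault(int(lab), len(order))
    labels = np.array([order[int(lab)] for lab in labels])
    out = crystal.copy()
    out.molecule_of_site = labels
    out.Z = int(ncomp)
    return out


def unwrap_molecules(crystal: CrystalStructure, bond_scale: float = 1.2
                     ) -> list[Molecule]:
    """Extract whole molecules with unwrapped Cartesian coordinates.

    Each molecule is rebuilt by a breadth-first walk over its bond graph,
    translating atoms by the lattice images that realize each bond, so no
    bond crosses a cell boundary in the result.
    """
    if crystal.molecule_of_site is None:
        crystal = identify_molecules(crystal, bond_scale)
    rc = np.array([get_element(s).covalent_radius for s in crystal.species])
    n = len(crystal)
    mols: list[Molecule] = []
    labels = crystal.molecule_of_site
    for mol_id in range(int(labels.max()) + 1):
        sites = np.flatnonzero(labels == mol_id)
        local = {int(s): k for k, s in enumerate(sites)}
        frac = crystal.frac_coords[sites].copy()
        # BFS unwrap
        seen = {0}
        queue = [0]
        pos = np.zeros_like(frac)
        pos[0] = frac[0]
        bonds = []
        while queue:
            a = queue.pop(0)
            for b in range(len(sites)):
                d = frac[b] - pos[a]
                d_wrapped = d - np.round(d)
                vec = d_wrapped @ crystal.lattice.cell
                dist = np.linalg.norm(vec)
                ia, ib = sites[a], sites[b]
                if a != b and dist <= bond_scale * (rc[ia] + rc[ib]):
                    if b not in seen:
                        pos[b] = pos[a] + d_wrapped
                        seen.add(b)
                        queue.append(b)
                    if a < b:
                        bonds.append((a, b))
        cart = frac_to_cart(crystal.lattice, pos)
        symbols = [crystal.species[int(s)] for s in sites]
        mols.append(Molecule(symbols, cart, bonds))
    return mols


def density(crystal: CrystalStructure) -> float:
    """Mass density in g/cm³ (total cell mass over cell volume)."""
    mass_g = crystal.masses.sum() * AMU_G
    vol_cm3 = crystal.lattice.volume * 1e-24
    return mass_g / vol_cm3


# --------------------------------------------------------------------- CIF I/O


def write_cif(crystal: CrystalStructure, name: str = "cspkit") -> str:
    """Serialize as a P1 CIF with explicit sites.

    Any space-group assignment on the structure is emitted as an annotation
    only; sites are always the full P1 set.
    """
    lat = crystal.lattice
    a, b, c = lat.lengths
    al, be, ga = lat.angles
    lines = [
        f"data_{name}",
        f"_cell_length_a {a:.10f}",
        f"_cell_length_b {b:.10f}",
        f"_cell_length_c {c:.10f}",
        f"_cell_angle_alpha {al:.10f}",
        f"_cell_angle_beta {be:.10f}",
        f"_cell_angle_gamma {ga:.10f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "_symmetry_Int_Tables_number 1",
    ]
    if crystal.space_group is not None:
        lines.append(f"_cspkit_annotated_space_group {crystal.space_group}")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    counts: dict[str, int] = {}
    for sym, f in zip(crystal.species, crystal.frac_coords):
        counts[sym] = counts.get(sym, 0) + 1
        lines.append(
            f"{sym}{counts[sym]} {sym} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}"
        )
    return "\n".join(lines) + "\n"


_CELL_TAGS = ["_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"]


def read_cif(text: str, merge_tol: float = 1e-3) -> CrystalStructure:
    """Parse a CIF (P1 or with a symmetry-operator list) into a crystal.

    Listed symmetry operations are applied to expand the asymmetric unit to
    the full P1 site set; duplicates closer than ``merge_tol`` (fractional,
    min-image) are merged.  Unknown tags are ignored.
    """
    doc = gcif.read_string(text)
    block = doc.sole_block()
    params = []
    for tag in _CELL_TAGS:
        val = block.find_value(tag)
        if val is None:
            raise ValueError(f"CIF missing required cell tag {tag}")
        params.append(float(gcif.as_number(val)))
    lattice = Lattice.from_parameters(*params)

    sym_col = None
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        if len(col) > 0:
            sym_col = [gcif.as_string(v) for v in col]
            break
    ops = [gemmi.Op(s) for s in sym_col] if sym_col else [gemmi.Op("x,y,z")]

    labels = block.find_loop("_atom_site_type_symbol")
    if len(labels) == 0:
        labels = block.find_loop("_atom_site_label")
    if len(labels) == 0:
        raise ValueError("CIF missing _atom_site loop")
    syms = []
    for raw in labels:
        s = gcif.as_string(raw)
        sym = s[:2] if len(s) >= 2 and s[:2].capitalize() in _known_symbols() else s[0]
        sym = sym.capitalize()
        if sym not in _known_symbols():
            raise ValueError(f"unknown element symbol in CIF: {s!r}")
        syms.append(sym)
    fx = [float(gcif.as_number(v)) for v in block.find_loop("_atom_site_fract_x")]
    fy = [float(gcif.as_number(v)) for v in block.find_loop("_atom_site_fract_y")]
    fz = [float(gcif.as_number(v)) for v in block.find_loop("_atom_site_fract_z")]
    if not (len(fx) == len(fy) == len(fz) == len(syms)):
        raise ValueError("inconsistent _atom_site loop lengths")
    asym = np.array([fx, fy, fz]).T

    species: list[str] = []
    frac: list[np.ndarray] = []
    for sym, f in zip(syms, asym):
        for op in ops:
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            new = np.mod(rot @ f + tran, 1.0)
            dup = False
            for g in frac:
                d = new - g
                if np.linalg.norm(d - np.round(d)) < merge_tol:
                    dup = True
                    break
            if not dup:
                species.append(sym)
                frac.append(new)
    return CrystalStructure(lattice, species, np.array(frac))


def _known_symbols() -> set[str]:
    from .constants import ELEMENTS
    return set(ELEMENTS)


# -------------------------------------------------------------------- XYZ I/O


def write_xyz(mol: Molecule | NMer, comment: str = "") -> str:
    if isinstance(mol, NMer):
        symbols, positions = mol.symbols, mol.positions
    else:
        symbols, positions = mol.symbols, mol.positions
    out = [str(len(symbols)), comment.replace("\n", " ")]
    for s, p in zip(symbols, positions):
        out.append(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    return "\n".join(out) + "\n"


def read_xyz(text: str, bond_scale: float = 1.2) -> Molecule:
    lines = text.strip().splitlines()
    n = int(lines[0])
    symbols, pos = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    return Molecule.from_geometry(symbols, np.array(pos), bond_scale=bond_scale)


def write_extxyz(crystal: CrystalStructure, extra: dict | None = None) -> str:
    """Extended-XYZ frame with a ``Lattice=`` header (Cartesian positions)."""
    cell = crystal.lattice.cell
    lat = " ".join(f"{x:.10f}" for x in cell.reshape(-1))
    props = 'Properties=species:S:1:pos:R:3'
    fields = [f'Lattice="{lat}"', props, "pbc=\"T T T\""]
    for k, v in (extra or {}).items():
        fields.append(f"{k}={v}")
    out = [str(len(crystal)), " ".join(fields)]
    for s, p in zip(crystal.species, crystal.cart_coords):
        out.append(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    return "\n".join(out) + "\n"


def read_extxyz(text: str) -> CrystalStructure:
    lines = text.strip().splitlines()
    n = int(lines[0])
    header = lines[1]
    key = 'Lattice="'
    start = header.index(key) + len(key)
    end = header.index('"', start)
    nums = [float(x) for x in header[start:end].split()]
    lattice = Lattice(np.array(nums).reshape(3, 3))
    symbols, cart = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        cart.append([float(x) for x in parts[1:4]])
    frac = cart_to_frac(lattice, np.array(cart))
    return CrystalStructure(lattice, symbols, frac)
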