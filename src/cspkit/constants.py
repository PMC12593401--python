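"""Physical constants and the packaged element table.

Internal units throughout the package: Å (length), eV (energy), amu (mass),
K (temperature), e (charge).  Relative lattice energies are reported in
kJ/mol per molecule via ``EV_TO_KJMOL``.
"""

from __future__ import annotations

from dataclasses import dataclass

K_B = 8.617333262e-5  # eV/K
HBAR = 6.582119569e-16  # eV·s
EV_TO_KJMOL = 96.48533  # 1 eV = 96.48533 kJ/mol

# sqrt(eV / (amu·Å²)) -> rad/s; from 1 eV = 1.602176634e-19 J,
# 1 amu = 1.66053906660e-27 kg, 1 Å = 1e-10 m.
_EV = 1.602176634e-19
_AMU = 1.66053906660e-27
OMEGA_SI = (_EV / (_AMU * 1e-20)) ** 0.5  # 9.8227e13 rad/s per sqrt(eV/amu/Å²)

# Coulomb constant e²/(4πε₀) in eV·Å
COULOMB_EV_A = 14.399645351950543

AVOGADRO = 6.02214076e23
AMU_G = 1.66053906660e-24  # grams


@dataclass(frozen=True)
class ElementSpec:
    """Chemical element with the radii and mass the toolkit needs.

    ``vdw_radius`` enters the intermolecular close-contact criterion
    d > s_r·(r_A + r_B); ``covalent_radius`` drives bond perception.
    """

    symbol: str
    mass: float  # amu
    vdw_radius: float  # Å
    covalent_radius: float  # Å

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.vdw_radius <= 0 or self.covalent_radius <= 0:
            raise ValueError(f"non-positive parameters for element {self.symbol}")


# Bondi/Alvarez-style vdW radii, Cordero covalent radii, IUPAC masses.
_ELEMENT_ROWS = [
    # symbol, mass, vdw, covalent
    ("H", 1.008, 1.10, 0.31),
    ("He", 4.0026, 1.40, 0.28),
    ("Li", 6.94, 1.81, 1.28),
    ("B", 10.81, 1.92, 0.84),
    ("C", 12.011, 1.70, 0.76),
    ("N", 14.007, 1.55, 0.71),
    ("O", 15.999, 1.52, 0.66),
    ("F", 18.998, 1.47, 0.57),
    ("Ne", 20.180, 1.54, 0.58),
    ("Na", 22.990, 2.27, 1.66),
    ("Mg", 24.305, 1.73, 1.41),
    ("Si", 28.085, 2.10, 1.11),
    ("P", 30.974, 1.80, 1.07),
    ("S", 32.06, 1.80, 1.05),
    ("Cl", 35.45, 1.75, 1.02),
    ("Ar", 39.948, 1.88, 1.06),
    ("K", 39.098, 2.75, 2.03),
    ("Ca", 40.078, 2.31, 1.76),
    ("Br", 79.904, 1.85, 1.20),
    ("Kr", 83.798, 2.02, 1.16),
    ("I", 126.904, 1.98, 1.39),
    ("Xe", 131.293, 2.16, 1.40),
]

ELEMENTS: dict[str, ElementSpec] = {
    sym: ElementSpec(sym, m, rv, rc) for sym, m, rv, rc in _ELEMENT_ROWS
}


def get_element(symbol: str) -> ElementSpec:
    """Look up an element; raises ``KeyError`` with a clear message."""
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None
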