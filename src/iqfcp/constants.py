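"""Physical constants, unit conversions and per-element default tables.

Internal units are atomic units throughout (bohr, hartree, electron charge);
geometry I/O is in angstrom and reported energies also carry kcal/mol.
"""

from __future__ import annotations

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
HARTREE_TO_KCALMOL = 627.509474

#: Nuclear charge by element symbol (subset sufficient for organic/biomolecular toys).
ATOMIC_NUMBER = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "Ar": 18,
}

SYMBOL_OF_Z = {z: s for s, z in ATOMIC_NUMBER.items()}

#: Default promolecular Gaussian exponents (bohr^-2), one s primitive per atom.
#: Only qualitative realism is intended: heavier atoms are more compact.
DEFAULT_EXPONENTS = {
    "H": 1.2, "He": 1.6,
    "Li": 1.0, "Be": 1.4, "B": 1.8, "C": 2.0, "N": 2.2, "O": 2.6, "F": 2.8, "Ne": 3.0,
    "Na": 1.2, "Mg": 1.4, "P": 1.8, "S": 2.0, "Cl": 2.2, "Ar": 2.4,
}

#: Bondi van der Waals radii (angstrom), used for ESP fitting shells.
VDW_RADII_ANGSTROM = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
}
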