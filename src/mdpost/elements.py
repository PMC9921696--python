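"""Bundled element table: atomic masses (kg) and default charge numbers.

Replaces any network lookup.  Masses are IUPAC 2021 standard atomic
weights converted from g/mol.  Default charge numbers are the common
monatomic-ion oxidation states for elements that form simple ions in
the melts and electrolytes this package targets; everything else
defaults to 0.  User-supplied values always override.
"""

from __future__ import annotations

from .units import AVOGADRO

_AMU = 1e-3 / AVOGADRO  # g/mol -> kg

_MASSES_GMOL = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "Br": 79.904, "Kr": 83.798, "Rb": 85.468,
    "Sr": 87.62, "Ag": 107.87, "I": 126.90, "Xe": 131.29, "Cs": 132.91,
    "Ba": 137.33, "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Pb": 207.2,
}

_DEFAULT_CHARGE = {
    "H": 1, "Li": 1, "Na": 1, "K": 1, "Rb": 1, "Cs": 1, "Ag": 1,
    "Mg": 2, "Ca": 2, "Sr": 2, "Ba": 2, "Zn": 2,
    "F": -1, "Cl": -1, "Br": -1, "I": -1, "O": -2, "S": -2,
}


def element_mass(symbol: str) -> float:
    """Mass of an element in kg; raises KeyError for unknown symbols."""
    return _MASSES_GMOL[symbol] * _AMU


def default_charge_number(symbol: str) -> int:
    """Common monatomic-ion charge number, 0 if the element has none."""
    return _DEFAULT_CHARGE.get(symbol, 0)


def is_known_element(symbol: str) -> bool:
    return symbol in _MASSES_GMOL
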