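"""Monoisotopic mass arithmetic for picolinyl-derivatized sterols.

Sterol hydroxyls are esterified with picolinic acid (PA, C6H5NO2) before
LC-IM-MS analysis; each ester bond adds a picolinoyl group C6H3NO
(PA minus H2O, +105.0215 Da) to the molecule.  All downstream m/z keys in
the library are computed from the underivatized monoisotopic mass, the
hydroxyl count and the adduct.
"""

from __future__ import annotations

import re

__all__ = [
    "MONOISOTOPIC",
    "PROTON",
    "ELECTRON",
    "SODIUM_CATION",
    "WATER",
    "PICOLINOYL",
    "PICOLINIC_ACID",
    "ADDUCT_SHIFTS",
    "UnknownAdductError",
    "NotDerivatizableError",
    "parse_formula",
    "formula_mass",
    "derivatized_mass",
    "derivatized_mz",
    "primary_adduct",
]

# CODATA/IUPAC monoisotopic masses (Da)
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825,
    "D": 2.014102,
    "N": 14.003074,
    "O": 15.994915,
    "Na": 22.989769,
    "S": 31.972071,
    "P": 30.973762,
    "K": 38.963706,
    "Cl": 34.968853,
    "F": 18.998403,
}

PROTON = 1.007276  # H minus one electron
ELECTRON = 0.000549
SODIUM_CATION = MONOISOTOPIC["Na"] - ELECTRON  # +22.989220
WATER = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownAdductError(ValueError):
    """Adduct kind is not one of the supported positive-mode sterol adducts."""


class NotDerivatizableError(ValueError):
    """Compound cannot be picolinyl-derivatized (hydroxyl count outside 1..5)."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-order elemental formula such as ``C27H46O`` into counts.

    Raises ``ValueError`` on unknown elements or malformed input.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass (Da) of a formula string or element-count dict."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC[el] * n for el, n in counts.items())


#: Mass added per esterified hydroxyl: picolinic acid minus water (C6H3NO).
PICOLINOYL = formula_mass("C6H3NO")  # 105.021464

#: Neutral picolinic acid C6H5NO2; the characteristic neutral loss in MS/MS.
PICOLINIC_ACID = formula_mass("C6H5NO2")  # 123.032028

#: Positive-mode adduct mass shifts applied to the (derivatized) neutral mass.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": PROTON,
    "[M+Na]+": SODIUM_CATION,
    "[M+H-H2O]+": PROTON - WATER,
    "[M+H-2H2O]+": PROTON - 2 * WATER,
}


def derivatized_mass(monoisotopic_mass: float, n_hydroxyl: int) -> float:
    """Neutral monoisotopic mass after picolinyl derivatization of every
    hydroxyl (one C6H3NO added per OH)."""
    if not 1 <= int(n_hydroxyl) <= 5:
        raise NotDerivatizableError(
            f"hydroxyl count {n_hydroxyl} outside the derivatizable range 1..5"
        )
    if monoisotopic_mass <= 0:
        raise ValueError(f"non-positive monoisotopic mass {monoisotopic_mass}")
    return monoisotopic_mass + int(n_hydroxyl) * PICOLINOYL


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged positive adduct of ``neutral_mass``."""
    try:
        shift = ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise UnknownAdductError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        ) from None
    return neutral_mass + shift


def derivatized_mz(compound, adduct: str) -> float:
    """Precursor m/z of the fully picolinyl-derivatized compound under the
    given adduct.

    ``compound`` needs ``monoisotopic_mass`` and ``n_hydroxyl`` attributes
    (any object, typically a :class:`sterol4d.library.SterolCompound`).
    """
    neutral = derivatized_mass(compound.monoisotopic_mass, compound.n_hydroxyl)
    return adduct_mz(neutral, adduct)


def primary_adduct(n_hydroxyl: int) -> str:
    """Default precursor adduct by hydroxyl class: protonated for
    monohydroxysterols, sodiated for di- and polyhydroxysterols."""
    return "[M+H]+" if int(n_hydroxyl) == 1 else "[M+Na]+"
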