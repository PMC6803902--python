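"""Unit conversions between mass and molar concentration scales.

All internal computation in this package uses mol/L for concentrations and
mL for volumes; mg/L (analytes) and g/L (cyclodextrin doses) are accepted at
the boundary and converted here.  Molar masses can be supplied directly or
computed from a molecular formula (D is recognised for deuterium, so labelled
isotopologues such as d3-guaiacol = C7H5D3O2 get the correct mass shift).
"""

from __future__ import annotations

import re

__all__ = [
    "molar_mass_from_formula",
    "mass_conc_to_molar",
    "molar_conc_to_mass",
]

# Standard atomic weights (g/mol), CIAAW conventional values.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "D": 2.014,  # deuterium, for isotopically labelled standards
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass in g/mol of a simple molecular formula like ``C7H8O2``.

    Only the elements in :data:`ATOMIC_MASS` are supported, which covers the
    volatile phenols, their deuterated isotopologues, and the cyclodextrins.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError("formula must be a non-empty string")
    pos = 0
    total = 0.0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += ATOMIC_MASS[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return total


def mass_conc_to_molar(value_mg_per_l: float, molar_mass: float) -> float:
    """Convert mg/L to mol/L given a molar mass in g/mol."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return value_mg_per_l / (1000.0 * molar_mass)


def molar_conc_to_mass(value_mol_per_l: float, molar_mass: float) -> float:
    """Convert mol/L back to mg/L; inverse of :func:`mass_conc_to_molar`."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return value_mol_per_l * 1000.0 * molar_mass
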