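"""Dose-unit bookkeeping: formula masses and molar-to-mass conversion.

Potency ratios are formed on a mass basis, so molar doses from the source
literature (nmol per application, mmol/kg) are converted using the
compound's molecular weight. Conversion is exact unit bookkeeping:
nmol x g/mol -> ng -> mg.
"""

from __future__ import annotations

import re

from pefkit.types import Compound, DoseGroup, DoseUnit

# Standard atomic masses, 4-5 significant digits — adequate for the
# elements occurring in (alkylated) PAHs and common derivatives.
ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
    "Br": 79.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Molecular weight (g/mol) from a simple molecular formula.

    >>> round(formula_mass("C20H12"), 3)   # benzo[a]pyrene
    252.316
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"cannot parse molecular formula: {formula!r}")
    total = 0.0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        total += ATOMIC_MASS[element] * (int(count) if count else 1)
    return total


def convert_dose_to_mass(
    dose: float, unit: DoseUnit, compound: Compound | None = None
) -> tuple[float, DoseUnit]:
    """Convert a dose to its mass basis (mg, or mg/kg for per-body-mass units).

    Mass units pass through unchanged (ug is rescaled to mg); molar units
    multiply by the compound's molecular weight. The conversion is linear
    and invertible.

    Returns ``(value, unit)`` with unit one of MG or MG_PER_KG.
    """
    unit = DoseUnit(unit)
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if unit is DoseUnit.MG:
        return dose, DoseUnit.MG
    if unit is DoseUnit.MG_PER_KG:
        return dose, DoseUnit.MG_PER_KG
    if unit is DoseUnit.UG:
        return dose / 1000.0, DoseUnit.MG
    # molar units need a molecular weight
    if compound is None or compound.molecular_weight is None:
        raise ValueError(
            f"molar unit {unit.value} requires a compound with molecular_weight"
        )
    mw = compound.molecular_weight
    if unit is DoseUnit.NMOL:
        # nmol * g/mol = ng; ng / 1e6 = mg
        return dose * mw / 1e6, DoseUnit.MG
    if unit is DoseUnit.MMOL_PER_KG:
        # mmol/kg * g/mol = mg/kg
        return dose * mw, DoseUnit.MG_PER_KG
    raise ValueError(f"unsupported unit: {unit}")  # pragma: no cover


def group_to_mass(group: DoseGroup, compound: Compound | None = None) -> DoseGroup:
    """Return a copy of ``group`` with its dose normalized to the mass basis."""
    value, unit = convert_dose_to_mass(group.dose, group.dose_unit, compound)
    return group.model_copy(update={"dose": value, "dose_unit": unit})
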