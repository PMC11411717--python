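"""Exact-mass arithmetic for electrospray adduct and transformation chemistry.

Small molecules detected by LC-HRMS appear as protonated ``[M+H]+`` (ESI+)
or deprotonated ``[M-H]-`` (ESI-) ions, so observed m/z and neutral
monoisotopic mass differ by one proton mass. Everything downstream —
cross-mode deduplication, suspect screening by transformation shifts —
reduces to sums of monoisotopic atomic masses at sub-mDa precision.
"""

from __future__ import annotations

import re

#: Mass of a proton in Da; the [M+H]+ / [M-H]- offset, electron mass folded in.
PROTON_MASS = 1.007276

#: Monoisotopic atomic masses (Da) for the elements that occur in the
#: compound classes handled here.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "Cl": 34.9688527,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C14H11Cl2NO2`` into element counts.

    Only flat formulas over C/H/N/O/S/Cl are supported; parentheses,
    isotopes and charges are not.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of a molecular formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def mz_from_neutral(neutral_mass: float, mode: str) -> float:
    """Expected m/z of the (de)protonated ion of a neutral molecule."""
    if mode == "ESI+":
        return neutral_mass + PROTON_MASS
    if mode == "ESI-":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unknown ionization mode {mode!r}")


def neutral_from_mz(mz: float, mode: str) -> float:
    """Neutral monoisotopic mass implied by an observed m/z, adjusting for
    (de)protonation."""
    if mode == "ESI+":
        if mz <= PROTON_MASS:
            raise ValueError("ESI+ m/z must exceed the proton mass")
        return mz - PROTON_MASS
    if mode == "ESI-":
        return mz + PROTON_MASS
    raise ValueError(f"unknown ionization mode {mode!r}")
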