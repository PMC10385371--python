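"""Per-element constants: masses, radii, atomic numbers.

Masses and atomic numbers are taken from rdkit's periodic table
(CODATA/NIST-derived).  Van der Waals radii follow Bondi's classic
compilation and covalent radii Pyykkö's single-bond set for the elements
that occur in organic/bio-organic structures; anything outside those
tables falls back to rdkit's values and, as a last resort, to 2.0 Å with
a warning.
"""

from __future__ import annotations

import warnings

from rdkit import Chem

_PT = Chem.GetPeriodicTable()

# Bondi (1964) van der Waals radii, Å.
BONDI_VDW = {
    "H": 1.20, "He": 1.40,
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Br": 1.85, "I": 1.98,
    "Na": 2.27, "K": 2.75, "Mg": 1.73, "Zn": 1.39,
}

# Pyykkö single-bond covalent radii (2009), Å.
PYYKKO_COVALENT = {
    "H": 0.32, "B": 0.85, "C": 0.75, "N": 0.71, "O": 0.63, "F": 0.64,
    "Si": 1.16, "P": 1.11, "S": 1.03, "Cl": 0.99,
    "Br": 1.14, "I": 1.33, "Se": 1.16,
    "Na": 1.55, "K": 1.96, "Mg": 1.39, "Ca": 1.71, "Zn": 1.18, "Fe": 1.16,
}

DEFAULT_VDW_RADIUS = 2.0


def normalize_symbol(symbol: str) -> str:
    """Canonical element symbol (\"CL\" -> \"Cl\")."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def atomic_number(symbol: str) -> int:
    symbol = normalize_symbol(symbol)
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
    if z <= 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return z


def is_element(symbol: str) -> bool:
    try:
        atomic_number(symbol)
        return True
    except ValueError:
        return False


def atomic_mass(symbol: str, kind: str = "average") -> float:
    """Mass in amu: ``average`` standard atomic weight or ``monoisotopic``
    most-abundant-isotope mass."""
    symbol = normalize_symbol(symbol)
    atomic_number(symbol)  # raises for unknown symbols
    if kind == "average":
        return float(_PT.GetAtomicWeight(symbol))
    if kind == "monoisotopic":
        return float(_PT.GetMostCommonIsotopeMass(symbol))
    raise ValueError(f"unknown mass kind: {kind!r}")


def vdw_radius(symbol: str) -> float:
    """Bondi van der Waals radius, Å; rdkit fallback, then 2.0 Å."""
    symbol = normalize_symbol(symbol)
    if symbol in BONDI_VDW:
        return BONDI_VDW[symbol]
    if is_element(symbol):
        r = float(_PT.GetRvdw(symbol))
        if r > 0:
            return r
    warnings.warn(
        f"no van der Waals radius for {symbol!r}; using "
        f"{DEFAULT_VDW_RADIUS} Å fallback"
    )
    return DEFAULT_VDW_RADIUS


def covalent_radius(symbol: str) -> float:
    """Pyykkö single-bond covalent radius, Å (rdkit fallback)."""
    symbol = normalize_symbol(symbol)
    if symbol in PYYKKO_COVALENT:
        return PYYKKO_COVALENT[symbol]
    if is_element(symbol):
        r = float(_PT.GetRcovalent(symbol))
        if r > 0:
            return r
    raise ValueError(f"no covalent radius available for {symbol!r}")
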