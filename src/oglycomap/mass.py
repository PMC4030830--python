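"""Mass computation for PA-glycan compositions.

Three mass flavors are exposed:

* **monoisotopic** — sum of monoisotopic residue masses + water + PA increment;
* **average** — chemical average masses, for comparison with averaged
  multi-adduct MALDI readouts;
* **nominal** — integer residue masses (Hex 162, HexNAc 203, dHex 146,
  Neu5Ac 291, SO3 80, water 18, PA 78). ``nominal_mh`` (nominal + 1 for the
  proton) is the convention that reproduces the integer "molecular mass"
  columns of published PA-O-glycan GU maps, and is what identification
  validates against.
"""

from __future__ import annotations

import math

from .structures import Composition, GlycanError

__all__ = [
    "MONOISOTOPIC",
    "AVERAGE",
    "NOMINAL",
    "PROTON_MASS",
    "monoisotopic_mass",
    "average_mass",
    "nominal_mass",
    "nominal_mh",
    "adduct_mz",
    "round_half_away",
]

#: Residue (dehydrated) monoisotopic masses, Da.
MONOISOTOPIC = {
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "dHex": 146.0579,
    "Neu5Ac": 291.0954,
    "SO3": 79.9568,
    "H2O": 18.0106,
    "PA": 78.0582,  # 2-aminopyridine, reductive amination: +C5H6N2 +2H -O
}

#: Chemical average masses, Da.
AVERAGE = {
    "Hex": 162.141,
    "HexNAc": 203.195,
    "dHex": 146.143,
    "Neu5Ac": 291.255,
    "SO3": 80.063,
    "H2O": 18.015,
    "PA": 78.118,
}

#: Integer nominal masses, Da.
NOMINAL = {
    "Hex": 162,
    "HexNAc": 203,
    "dHex": 146,
    "Neu5Ac": 291,
    "SO3": 80,
    "H2O": 18,
    "PA": 78,
}

PROTON_MASS = 1.00728
_SODIUM_MASS = 22.9892

#: (continuous shift, nominal shift) per supported adduct.
_ADDUCTS = {
    "H": (PROTON_MASS, 1),
    "Na": (_SODIUM_MASS, 23),
    "deprotonated": (-PROTON_MASS, -1),
}


def round_half_away(x: float) -> int:
    """Round half away from zero (5 always rounds up in magnitude)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _sum(composition: Composition, table: dict) -> float:
    if composition.total_residues < 1:
        raise GlycanError("composition contains no residues")
    return (
        composition.hex * table["Hex"]
        + composition.hexnac * table["HexNAc"]
        + composition.dhex * table["dHex"]
        + composition.neu5ac * table["Neu5Ac"]
        + composition.so3 * table["SO3"]
        + table["H2O"]
        + (table["PA"] if composition.pa else 0)
    )


def monoisotopic_mass(composition: Composition) -> float:
    """Neutral monoisotopic mass M, Da."""
    return _sum(composition, MONOISOTOPIC)


def average_mass(composition: Composition) -> float:
    """Neutral chemical average mass, Da."""
    return _sum(composition, AVERAGE)


def nominal_mass(composition: Composition) -> int:
    """Neutral nominal (integer) mass, Da."""
    return int(_sum(composition, NOMINAL))


def nominal_mh(composition: Composition, adduct: str = "H") -> int:
    """Integer nominal m/z of the singly charged ion for the given adduct.

    ``nominal_mh(c, "H")`` reproduces the printed integer masses of the
    bundled reference map exactly.
    """
    if adduct not in _ADDUCTS:
        raise GlycanError(f"unknown adduct {adduct!r}; choose from {sorted(_ADDUCTS)}")
    return nominal_mass(composition) + _ADDUCTS[adduct][1]


def adduct_mz(composition: Composition, adduct: str = "H") -> float:
    """Continuous monoisotopic m/z of the singly charged ion."""
    if adduct not in _ADDUCTS:
        raise GlycanError(f"unknown adduct {adduct!r}; choose from {sorted(_ADDUCTS)}")
    return monoisotopic_mass(composition) + _ADDUCTS[adduct][0]
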