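"""The bundled two-dimensional GU reference map of PA-O-glycans.

Each entry records a structure's glucose-unit coordinates on the amide
(size-fractionation) and C30 (extended reversed-phase) columns plus its
printed nominal mass and source. Anionic charge class (Neu5Ac + sulfate
count) emulates the Mono-Q anion-exchange pre-fractionation, which has no
GU axis and is modeled as a categorical gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional

import pandas as pd

from .grammar import parse_structure
from .mass import nominal_mh
from .structures import Composition, GlycanStructure, composition_of

__all__ = [
    "MapEntry",
    "MapError",
    "load_map",
    "bundled_map_path",
    "filter_by_charge",
    "find_entry",
]

_REQUIRED_COLUMNS = ["structure", "gu_amide", "gu_c30", "mass_printed", "source"]


class MapError(ValueError):
    """Reference map fails validation."""


@dataclass(frozen=True)
class MapEntry:
    """One reference glycan with its HPLC coordinates and printed mass."""

    structure: GlycanStructure
    gu_amide: float
    gu_c30: float
    mass_printed: int
    source: str

    @property
    def structure_text(self) -> str:
        return self.structure.canonical()

    @property
    def composition(self) -> Composition:
        return composition_of(self.structure)

    @property
    def charge_class(self) -> int:
        return self.composition.charge_class

    @property
    def category(self) -> str:
        c = self.composition
        if c.so3 > 0:
            return "sulfated"
        if c.neu5ac > 0:
            return "sialylated"
        return "neutral"


def bundled_map_path() -> Path:
    return Path(resources.files("oglycomap").joinpath("data/reference_map.tsv"))


def load_map(path=None, mass_tolerance: int = 1) -> List[MapEntry]:
    """Load and validate a reference map TSV.

    Every row is parsed, checked for duplicate canonical structures, and its
    recomputed nominal [M+H]+ compared with the printed mass column within
    ``mass_tolerance`` Da.
    """
    path = bundled_map_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise MapError(f"map file {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise MapError(f"map file {path} contains no entries")
    entries: List[MapEntry] = []
    seen = {}
    for idx, row in df.iterrows():
        text = str(row["structure"])
        try:
            structure = parse_structure(text)
        except Exception as exc:
            raise MapError(f"row {idx + 1} ({text!r}): {exc}") from exc
        canonical = structure.canonical()
        if canonical in seen:
            raise MapError(
                f"row {idx + 1} duplicates row {seen[canonical]} ({canonical})"
            )
        seen[canonical] = idx + 1
        entry = MapEntry(
            structure=structure,
            gu_amide=float(row["gu_amide"]),
            gu_c30=float(row["gu_c30"]),
            mass_printed=int(row["mass_printed"]),
            source=str(row["source"]),
        )
        computed = nominal_mh(entry.composition, "H")
        if abs(computed - entry.mass_printed) > mass_tolerance:
            raise MapError(
                f"row {idx + 1} ({text!r}): computed [M+H]+ {computed} "
                f"differs from printed {entry.mass_printed} by more than "
                f"{mass_tolerance} Da"
            )
        entries.append(entry)
    return entries


def filter_by_charge(entries: List[MapEntry], charge: int) -> List[MapEntry]:
    """Subset of entries in one Mono-Q charge class."""
    return [e for e in entries if e.charge_class == charge]


def find_entry(entries: List[MapEntry], structure) -> Optional[MapEntry]:
    """Look an entry up by structure (string or parsed), by canonical form."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    canonical = structure.canonical()
    for e in entries:
        if e.structure_text == canonical:
            return e
    return None
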