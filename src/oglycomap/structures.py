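"""Core data model for PA-labeled O-glycan structures.

An O-glycan is represented as a rooted tree of monosaccharide residues.
The root is the reducing-end residue (GalNAc for mucin-type O-glycans,
or the lone residue for free monosaccharides), optionally derivatized
with 2-aminopyridine (PA) for fluorescence detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple

__all__ = [
    "MONOSACCHARIDE_CLASS",
    "Residue",
    "GlycanStructure",
    "Composition",
    "composition_of",
    "GlycanError",
]


class GlycanError(ValueError):
    """Invalid glycan structure or notation."""


#: Residue vocabulary -> mass class (Hex, HexNAc, dHex, Neu5Ac).
MONOSACCHARIDE_CLASS = {
    "Gal": "Hex",
    "Glc": "Hex",
    "Man": "Hex",
    "Fuc": "dHex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Neu5Ac": "Neu5Ac",
}

#: Anomeric carbon each residue links from (Neu5Ac is a ketose: C2).
ANOMERIC_POSITION = {name: ("2" if name == "Neu5Ac" else "1") for name in MONOSACCHARIDE_CLASS}


@dataclass
class Residue:
    """One monosaccharide in the tree.

    ``linkage`` is ``(child_pos, parent_pos)`` — the anomeric position of this
    residue and the ring position of the parent it is attached to — or ``None``
    for the root. ``'?'`` marks an unknown position; ``anomer`` is ``'a'``,
    ``'b'`` or ``'?'``.
    """

    name: str
    anomer: str = "?"
    linkage: Optional[Tuple[str, str]] = None
    sulfates: Tuple[int, ...] = ()
    children: list["Residue"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in MONOSACCHARIDE_CLASS:
            raise GlycanError(f"unknown monosaccharide name: {self.name!r}")
        if self.anomer not in ("a", "b", "?"):
            raise GlycanError(f"invalid anomeric configuration: {self.anomer!r}")
        if self.linkage is not None:
            child_pos, parent_pos = self.linkage
            expected = ANOMERIC_POSITION[self.name]
            if child_pos not in ("?", expected):
                raise GlycanError(
                    f"{self.name} must link from position {expected}, got {child_pos}"
                )
        self.sulfates = tuple(sorted(set(self.sulfates)))
        for pos in self.sulfates:
            if not 1 <= pos <= 6:
                raise GlycanError(f"sulfate position {pos} outside ring positions 1-6")

    @property
    def parent_pos(self) -> Optional[str]:
        return None if self.linkage is None else self.linkage[1]

    def is_terminal(self) -> bool:
        return not self.children

    def occupied_positions(self) -> set:
        """Ring positions engaged by glycosidic bonds to children."""
        return {c.parent_pos for c in self.children if c.parent_pos != "?"}

    def add_child(self, child: "Residue") -> None:
        if child.linkage is None:
            raise GlycanError("non-root residue requires a linkage")
        pos = child.parent_pos
        if pos != "?" and pos in self.occupied_positions():
            raise GlycanError(
                f"position {pos} of {self.name} already carries a substituent"
            )
        if pos != "?" and int(pos) in self.sulfates:
            raise GlycanError(f"position {pos} of {self.name} is sulfated")
        self.children.append(child)

    def validate(self) -> None:
        occupied = self.occupied_positions()
        seen = set()
        for c in self.children:
            if c.parent_pos != "?":
                if c.parent_pos in seen:
                    raise GlycanError(
                        f"two residues attached at position {c.parent_pos} of {self.name}"
                    )
                seen.add(c.parent_pos)
        for pos in self.sulfates:
            if str(pos) in occupied:
                raise GlycanError(
                    f"sulfate at position {pos} of {self.name} clashes with a glycosidic bond"
                )
        for c in self.children:
            c.validate()

    def copy(self) -> "Residue":
        return Residue(
            name=self.name,
            anomer=self.anomer,
            linkage=self.linkage,
            sulfates=self.sulfates,
            children=[c.copy() for c in self.children],
        )

    def walk(self) -> Iterator["Residue"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class GlycanStructure:
    """Rooted residue tree plus the PA (2-aminopyridine) reducing-end tag."""

    root: Residue
    pa: bool = True

    def __post_init__(self) -> None:
        if self.root.linkage is not None:
            raise GlycanError("root residue must not carry a linkage")
        self.root.validate()

    def residues(self) -> Iterator[Residue]:
        return self.root.walk()

    @property
    def size(self) -> int:
        return sum(1 for _ in self.residues())

    def copy(self) -> "GlycanStructure":
        return GlycanStructure(root=self.root.copy(), pa=self.pa)

    def canonical(self) -> str:
        from .grammar import serialize_structure

        return serialize_structure(self)

    def __str__(self) -> str:
        return self.canonical()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


@dataclass(frozen=True)
class Composition:
    """Monosaccharide-class counts — the mass-bearing abstraction.

    ``(Hex)1(HexNAc)2-PA`` is ``Composition(hex=1, hexnac=2, pa=True)``.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neu5ac: int = 0
    so3: int = 0
    pa: bool = True

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neu5ac", "so3"):
            if getattr(self, name) < 0:
                raise GlycanError(f"negative count for {name}")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neu5ac

    @property
    def charge_class(self) -> int:
        """Anionic charge equivalents (Neu5Ac + sulfate) used for Mono-Q gating."""
        return self.neu5ac + self.so3

    def __sub__(self, other: "Composition") -> "Composition":
        return Composition(
            hex=self.hex - other.hex,
            hexnac=self.hexnac - other.hexnac,
            dhex=self.dhex - other.dhex,
            neu5ac=self.neu5ac - other.neu5ac,
            so3=self.so3 - other.so3,
            pa=self.pa,
        )

    def contains(self, other: "Composition") -> bool:
        return (
            self.hex >= other.hex
            and self.hexnac >= other.hexnac
            and self.dhex >= other.dhex
            and self.neu5ac >= other.neu5ac
            and self.so3 >= other.so3
        )

    def without_pa(self) -> "Composition":
        return replace(self, pa=False)

    def label(self) -> str:
        parts = []
        for count, tag in (
            (self.hex, "Hex"),
            (self.hexnac, "HexNAc"),
            (self.dhex, "dHex"),
            (self.neu5ac, "Neu5Ac"),
            (self.so3, "SO3"),
        ):
            if count:
                parts.append(f"({tag}){count}")
        if self.pa:
            parts.append("-PA")
        return "".join(parts) or "(empty)"


def composition_of(glycan: GlycanStructure) -> Composition:
    """Collapse a structure to monosaccharide-class counts plus sulfates."""
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "Neu5Ac": 0}
    so3 = 0
    for r in glycan.residues():
        counts[MONOSACCHARIDE_CLASS[r.name]] += 1
        so3 += len(r.sulfates)
    return Composition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        dhex=counts["dHex"],
        neu5ac=counts["Neu5Ac"],
        so3=so3,
        pa=glycan.pa,
    )
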