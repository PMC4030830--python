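"""Glycosidic-fragment prediction for PA-glycans and branching evidence.

Collision-induced dissociation of a protonated PA-glycan is dominated by
single glycosidic-bond cleavages: Y ions retain the reducing end (and hence
the PA tag), B ions are the released non-reducing piece. The pattern of
PA-retaining single-cleavage compositions discriminates a branched core
(two different one-residue losses, or two cleavages giving the same
composition) from a linear chain (a strict inclusion ladder of suffixes).
Cross-ring (A/X) fragments and intensity modeling are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .mass import NOMINAL, nominal_mass, nominal_mh
from .structures import Composition, GlycanStructure, MONOSACCHARIDE_CLASS, composition_of

__all__ = ["Fragment", "FragmentSet", "fragment_compositions", "is_branched_evidence"]


@dataclass(frozen=True)
class Fragment:
    composition: Composition
    pa_retaining: bool
    mz_nominal: int
    ion_type: str  # 'Y' or 'B'


@dataclass(frozen=True)
class FragmentSet:
    precursor: Composition
    precursor_mz: int
    fragments: Tuple[Fragment, ...]

    def pa_fragments(self) -> List[Fragment]:
        return [f for f in self.fragments if f.pa_retaining]


def _subtree_counts(residue) -> Composition:
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "Neu5Ac": 0}
    so3 = 0
    for r in residue.walk():
        counts[MONOSACCHARIDE_CLASS[r.name]] += 1
        so3 += len(r.sulfates)
    return Composition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        dhex=counts["dHex"],
        neu5ac=counts["Neu5Ac"],
        so3=so3,
        pa=False,
    )


def fragment_compositions(glycan: GlycanStructure) -> FragmentSet:
    """All single-glycosidic-cleavage B/Y fragment compositions.

    Each non-root residue defines one cleavable bond; cutting it yields a
    B piece (that residue's subtree, no PA, no water — nominal m/z is the
    residue sum plus the proton) and a Y piece (the remainder with the PA
    tag — nominal m/z is its [M+H]+). A single residue has no bonds and
    yields an empty set.
    """
    precursor = composition_of(glycan)
    precursor_mz = nominal_mh(precursor, "H")
    fragments: List[Fragment] = []
    for residue in glycan.root.walk():
        if residue.linkage is None:
            continue
        b_piece = _subtree_counts(residue)
        y_piece = Composition(
            hex=precursor.hex - b_piece.hex,
            hexnac=precursor.hexnac - b_piece.hexnac,
            dhex=precursor.dhex - b_piece.dhex,
            neu5ac=precursor.neu5ac - b_piece.neu5ac,
            so3=precursor.so3 - b_piece.so3,
            pa=glycan.pa,
        )
        b_mz = nominal_mass(b_piece) - NOMINAL["H2O"] + 1
        y_mz = nominal_mh(y_piece, "H")
        fragments.append(Fragment(b_piece, False, b_mz, "B"))
        fragments.append(Fragment(y_piece, True, y_mz, "Y"))
    return FragmentSet(
        precursor=precursor, precursor_mz=precursor_mz, fragments=tuple(fragments)
    )


def is_branched_evidence(fragset: FragmentSet) -> str:
    """Classify the precursor topology from PA-retaining fragments.

    Returns ``"branched"``, ``"linear"`` or ``"indeterminate"``.

    * branched — two different cleavages give the same PA-retaining
      composition (symmetric arms), or two distinct compositions share the
      same residue count (two different single-subtree losses of equal size);
    * linear — the distinct compositions form the complete strict inclusion
      ladder of suffixes (sizes n-1 down to 1);
    * indeterminate — anything else, including precursors smaller than a
      trisaccharide.
    """
    y_keys = [
        (f.composition.hex, f.composition.hexnac, f.composition.dhex,
         f.composition.neu5ac, f.composition.so3)
        for f in fragset.pa_fragments()
    ]
    n = fragset.precursor.total_residues
    if not y_keys or n < 3:
        return "indeterminate"
    if len(set(y_keys)) < len(y_keys):
        return "branched"
    sizes = [sum(k[:4]) for k in y_keys]
    if len(set(sizes)) < len(sizes):
        return "branched"
    order = sorted(range(len(y_keys)), key=lambda i: -sizes[i])
    expected_sizes = list(range(n - 1, 0, -1))
    if [sizes[i] for i in order] == expected_sizes:
        chain = [y_keys[i] for i in order]
        nested = all(
            all(a >= b for a, b in zip(chain[i], chain[i + 1]))
            for i in range(len(chain) - 1)
        )
        if nested:
            return "linear"
    return "indeterminate"
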