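"""In-silico enzymatic derivatization of PA-glycans.

Three families of operations are modeled, the same toolbox used to build and
confirm entries of the reference map:

* **exoglycosidases** — remove terminal residues matching a name, anomeric
  configuration and (optionally) linkage. Sulfated residues resist removal,
  and the PA-tagged reducing-end residue is never removed.
* **sialyltransferases** — add Neu5Ac in alpha2-3 or alpha2-6 linkage to a
  named acceptor residue whose target hydroxyl is free.
* **GlcNAc6ST-1 sulfation** — adds sulfate to C6 of a terminal GlcNAc, with
  a deterministic branch preference for the beta1-6-linked arm over the
  beta1-3 arm. Kinetic rate modeling lives in :mod:`oglycomap.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .structures import GlycanError, GlycanStructure, Residue

__all__ = [
    "EnzymeRule",
    "DigestResult",
    "load_enzyme_rules",
    "get_rule",
    "digest",
    "sialylate",
    "sulfate_glcnac6st1",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Exoglycosidase specificity: what terminal residue it releases."""

    name: str
    action: str  # only "remove" rules are tabulated
    targets: Tuple[str, ...]
    anomer: str  # 'a' | 'b' | '?' (wildcard)
    linkage: Optional[Tuple[str, str]]  # None = any linkage
    terminal_only: bool = True

    def matches(self, residue: Residue, is_root: bool) -> bool:
        if is_root:
            return False  # reducing-end residue carries the PA tag
        if residue.name not in self.targets:
            return False
        if self.anomer != "?" and residue.anomer != self.anomer:
            return False
        if self.linkage is not None and residue.linkage != self.linkage:
            return False
        if residue.sulfates:
            return False  # sulfated residues resist exoglycosidases
        return True


@dataclass(frozen=True)
class DigestResult:
    structure: GlycanStructure
    removed: int

    @property
    def cleaved(self) -> bool:
        return self.removed > 0


def bundled_rules_path() -> Path:
    return Path(resources.files("oglycomap").joinpath("data/enzymes.tsv"))


def load_enzyme_rules(path=None) -> Dict[str, EnzymeRule]:
    """Load the exoglycosidase rule table (editable TSV)."""
    path = bundled_rules_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    rules: Dict[str, EnzymeRule] = {}
    for _, row in df.iterrows():
        linkage = None
        if str(row["linkage"]) != "*":
            child, parent = str(row["linkage"]).split("-")
            linkage = (child, parent)
        rules[str(row["name"])] = EnzymeRule(
            name=str(row["name"]),
            action=str(row["action"]),
            targets=tuple(str(row["targets"]).split(",")),
            anomer=str(row["anomer"]),
            linkage=linkage,
            terminal_only=str(row["terminal_only"]).lower() in ("yes", "true", "1"),
        )
    return rules


_RULE_CACHE: Optional[Dict[str, EnzymeRule]] = None


def get_rule(name: str) -> EnzymeRule:
    global _RULE_CACHE
    if _RULE_CACHE is None:
        _RULE_CACHE = load_enzyme_rules()
    try:
        return _RULE_CACHE[name]
    except KeyError:
        raise GlycanError(
            f"unknown enzyme {name!r}; available: {sorted(_RULE_CACHE)}"
        ) from None


def digest(
    glycan: GlycanStructure, rule, exhaustive: bool = False
) -> DigestResult:
    """Apply an exoglycosidase rule; returns the product and cleavage count.

    One round removes every currently-terminal matching residue; exhaustive
    digestion repeats rounds until a fixpoint. A no-op is not an error — the
    result's ``cleaved`` flag is simply False.
    """
    if isinstance(rule, str):
        rule = get_rule(rule)
    if rule.action != "remove":
        raise GlycanError(f"digest requires a remove-action rule, got {rule.action!r}")
    product = glycan.copy()

    def strip(residue: Residue) -> int:
        removed = 0
        keep = []
        for child in residue.children:
            if child.is_terminal() and rule.matches(child, is_root=False):
                removed += 1
            else:
                keep.append(child)
        residue.children = keep
        for child in residue.children:
            removed += strip(child)
        return removed

    total = 0
    while True:
        n = strip(product.root)
        total += n
        if n == 0 or not exhaustive:
            break
    return DigestResult(structure=product if total else glycan, removed=total)


def sialylate(
    glycan: GlycanStructure,
    linkage: str = "2-6",
    acceptor: str = "Gal",
    acceptor_linkage: Optional[str] = None,
) -> GlycanStructure:
    """Add one Neu5Ac in the stated linkage to a named acceptor residue.

    ``linkage`` is ``"2-3"`` or ``"2-6"`` (Neu5Ac always links from C2).
    ``acceptor`` names the residue to decorate; if several residues of that
    name have the target position free, ``acceptor_linkage`` (e.g. ``"1-4"``,
    or ``"root"`` for the reducing end) disambiguates.
    """
    child_pos, parent_pos = linkage.split("-")
    if child_pos != "2":
        raise GlycanError("Neu5Ac links from position 2")
    product = glycan.copy()
    candidates = []
    for residue in product.root.walk():
        if residue.name != acceptor:
            continue
        if acceptor_linkage == "root":
            if residue.linkage is not None:
                continue
        elif acceptor_linkage is not None:
            if residue.linkage is None or "-".join(residue.linkage) != acceptor_linkage:
                continue
        if parent_pos in residue.occupied_positions():
            continue
        if int(parent_pos) in residue.sulfates:
            continue
        candidates.append(residue)
    if not candidates:
        raise GlycanError(
            f"no free {acceptor} acceptor with position {parent_pos} available"
        )
    if len(candidates) > 1:
        raise GlycanError(
            f"{len(candidates)} {acceptor} residues could accept Neu5Ac at "
            f"position {parent_pos}; disambiguate with acceptor_linkage"
        )
    candidates[0].add_child(
        Residue(name="Neu5Ac", anomer="a", linkage=(child_pos, parent_pos))
    )
    return product


def sulfate_glcnac6st1(glycan: GlycanStructure) -> List[GlycanStructure]:
    """Mono-sulfated products of GlcNAc-6-O-sulfotransferase 1.

    Eligible sites are terminal GlcNAc residues whose C6 is free. Products are
    ordered by the enzyme's branch preference: the GlcNAc on the beta1-6 arm
    first, then remaining sites by attachment position ascending.
    """
    sites = []
    for index, residue in enumerate(glycan.root.walk()):
        if residue.name != "GlcNAc" or not residue.is_terminal():
            continue
        if 6 in residue.sulfates or "6" in residue.occupied_positions():
            continue
        parent_pos = residue.parent_pos or ""
        sites.append((parent_pos != "6", parent_pos, index))
    if not sites:
        raise GlycanError("no terminal GlcNAc with a free C6 position")
    sites.sort()
    products = []
    for _, _, index in sites:
        product = glycan.copy()
        target = list(product.root.walk())[index]
        target.sulfates = tuple(sorted(target.sulfates + (6,)))
        products.append(product)
    return products
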