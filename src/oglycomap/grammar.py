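"""Parser and canonical serializer for condensed O-glycan notation.

The accepted grammar covers the condensed nomenclature used in glycomics
tables, e.g. ``Galβ1-3(GlcNAcβ1-6)GalNAc-PA``, plus an ASCII-safe variant
``Gal(b1-3)[GlcNAc(b1-6)]GalNAc-PA``:

* residue names from the fixed vocabulary (Gal, Glc, Man, Fuc, GlcNAc,
  GalNAc, Neu5Ac);
* anomer + linkage written inline (``β1-3`` / ``b1-3``) or parenthesized
  (``(b1-3)``); ``?`` marks unknown anomer/positions; a non-root residue
  written with no linkage at all gets fully unknown linkage;
* branches in parentheses or square brackets immediately before the residue
  they attach to;
* sulfate as a leading ``HSO3-6`` / ``S6-`` prefix (position defaults to 6)
  or a ``[6S]`` modifier after the name;
* optional ``-PA`` suffix for the 2-aminopyridine tag.

Canonical output uses Unicode anomer symbols, ``[6S]`` sulfate modifiers and
parenthesized branches: children of a residue are ordered by attachment
position ascending, the lowest-position child continuing the written chain.
"""

from __future__ import annotations

import re

from .structures import (
    ANOMERIC_POSITION,
    GlycanError,
    GlycanStructure,
    MONOSACCHARIDE_CLASS,
    Residue,
)

__all__ = ["parse_structure", "serialize_structure", "ParseError"]


class ParseError(GlycanError):
    """Syntax error in a structure string; carries the character position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


# Longest names first so GlcNAc wins over Glc.
_NAMES = sorted(MONOSACCHARIDE_CLASS, key=len, reverse=True)
_LINKAGE_RE = re.compile(r"([ab?])([0-9?])-([0-9?])")
_SULF_MOD_RE = re.compile(r"\[([1-6])S\]")
_SULF_PREFIX_RE = re.compile(r"(?:HSO3-([1-6])?|S([1-6])-)")


def _normalize(text: str) -> str:
    text = text.strip().replace(" ", "")
    text = text.replace("β", "b").replace("α", "a")
    # en/em dashes and markdown-mangled subscripts occasionally survive copy-paste
    text = text.replace("–", "-").replace("—", "-")
    text = text.replace("HSO_3_", "HSO3")
    return text


def _matching(s: str, i: int) -> int:
    """Index of the bracket matching ``s[i]`` (one of ``([``)."""
    open_ch = s[i]
    close_ch = ")" if open_ch == "(" else "]"
    depth = 0
    for j in range(i, len(s)):
        if s[j] in "([":
            depth += 1
        elif s[j] in ")]":
            depth -= 1
            if depth == 0:
                if s[j] != close_ch:
                    raise ParseError("mismatched bracket", j)
                return j
    raise ParseError("unbalanced bracket", i)


def _parse_unit(s: str, i: int, offset: int) -> tuple[Residue, int]:
    """Parse one residue (sulfate prefix, name, modifiers, optional linkage)."""
    sulfates: list[int] = []
    m = _SULF_PREFIX_RE.match(s, i)
    if m:
        sulfates.append(int(m.group(1) or m.group(2) or 6))
        i = m.end()
    name = next((n for n in _NAMES if s.startswith(n, i)), None)
    if name is None:
        raise ParseError(f"unknown monosaccharide name at {s[i:i + 8]!r}", offset + i)
    i += len(name)
    while (m := _SULF_MOD_RE.match(s, i)) is not None:
        sulfates.append(int(m.group(1)))
        i = m.end()
    linkage = None
    anomer = "?"
    m = _LINKAGE_RE.match(s, i)
    if m is None and s.startswith("(", i):
        # ASCII style: linkage in parentheses after the name
        j = _matching(s, i)
        inner = _LINKAGE_RE.fullmatch(s[i + 1 : j])
        if inner is not None:
            m = inner
            i = j + 1
    elif m is not None:
        i = m.end()
    if m is not None:
        anomer = m.group(1)
        linkage = (m.group(2), m.group(3))
    residue = Residue(name=name, anomer=anomer, linkage=linkage, sulfates=tuple(sulfates))
    return residue, i


def _parse_chain(s: str, offset: int) -> Residue:
    """Parse a chain segment; returns the rightmost residue (subtree root).

    Elements are residues and bracketed branch groups; every element attaches
    to the next residue on its right.
    """
    if not s:
        raise ParseError("empty chain", offset)
    elements: list[tuple[str, Residue]] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "([":
            j = _matching(s, i)
            inner = s[i + 1 : j]
            elements.append(("group", _parse_chain(inner, offset + i + 1)))
            i = j + 1
        elif ch in ")]":
            raise ParseError("unexpected closing bracket", offset + i)
        else:
            residue, i = _parse_unit(s, i, offset)
            elements.append(("unit", residue))
    kind, last = elements[-1]
    if kind != "unit":
        raise ParseError("chain must end with a residue", offset + len(s) - 1)
    # attach each element to the next plain residue to its right
    for idx, (kind, res) in enumerate(elements[:-1]):
        parent = next(
            (r for k, r in elements[idx + 1 :] if k == "unit"), None
        )
        if parent is None:
            raise ParseError("branch has no residue to attach to", offset)
        if res.linkage is None:
            # linkage omitted in the text: fully unknown
            res.linkage = ("?", "?")
        try:
            parent.add_child(res)
        except GlycanError as exc:
            raise ParseError(str(exc), offset) from exc
    return last


def parse_structure(text: str) -> GlycanStructure:
    """Parse condensed notation into a :class:`GlycanStructure`."""
    s = _normalize(text)
    if not s:
        raise ParseError("empty structure string", 0)
    pa = False
    if s.endswith("-PA"):
        pa = True
        s = s[:-3]
    root = _parse_chain(s, 0)
    if root.linkage is not None:
        raise ParseError("reducing-end residue must not carry a linkage", len(s))
    glycan = GlycanStructure(root=root, pa=pa)
    return glycan


_ANOMER_OUT = {"a": "α", "b": "β", "?": "?"}


def _sort_key(residue: Residue):
    pos = residue.parent_pos
    return (pos == "?", pos, serialize_residue(residue))


def serialize_residue(residue: Residue) -> str:
    kids = sorted(residue.children, key=_sort_key)
    prefix = ""
    if kids:
        prefix = serialize_residue(kids[0])
        prefix += "".join(f"({serialize_residue(k)})" for k in kids[1:])
    out = residue.name + "".join(f"[{p}S]" for p in residue.sulfates)
    if residue.linkage is not None:
        child_pos, parent_pos = residue.linkage
        out += f"{_ANOMER_OUT[residue.anomer]}{child_pos}-{parent_pos}"
    return prefix + out


def serialize_structure(glycan: GlycanStructure) -> str:
    """Canonical condensed-notation string for a structure."""
    out = serialize_residue(glycan.root)
    if glycan.pa:
        out += "-PA"
    return out
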