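"""Tolerance-based identification against the GU reference map.

A query carries observed glucose units on one or both columns, optionally a
nominal mass and a Mono-Q charge class. Candidates must pass the charge gate,
then every supplied GU axis within its tolerance, then the mass tolerance.
The score normalizes each GU deviation by its tolerance so the amide and C30
axes contribute equally; when more than one entry survives, the result is
flagged ambiguous rather than silently resolved — mirroring the bench
practice of confirming such cases enzymatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .mass import nominal_mh
from .reference_map import MapEntry
from .structures import Composition, GlycanError

__all__ = [
    "Query",
    "Match",
    "MatchResult",
    "CompositionBounds",
    "match_query",
    "enumerate_compositions",
    "minimum_pairwise_gap",
]

DEFAULT_GU_TOLERANCE = 0.2
DEFAULT_MASS_TOLERANCE = 1.0


@dataclass(frozen=True)
class Query:
    """Observed coordinates of one unknown PA-glycan."""

    gu_amide: Optional[float] = None
    gu_c30: Optional[float] = None
    mass: Optional[float] = None
    charge: Optional[int] = None
    tol_gu_amide: float = DEFAULT_GU_TOLERANCE
    tol_gu_c30: float = DEFAULT_GU_TOLERANCE
    tol_mass: float = DEFAULT_MASS_TOLERANCE

    def __post_init__(self) -> None:
        if self.gu_amide is None and self.gu_c30 is None:
            raise ValueError("query needs at least one GU coordinate")
        if min(self.tol_gu_amide, self.tol_gu_c30, self.tol_mass) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class Match:
    entry: MapEntry
    score: float
    d_amide: Optional[float]
    d_c30: Optional[float]
    d_mass: Optional[float]


@dataclass(frozen=True)
class MatchResult:
    matches: List[Match] = field(default_factory=list)
    ambiguous: bool = False

    @property
    def top(self) -> Optional[Match]:
        return self.matches[0] if self.matches else None


def _evaluate(query: Query, entry: MapEntry) -> Optional[Match]:
    if query.charge is not None and entry.charge_class != query.charge:
        return None
    d_amide = d_c30 = d_mass = None
    score_sq = 0.0
    if query.gu_amide is not None:
        d_amide = entry.gu_amide - query.gu_amide
        if abs(d_amide) > query.tol_gu_amide:
            return None
        score_sq += (d_amide / query.tol_gu_amide) ** 2
    if query.gu_c30 is not None:
        d_c30 = entry.gu_c30 - query.gu_c30
        if abs(d_c30) > query.tol_gu_c30:
            return None
        score_sq += (d_c30 / query.tol_gu_c30) ** 2
    if query.mass is not None:
        d_mass = entry.mass_printed - query.mass
        if abs(d_mass) > query.tol_mass:
            return None
    return Match(entry, math.sqrt(score_sq), d_amide, d_c30, d_mass)


def match_query(query: Query, entries: Sequence[MapEntry]) -> MatchResult:
    """Rank map entries compatible with the query.

    Ties break deterministically by smaller absolute mass deviation, then by
    canonical structure string.
    """
    if not entries:
        raise ValueError("reference map is empty")
    matches = [m for m in (_evaluate(query, e) for e in entries) if m is not None]
    matches.sort(
        key=lambda m: (
            m.score,
            abs(m.d_mass) if m.d_mass is not None else float("inf"),
            m.entry.structure_text,
        )
    )
    return MatchResult(matches=matches, ambiguous=len(matches) > 1)


@dataclass(frozen=True)
class CompositionBounds:
    """Per-class maxima for composition enumeration."""

    hex: int = 6
    hexnac: int = 6
    dhex: int = 2
    neu5ac: int = 4
    so3: int = 2


def enumerate_compositions(
    mass: float,
    tol: float = DEFAULT_MASS_TOLERANCE,
    bounds: CompositionBounds = CompositionBounds(),
    nominal: bool = True,
) -> List[Composition]:
    """All PA compositions whose mass lies within ``tol`` of ``mass``.

    ``nominal=True`` compares against the integer nominal [M+H]+ (the
    printed-table convention); otherwise the neutral monoisotopic mass.
    Sorted by absolute mass deviation, then total residue count, then counts.
    """
    if mass <= 0 or tol <= 0:
        raise GlycanError("mass and tolerance must be positive")
    from .mass import monoisotopic_mass

    hits: List[tuple] = []
    for h in range(bounds.hex + 1):
        for n in range(bounds.hexnac + 1):
            for d in range(bounds.dhex + 1):
                for s in range(bounds.neu5ac + 1):
                    for so in range(bounds.so3 + 1):
                        if h + n + d + s == 0:
                            continue
                        c = Composition(hex=h, hexnac=n, dhex=d, neu5ac=s, so3=so)
                        m = nominal_mh(c, "H") if nominal else monoisotopic_mass(c)
                        dev = abs(m - mass)
                        if dev <= tol:
                            hits.append((dev, c.total_residues, (h, n, d, s, so), c))
    hits.sort(key=lambda t: t[:3])
    return [t[3] for t in hits]


def minimum_pairwise_gap(entries: Sequence[MapEntry]) -> float:
    """Smallest Chebyshev (max over the two GU axes) distance between map entries.

    Documents how tightly the map is packed; entry pairs closer than the GU
    tolerance on both axes can only be resolved with mass, charge, or
    enzymatic evidence.
    """
    gap = float("inf")
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            gap = min(
                gap, max(abs(a.gu_amide - b.gu_amide), abs(a.gu_c30 - b.gu_c30))
            )
    return gap
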