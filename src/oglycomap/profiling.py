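"""Quantitative O-glycosylation profiling from HPLC peak lists.

The workflow mirrors the three-column separation: Mono-Q anion exchange
splits the PA-glycan pool into charge fractions (neutral / mono- / di-
anionic), each fraction is resolved on the C30 column, and C30 peaks are
confirmed on the amide column. Peaks belonging to one analyte across
columns share a ``group_id``. Retention times are converted to GU with
per-column calibrations and matched jointly against the reference map with
the fraction's charge as a gate.

Quantitation assumes equimolar fluorescence response of PA derivatives, so
the molar percent of each species is its peak area over the total area of
all non-excluded peaks. Carryover peaks (e.g. melibiose from lectin
elution) are excluded by label before the denominator is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .calibration import GUCalibration
from .identify import Query, match_query
from .reference_map import MapEntry

__all__ = [
    "Peak",
    "ProfileEntry",
    "Profile",
    "ProfilingError",
    "exclude_flagged",
    "profile_pipeline",
    "read_peaks_csv",
    "write_profile_tsv",
]

PEAK_COLUMNS = ["group_id", "fraction", "charge", "column", "rt_min", "area", "flag"]


class ProfilingError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """One fluorescence peak on one column."""

    group_id: str
    fraction: str
    charge: int
    column: str  # 'C30' | 'amide'
    rt_min: float
    area: float
    flag: str = ""

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ProfilingError(f"peak {self.group_id}: negative area")
        if self.rt_min <= 0:
            raise ProfilingError(f"peak {self.group_id}: non-positive retention time")
        if self.column not in ("C30", "amide"):
            raise ProfilingError(f"peak {self.group_id}: unknown column {self.column!r}")


@dataclass(frozen=True)
class ProfileEntry:
    assignment: str  # canonical structure or 'unassigned'
    molar_percent: float
    peaks: tuple
    score: Optional[float] = None
    ambiguous: bool = False
    conflicted: bool = False
    candidates: tuple = ()


@dataclass(frozen=True)
class Profile:
    entries: tuple

    def percents(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for e in self.entries:
            out[e.assignment] = out.get(e.assignment, 0.0) + e.molar_percent
        return out

    def total_percent(self) -> float:
        return sum(e.molar_percent for e in self.entries)


def exclude_flagged(peaks: Iterable[Peak], labels: Sequence[str]) -> List[Peak]:
    """Drop peaks whose flag is in ``labels`` (e.g. melibiose carryover)."""
    labels = set(labels)
    return [p for p in peaks if p.flag not in labels or not p.flag]


def _group_area(group: List[Peak]) -> float:
    # C30 is the quantitation dimension; amide areas back it up when a group
    # was only observed there.
    c30 = [p.area for p in group if p.column == "C30"]
    if c30:
        return sum(c30)
    return sum(p.area for p in group)


def profile_pipeline(
    peaks: Sequence[Peak],
    calibrations: Dict[str, GUCalibration],
    entries: Sequence[MapEntry],
    tol_gu_amide: float = 0.2,
    tol_gu_c30: float = 0.2,
    exclusion_labels: Sequence[str] = ("melibiose",),
) -> Profile:
    """Identify and quantify every peak group; returns a molar-percent profile.

    Peak groups whose joint (both-axis) match is empty although each single
    axis alone matches something are marked conflicted, not dropped: they
    appear as 'unassigned' with their area still in the denominator.
    """
    kept = exclude_flagged(peaks, exclusion_labels)
    if not kept:
        raise ProfilingError("no peaks remain after exclusion")
    for p in kept:
        if p.column not in calibrations:
            raise ProfilingError(f"no calibration supplied for column {p.column!r}")

    groups: Dict[str, List[Peak]] = {}
    for p in kept:
        groups.setdefault(p.group_id, []).append(p)

    total_area = sum(_group_area(g) for g in groups.values())
    if total_area <= 0:
        raise ProfilingError("total peak area is zero")

    result_entries: List[ProfileEntry] = []
    for gid in sorted(groups):
        group = groups[gid]
        charges = {p.charge for p in group}
        if len(charges) != 1:
            raise ProfilingError(f"group {gid}: inconsistent charge labels {charges}")
        charge = charges.pop()
        gu: Dict[str, float] = {}
        for col in ("C30", "amide"):
            times = [p.rt_min for p in group if p.column == col]
            if times:
                cal = calibrations[col]
                gu[col] = sum(cal.time_to_gu(t) for t in times) / len(times)
        query = Query(
            gu_amide=gu.get("amide"),
            gu_c30=gu.get("C30"),
            charge=charge,
            tol_gu_amide=tol_gu_amide,
            tol_gu_c30=tol_gu_c30,
        )
        res = match_query(query, entries)
        percent = 100.0 * _group_area(group) / total_area
        if res.top is not None:
            result_entries.append(
                ProfileEntry(
                    assignment=res.top.entry.structure_text,
                    molar_percent=percent,
                    peaks=tuple(group),
                    score=res.top.score,
                    ambiguous=res.ambiguous,
                    candidates=tuple(m.entry.structure_text for m in res.matches),
                )
            )
        else:
            conflicted = False
            if "amide" in gu and "C30" in gu:
                # would either axis alone have matched?
                for axis_query in (
                    Query(gu_amide=gu["amide"], charge=charge, tol_gu_amide=tol_gu_amide),
                    Query(gu_c30=gu["C30"], charge=charge, tol_gu_c30=tol_gu_c30),
                ):
                    if match_query(axis_query, entries).matches:
                        conflicted = True
                        break
            result_entries.append(
                ProfileEntry(
                    assignment="unassigned",
                    molar_percent=percent,
                    peaks=tuple(group),
                    conflicted=conflicted,
                )
            )
    result_entries.sort(key=lambda e: -e.molar_percent)
    return Profile(entries=tuple(result_entries))


def read_peaks_csv(path) -> List[Peak]:
    df = pd.read_csv(Path(path), dtype={"flag": str}, keep_default_na=False)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ProfilingError(f"peaks CSV missing columns: {sorted(missing)}")
    return [
        Peak(
            group_id=str(r.group_id),
            fraction=str(r.fraction),
            charge=int(r.charge),
            column=str(r.column),
            rt_min=float(r.rt_min),
            area=float(r.area),
            flag=str(r.flag),
        )
        for r in df.itertuples()
    ]


def write_profile_tsv(profile: Profile, path) -> None:
    rows = [
        {
            "assignment": e.assignment,
            "molar_percent": round(e.molar_percent, 4),
            "score": "" if e.score is None else round(e.score, 4),
            "ambiguous": e.ambiguous,
            "conflicted": e.conflicted,
            "n_peaks": len(e.peaks),
        }
        for e in profile.entries
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
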