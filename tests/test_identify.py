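"""Map matching and composition enumeration against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from oglycomap import (
    CompositionBounds,
    Query,
    enumerate_compositions,
    match_query,
    nominal_mh,
)
from oglycomap.identify import minimum_pairwise_gap
from oglycomap.structures import Composition, GlycanError


def test_worked_example_unique_top_hit(entries):
    q = Query(gu_amide=3.2, gu_c30=4.6, mass=665, tol_gu_amide=0.2, tol_gu_c30=0.2, tol_mass=1)
    res = match_query(q, entries)
    assert res.top.entry.structure_text == "Galβ1-3(GlcNAcβ1-6)GalNAc-PA"
    assert not res.ambiguous


def test_self_match_scores_zero_for_every_entry(entries):
    for e in entries:
        q = Query(gu_amide=e.gu_amide, gu_c30=e.gu_c30, mass=e.mass_printed)
        res = match_query(q, entries)
        assert res.top.entry.structure_text == e.structure_text
        assert res.top.score == 0.0


def test_two_axis_query_without_mass(entries):
    res = match_query(Query(gu_amide=2.4, gu_c30=6.3), entries)
    assert res.top.entry.structure_text == "GlcNAcβ1-6GalNAc-PA"


def test_query_requires_an_axis_and_positive_tolerances():
    with pytest.raises(ValueError):
        Query(mass=665)
    with pytest.raises(ValueError):
        Query(gu_amide=3.2, tol_gu_amide=0)


def test_empty_map_is_an_error():
    with pytest.raises(ValueError):
        match_query(Query(gu_amide=1.0), [])


def _oracle_match(q, entries):
    """Independent exhaustive scan with the documented gates and ordering."""
    out = []
    for e in entries:
        if q.charge is not None and e.charge_class != q.charge:
            continue
        score = 0.0
        ok = True
        if q.gu_amide is not None:
            d = abs(e.gu_amide - q.gu_amide)
            ok &= d <= q.tol_gu_amide
            score += (d / q.tol_gu_amide) ** 2
        if q.gu_c30 is not None:
            d = abs(e.gu_c30 - q.gu_c30)
            ok &= d <= q.tol_gu_c30
            score += (d / q.tol_gu_c30) ** 2
        if q.mass is not None:
            ok &= abs(e.mass_printed - q.mass) <= q.tol_mass
        if ok:
            dm = abs(e.mass_printed - q.mass) if q.mass is not None else math.inf
            out.append((math.sqrt(score), dm, e.structure_text))
    return sorted(out)


def test_matching_agrees_with_brute_force_on_1000_random_queries(entries):
    rng = np.random.default_rng(2024)
    n_checked = 0
    while n_checked < 1000:
        gu_amide = float(rng.uniform(0, 7)) if rng.random() < 0.8 else None
        gu_c30 = float(rng.uniform(0, 13)) if rng.random() < 0.8 else None
        if gu_amide is None and gu_c30 is None:
            continue
        q = Query(
            gu_amide=gu_amide,
            gu_c30=gu_c30,
            mass=float(rng.choice([259, 300, 462, 503, 583, 608, 665, 745, 753, 811,
                                   827, 868, 948, 956, 1044, 1118, 1395, 1475]))
            if rng.random() < 0.5
            else None,
            charge=int(rng.integers(0, 3)) if rng.random() < 0.4 else None,
            tol_gu_amide=float(rng.uniform(0.05, 0.5)),
            tol_gu_c30=float(rng.uniform(0.05, 0.5)),
            tol_mass=float(rng.uniform(0.5, 2.0)),
        )
        n_checked += 1
        res = match_query(q, entries)
        got = [(m.score, abs(m.d_mass) if m.d_mass is not None else math.inf,
                m.entry.structure_text) for m in res.matches]
        expected = _oracle_match(q, entries)
        assert [g[2] for g in got] == [e[2] for e in expected]
        for g, e in zip(got, expected):
            assert g[0] == pytest.approx(e[0], abs=1e-12)
        assert res.ambiguous == (len(expected) > 1)


def test_tightening_tolerance_never_adds_candidates(entries):
    base = Query(gu_amide=2.5, gu_c30=3.0, tol_gu_amide=0.5, tol_gu_c30=0.5)
    wide = {m.entry.structure_text for m in match_query(base, entries).matches}
    for tol in (0.4, 0.3, 0.2, 0.1, 0.05):
        narrow_q = Query(gu_amide=2.5, gu_c30=3.0, tol_gu_amide=tol, tol_gu_c30=tol)
        narrow = {m.entry.structure_text for m in match_query(narrow_q, entries).matches}
        assert narrow <= wide
        wide = narrow


def test_disialyl_isomer_pair_flagged_ambiguous(entries):
    # closest pair in the map: 0.1 GU apart on C30, identical mass and charge
    res = match_query(Query(gu_amide=2.7, gu_c30=2.25, charge=2), entries)
    assert res.ambiguous and len(res.matches) == 2


def test_minimum_pairwise_gap_is_the_disialyl_gap(entries):
    assert minimum_pairwise_gap(entries) == pytest.approx(0.1)


# ---- composition enumeration ------------------------------------------------


def _oracle_enumerate(mass, tol, bounds):
    hits = []
    for h, n, d, s, so in itertools.product(
        range(bounds.hex + 1),
        range(bounds.hexnac + 1),
        range(bounds.dhex + 1),
        range(bounds.neu5ac + 1),
        range(bounds.so3 + 1),
    ):
        if h + n + d + s == 0:
            continue
        c = Composition(hex=h, hexnac=n, dhex=d, neu5ac=s, so3=so)
        if abs(nominal_mh(c, "H") - mass) <= tol:
            hits.append(c)
    return set(hits)


def test_665_resolves_uniquely_to_hex1_hexnac2():
    hits = enumerate_compositions(665, 1)
    assert hits == [Composition(hex=1, hexnac=2)]


def test_1475_includes_the_sulfated_heptasaccharide_composition():
    assert Composition(hex=3, hexnac=4, so3=1) in enumerate_compositions(1475, 1)


def test_tiny_mass_yields_no_composition():
    assert enumerate_compositions(0.5, 0.1) == []


def test_nonpositive_inputs_rejected():
    with pytest.raises(GlycanError):
        enumerate_compositions(-1, 1)
    with pytest.raises(GlycanError):
        enumerate_compositions(665, 0)


@pytest.mark.parametrize("mass,tol", [(665, 1), (1044, 1), (1475, 2), (500, 10), (300, 0.5)])
def test_enumeration_agrees_with_exhaustive_oracle(mass, tol):
    bounds = CompositionBounds()
    assert set(enumerate_compositions(mass, tol, bounds)) == _oracle_enumerate(
        mass, tol, bounds
    )


def test_enumeration_sorted_by_mass_deviation_then_size():
    hits = enumerate_compositions(665, 40)
    devs = [abs(nominal_mh(c, "H") - 665) for c in hits]
    assert devs == sorted(devs)
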