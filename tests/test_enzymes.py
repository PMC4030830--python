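"""In-silico enzymology: digestion, sialylation, GlcNAc6ST-1 sulfation."""

import pytest

from oglycomap import (
    composition_of,
    digest,
    find_entry,
    get_rule,
    load_enzyme_rules,
    monoisotopic_mass,
    nominal_mh,
    parse_structure,
    sialylate,
    sulfate_glcnac6st1,
)
from oglycomap.mass import MONOISOTOPIC
from oglycomap.structures import GlycanError


def test_b13_galactosidase_confirms_the_core2_assignment():
    g = parse_structure("Galβ1-3(GlcNAcβ1-6)GalNAc-PA")
    res = digest(g, "b1,3-galactosidase")
    assert res.cleaved and res.removed == 1
    assert res.structure.canonical() == "GlcNAcβ1-6GalNAc-PA"


def test_digest_product_found_in_map_at_c30_gu_6_3(entries):
    res = digest(parse_structure("Galβ1-3(GlcNAcβ1-6)GalNAc-PA"), "b1,3-galactosidase")
    entry = find_entry(entries, res.structure)
    assert entry is not None and entry.gu_c30 == 6.3


def test_broad_sialidase_exhaustive_strips_both_neu5ac():
    g = parse_structure("Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-PA")
    res = digest(g, "a-sialidase", exhaustive=True)
    assert res.structure.canonical() == "Galβ1-3GalNAc-PA"
    assert res.removed == 2


def test_a23_sialidase_spares_the_26_linked_neu5ac():
    g = parse_structure("Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-PA")
    res = digest(g, "a2,3-sialidase", exhaustive=True)
    assert res.structure.canonical() == "Galβ1-3(Neu5Acα2-6)GalNAc-PA"


def test_noop_digest_returns_unchanged_with_flag():
    g = parse_structure("GalNAc-PA")
    res = digest(g, "b-galactosidase")
    assert not res.cleaved and res.structure == g


def test_root_galnac_never_removed():
    g = parse_structure("GalNAc-PA")
    res = digest(g, "b-N-acetylhexosaminidase", exhaustive=True)
    assert not res.cleaved


def test_sulfated_glcnac_resists_hexosaminidase():
    g = parse_structure("HSO3-6GlcNAcβ1-6GalNAc-PA")
    res = digest(g, "b-N-acetylhexosaminidase", exhaustive=True)
    assert not res.cleaved
    plain = parse_structure("GlcNAcβ1-6GalNAc-PA")
    assert digest(plain, "b-N-acetylhexosaminidase").cleaved


def test_exhaustive_digestion_reaches_a_fixpoint(entries):
    for e in entries:
        res = digest(e.structure, "b-galactosidase", exhaustive=True)
        again = digest(res.structure, "b-galactosidase", exhaustive=True)
        assert not again.cleaved


def test_digestion_mass_bookkeeping_exact(entries):
    rule = get_rule("a-sialidase")
    for e in entries:
        res = digest(e.structure, rule, exhaustive=True)
        dm = monoisotopic_mass(composition_of(e.structure)) - monoisotopic_mass(
            composition_of(res.structure)
        )
        assert dm == pytest.approx(res.removed * MONOISOTOPIC["Neu5Ac"], abs=1e-9)


def test_a26_sialylation_reproduces_the_disialyl_product():
    g = parse_structure("Galβ1-3(Neu5Acα2-6)GalNAc-PA")
    product = sialylate(g, linkage="2-6", acceptor="Gal")
    assert product.canonical() == "Neu5Acα2-6Galβ1-3(Neu5Acα2-6)GalNAc-PA"
    dm = monoisotopic_mass(composition_of(product)) - monoisotopic_mass(composition_of(g))
    assert dm == pytest.approx(MONOISOTOPIC["Neu5Ac"], abs=1e-9)


def test_a23_sialylation_on_the_b14_gal_arm(entries):
    g = parse_structure("Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-PA")
    product = sialylate(g, linkage="2-3", acceptor="Gal", acceptor_linkage="1-4")
    assert product.canonical() == "Galβ1-3(Neu5Acα2-3Galβ1-4GlcNAcβ1-6)GalNAc-PA"
    assert find_entry(entries, product).mass_printed == 1118


def test_sialylation_of_occupied_site_is_an_error():
    g = parse_structure("Neu5Acα2-6Galβ1-3(Neu5Acα2-6)GalNAc-PA")
    with pytest.raises(GlycanError, match="no free"):
        sialylate(g, linkage="2-6", acceptor="Gal")


def test_ambiguous_acceptor_requires_disambiguation():
    g = parse_structure("Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-PA")
    with pytest.raises(GlycanError, match="disambiguate"):
        sialylate(g, linkage="2-3", acceptor="Gal")


def test_sialidase_inverts_sialylation():
    g = parse_structure("Galβ1-3GalNAc-PA")
    product = sialylate(g, linkage="2-3", acceptor="Gal")
    back = digest(product, "a2,3-sialidase")
    assert back.structure == g


def test_glcnac6st1_prefers_the_b16_branch():
    g = parse_structure("GlcNAcβ1-6(GlcNAcβ1-3Galβ1-3)GalNAc-PA")
    products = [p.canonical() for p in sulfate_glcnac6st1(g)]
    assert products == [
        "GlcNAcβ1-3Galβ1-3(GlcNAc[6S]β1-6)GalNAc-PA",
        "GlcNAc[6S]β1-3Galβ1-3(GlcNAcβ1-6)GalNAc-PA",
    ]


def test_glcnac6st1_single_site_product_and_mass():
    g = parse_structure("GlcNAcβ1-6GalNAc-PA")
    products = sulfate_glcnac6st1(g)
    assert len(products) == 1
    assert products[0].canonical() == "GlcNAc[6S]β1-6GalNAc-PA"
    dm = monoisotopic_mass(composition_of(products[0])) - monoisotopic_mass(
        composition_of(g)
    )
    assert dm == pytest.approx(79.9568, abs=1e-9)
    assert nominal_mh(composition_of(products[0]), "H") == 583


def test_glcnac6st1_without_eligible_site_is_an_error():
    with pytest.raises(GlycanError, match="no terminal GlcNAc"):
        sulfate_glcnac6st1(parse_structure("Galβ1-3GalNAc-PA"))


def test_bundled_rule_table_loads_all_six_exoglycosidases():
    rules = load_enzyme_rules()
    assert {
        "a-sialidase",
        "a2,3-sialidase",
        "b-galactosidase",
        "b1,3-galactosidase",
        "a-galactosidase",
        "b-N-acetylhexosaminidase",
    } <= set(rules)
    assert all(r.action == "remove" and r.terminal_only for r in rules.values())
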