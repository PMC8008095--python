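"""Structure identifiers: parsing, canonical serialization, core
classification, and the external linear notations."""

import pytest
from hypothesis import given

from gangliosim import (GangliosimError, GlycanParseError, Structure,
                        UnclassifiableStructureError, parse_identifier)

from conftest import structures

GM1A = "L3Vb4[S3]L4GT"
GP1CA = "S3L3[S6]Vb4[S8S8S3]L4GT"


class TestParse:
    def test_gm1a_tree_shape(self):
        s = Structure.parse("Lb3Vb4[Sa3]Lb4GbT")
        t = s.root
        assert t.code == "T" and len(t.children) == 1
        glc = t.children[0]
        assert (glc.code, glc.anomer, glc.linkage) == ("G", "b", None)
        gal2 = glc.chain_child
        assert (gal2.code, gal2.linkage) == ("L", 4)
        assert [b.code for b in gal2.branch_children] == ["S"]
        galnac = gal2.chain_child
        assert (galnac.code, galnac.anomer, galnac.linkage) == ("V", "b", 4)
        gal4 = galnac.chain_child
        assert (gal4.code, gal4.linkage) == ("L", 3)
        assert gal4.children == []

    def test_both_dialects_parse_to_the_same_tree(self):
        assert Structure.parse("Lb3Vb4[Sa3]Lb4GbT") == Structure.parse(GM1A)

    def test_bare_ceramide(self):
        s = Structure.parse("T")
        assert len(s) == 1 and s.root.children == []

    def test_pentasialo_example_tree(self):
        s = Structure.parse(GP1CA)
        assert s.count_residues("S") == 5
        gal2 = s.root.children[0].chain_child
        branch = gal2.branch_children[0]
        # chain of three sialic acids on the inner galactose
        assert (branch.code, branch.linkage) == ("S", 3)
        assert (branch.chain_child.code, branch.chain_child.linkage) == ("S", 8)
        assert branch.chain_child.chain_child.linkage == 8
        galnac = gal2.chain_child
        assert [(b.code, b.linkage) for b in galnac.branch_children] == [("S", 6)]

    @pytest.mark.parametrize("bad", [
        "", "L3Vb4[S3L4GT", "L3Vb4S3]L4GT",     # empty / unbalanced
        "X4GT",                                   # unknown letter
        "L4G", "TL4G",                            # T absent / not last
        "L4G4T",                                  # linkage on the T-adjacent residue
        "L4GTT", "[L4GT]T",                       # multiple T / branch on T
        "LLT",                                    # missing linkage
        "[S3][S3]L4GT",                           # duplicate position
        "[]L4GT",                                 # empty branch
        "Tb", "T3",                               # decorated ceramide
    ])
    def test_rejects_malformed_identifiers(self, bad):
        with pytest.raises(GlycanParseError):
            Structure.parse(bad)

    def test_parse_identifier_alias(self):
        assert parse_identifier(GM1A) == Structure.parse(GM1A)


class TestSerialize:
    @pytest.mark.parametrize("abbrev, full", [
        (GM1A, "Lb3Vb4[Sa3]Lb4GbT"),
        ("LT", "LbT"),
        ("GT", "GbT"),
        (GP1CA, "Sa3Lb3[Sa6]Vb4[Sa8Sa8Sa3]Lb4GbT"),
        ("T", "T"),
    ])
    def test_dialects(self, abbrev, full):
        s = Structure.parse(abbrev)
        assert s.abbreviated == abbrev
        assert s.full == full
        assert Structure.parse(full).abbreviated == abbrev

    def test_galnac_beta_always_written(self):
        # the abbreviated dialect drops default anomers but keeps GalNAc's b
        assert "Vb4" in Structure.parse("Vb4L4GT").abbreviated

    def test_unknown_dialect_rejected(self):
        with pytest.raises(GangliosimError):
            Structure.parse("T").serialize("compact")

    def test_branch_order_is_canonicalized(self):
        # two bracketed branches in either textual order give one canonical form
        a = Structure.parse("[S6][S3]L4GT")
        b = Structure.parse("[S3][S6]L4GT")
        assert a == b
        assert a.abbreviated == "[S6][S3]L4GT"  # lowest linkage nearest parent

    def test_canonicalization_is_idempotent(self, wild_type):
        for nid in wild_type.node_ids():
            assert Structure.parse(nid).abbreviated == nid


class TestRoundTrip:
    def test_all_network_structures_round_trip(self, wild_type):
        for nid in wild_type.node_ids():
            s = wild_type.structure(nid)
            assert Structure.parse(s.abbreviated) == s
            assert Structure.parse(s.full) == s

    @given(structures())
    def test_random_trees_round_trip_both_dialects(self, s):
        assert Structure.parse(s.abbreviated) == s
        assert Structure.parse(s.full) == s

    @given(structures())
    def test_residue_counts_sum_to_tree_size(self, s):
        assert sum(s.count_residues(c) for c in "GLSVT") == len(s)


class TestCounting:
    @pytest.mark.parametrize("text, code, expected", [
        (GP1CA, "S", 5),
        ("T", "S", 0),
        ("T", "G", 0),
        (GM1A, "L", 2),
        (GP1CA, "L", 2),
        (GM1A, "V", 1),
    ])
    def test_count_residues(self, text, code, expected):
        assert Structure.parse(text).count_residues(code) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(GangliosimError):
            Structure.parse("T").count_residues("X")


class TestCoreInfo:
    def test_gm1a(self):
        info = Structure.parse(GM1A).core_info()
        assert (info.base_kind, info.core_length) == ("Glc", 4)
        assert (info.sialo_ii, info.sialo_iv, info.sialo_iii) == (1, 0, 0)
        assert info.core_number == 1
        assert sorted(info.positions) == ["I", "II", "III", "IV"]
        assert info.positions["III"].code == "V"

    def test_galcer(self):
        info = Structure.parse("LT").core_info()
        assert (info.base_kind, info.core_number) == ("Gal", 4)
        assert (info.sialo_ii, info.sialo_iv, info.sialo_iii) == (0, 0, 0)

    def test_pentasialo(self):
        info = Structure.parse(GP1CA).core_info()
        assert info.core_length == 4
        assert (info.sialo_ii, info.sialo_iv, info.sialo_iii) == (3, 1, 1)

    @pytest.mark.parametrize("text, n, core_number", [
        ("GT", 1, 4), ("L4GT", 2, 3), ("Vb4L4GT", 3, 2), ("L3Vb4L4GT", 4, 1),
    ])
    def test_core_lengths(self, text, n, core_number):
        info = Structure.parse(text).core_info()
        assert (info.core_length, info.core_number) == (n, core_number)

    def test_bare_ceramide_has_no_core(self):
        info = Structure.parse("T").core_info()
        assert info.base_kind is None and info.core_length == 0

    @pytest.mark.parametrize("bad", [
        "S3L4GT",              # unbracketed sialyl chain on position II
        "[S8S8S8S3]L4GT",      # sialyl chain longer than three
        "[S4]L4GT",            # sialic acid through the wrong position
        "L3L4GT",              # Gal where GalNAc belongs
        "Va4L4GT",             # alpha-GalNAc (model requires beta)
        "[S6S6]Vb4L4GT",       # extended alpha-2,6 branch on GalNAc
        "ST",                  # sialic acid on ceramide
        "[G3]L4GT",            # non-sialic branch
    ])
    def test_unclassifiable_structures_raise(self, bad):
        with pytest.raises(UnclassifiableStructureError):
            Structure.parse(bad).core_info()


class TestIupacCondensed:
    @pytest.mark.parametrize("ident, iupac", [
        (GM1A, "Galb1-3GalNAcb1-4[Neu5Aca2-3]Galb1-4GlcCer"),
        ("GT", "GlcCer"),
        ("LT", "GalCer"),
        ("L4GT", "Galb1-4GlcCer"),
        ("T", "Cer"),
        ("[S3]L4GT", "[Neu5Aca2-3]Galb1-4GlcCer"),
    ])
    def test_known_translations(self, ident, iupac):
        s = Structure.parse(ident)
        assert s.to_iupac_condensed() == iupac
        assert Structure.from_iupac_condensed(iupac) == s

    def test_network_wide_round_trip(self, wild_type):
        for nid in wild_type.node_ids():
            s = wild_type.structure(nid)
            assert Structure.from_iupac_condensed(s.to_iupac_condensed()) == s

    def test_lactose_shorthand(self):
        assert Structure.from_iupac_condensed("LacCer").abbreviated == "L4GT"

    @pytest.mark.parametrize("bad", ["", "FooCer", "Galb1-4Glc",
                                     "Neu5Acb1-3GalCer", "Lacb1-4Cer"])
    def test_malformed_iupac_rejected(self, bad):
        with pytest.raises(GlycanParseError):
            Structure.from_iupac_condensed(bad)


class TestLinearCode:
    @pytest.mark.parametrize("ident, lc", [
        (GM1A, "Ab3GNb4(NNa3)Ab4GCer"),
        ("T", "Cer"),
        ("L4GT", "Ab4GCer"),
        (GP1CA, "NNa3Ab3(NNa6)GNb4(NNa8NNa8NNa3)Ab4GCer"),
    ])
    def test_export(self, ident, lc):
        assert Structure.parse(ident).to_linear_code() == lc


class TestIdentity:
    def test_equality_and_hash_by_canonical_form(self):
        a = Structure.parse("Lb3Vb4[Sa3]Lb4GbT")
        b = Structure.parse(GM1A)
        assert a == b and hash(a) == hash(b)
        assert a != Structure.parse("L4GT")
        assert len({a, b}) == 1
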