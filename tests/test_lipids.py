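"""Annotation parsing, the component partition, and structural Z_C rules."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidzc.chem import parse_formula, zc
from lipidzc.lipids import (
    BACKBONES,
    HEADGROUPS,
    ChainSpec,
    LipidSpec,
    assemble,
    backbone_formula,
    canonical_name,
    chain_formula,
    headgroup_formula,
    parse_ipl_name,
)

F = parse_formula


class TestParser:
    def test_diacyl_lipid(self):
        s = parse_ipl_name("PC-DAG(32:0)")
        assert s.headgroup_codes == ("PC",)
        assert s.backbone_class == "DAG"
        assert [c.n_c for c in s.chains] == [16, 16]
        assert all(c.linkage == "ester" for c in s.chains)

    def test_gdgt_gets_hydroxyl_headgroup_and_half_chains(self):
        s = parse_ipl_name("1G-GDGT(2)")
        assert s.headgroup_codes == ("1G", "H")
        assert s.n_backbones == 2
        assert len(s.chains) == 4
        assert all(c.is_gdgt_half and c.n_c == 20 for c in s.chains)
        assert s.rings_total == 2

    def test_total_unsaturation_split(self):
        s = parse_ipl_name("SQ-DAG(34:1)")
        assert sorted(c.n_c for c in s.chains) == [17, 17]
        assert sum(c.n_unsat for c in s.chains) == 1

    def test_odd_carbon_total_splits_nearly_evenly(self):
        s = parse_ipl_name("2G-P-AR(55:0)")
        assert sorted(c.n_c for c in s.chains) == [27, 28]
        assert all(c.linkage == "ether" for c in s.chains)

    def test_per_chain_syntax(self):
        s = parse_ipl_name("PC-DAG(16:0/18:1)")
        assert [(c.n_c, c.n_unsat) for c in s.chains] == [(16, 0), (18, 1)]

    def test_archaeol_is_isoprenoid_diether(self):
        s = parse_ipl_name("2G-P-AR(40:0)")
        assert s.backbone_class == "DEG"
        assert all(c.linkage == "ether" and c.isoprenoid for c in s.chains)

    def test_cardiolipin_has_two_backbones_four_chains(self):
        s = parse_ipl_name("DPG(64:2)")
        assert s.backbone_class == "DPG"
        assert s.n_backbones == 2 and s.n_chains == 4

    def test_three_chain_glycophospholipid(self):
        s = parse_ipl_name("NAcG-P-DAG(48:0)")
        assert s.n_chains == 3
        assert [c.n_c for c in s.chains] == [16, 16, 16]

    def test_mixed_acyl_ether(self):
        s = parse_ipl_name("PI-AEG(32:0)")
        assert [c.linkage for c in s.chains] == ["ester", "ether"]

    def test_hydroxylation_flag(self):
        s = parse_ipl_name("OL-FA-OH-FAm-OH(32:1;OH)")
        assert sum(c.n_oh for c in s.chains) == 1

    @pytest.mark.parametrize(
        "bad",
        ["XX-DAG(32:0)", "PC-XXX(32:0)", "PC-DAG(2)", "PC-DAG(1:0)",
         "PC-DAG(16:0/18:1/12:0)", "1G-GDGT(2:0)", "PC-DAG"],
    )
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_ipl_name(bad)

    def test_zero_chain_spec_rejected(self):
        with pytest.raises(ValueError):
            LipidSpec(("PC",), "DAG", ())

    def test_canonical_name_round_trips(self):
        # the serialized text may differ from the input; the structure must not
        for name in ("PC-DAG(32:0)", "1G-GDGT(2)", "2G-P-AR(40:0)",
                     "DPG(64:2)", "SQ-DAG(34:1)"):
            spec = parse_ipl_name(name)
            again = parse_ipl_name(canonical_name(spec))
            assert again.headgroup_codes == spec.headgroup_codes
            assert again.backbone_class == spec.backbone_class
            assert again.chains == spec.chains


class TestRegistries:
    def test_headgroup_examples(self):
        assert headgroup_formula("2G") == F("C12H21O10")
        h = headgroup_formula("H")
        assert (h.c, h.h, h.z) == (0, 1, 0)
        tmkl = headgroup_formula("TM-KL")
        assert tmkl == F("C9H19NO2+") and tmkl.z == 1

    def test_unknown_headgroup(self):
        with pytest.raises(ValueError):
            headgroup_formula("NOPE")

    def test_quaternary_ammonium_charges(self):
        for code in ("PC", "BL", "TM-KL", "TM-OL"):
            assert headgroup_formula(code).z == 1

    def test_backbones(self):
        assert backbone_formula("DAG") == F("C3H5O3")
        assert zc(backbone_formula("DAG")) == Fraction(1, 3)
        assert backbone_formula("CER") == F("C3H6NO2")
        assert BACKBONES["GDGT"]["n_backbones"] == 2
        with pytest.raises(ValueError):
            backbone_formula("NOPE")


class TestChainFormula:
    def test_ester_acyl(self):
        f = chain_formula(ChainSpec("ester", 16))
        assert f == F("C16H31O")
        assert zc(f) == Fraction(-29, 16)

    def test_ether(self):
        f = chain_formula(ChainSpec("ether", 16))
        assert f == F("C16H33")
        assert zc(f) == Fraction(-33, 16)

    def test_gdgt_half_chain_and_ring(self):
        f0 = chain_formula(ChainSpec("ether", 20, is_gdgt_half=True))
        assert f0 == F("C20H40") and zc(f0) == -2
        f1 = chain_formula(ChainSpec("ether", 20, is_gdgt_half=True, rings=1))
        assert f1 == F("C20H38") and zc(f1) == Fraction(-19, 10)

    def test_archaeol_chain_one_h_more_than_half_chain(self):
        ar = chain_formula(ChainSpec("ether", 20, isoprenoid=True))
        half = chain_formula(ChainSpec("ether", 20, is_gdgt_half=True))
        assert ar == F("C20H41")
        assert ar.h == half.h + 1 and ar.c == half.c

    def test_negative_hydrogen_rejected(self):
        with pytest.raises(ValueError):
            chain_formula(ChainSpec("ester", 2, n_unsat=2))

    @given(st.integers(8, 40), st.integers(0, 3))
    def test_unsaturation_shifts_zc_by_two_over_n(self, n, u):
        sat = chain_formula(ChainSpec("ester", n))
        mod = chain_formula(ChainSpec("ester", n, n_unsat=u))
        assert zc(mod) - zc(sat) == Fraction(2 * u, n)

    @given(st.integers(1, 40))
    def test_hydroxylation_adds_oxygen_only(self, n):
        plain = chain_formula(ChainSpec("ether", n))
        hydroxy = chain_formula(ChainSpec("ether", n, n_oh=1))
        assert hydroxy.h == plain.h and hydroxy.o == plain.o + 1
        assert zc(hydroxy) - zc(plain) == Fraction(2, n)

    def test_saturated_cc_chain_zc_approaches_minus_two_from_below(self):
        # -(2n+1)/n = -2 - 1/n: every added CH2 drives Z_C toward -2
        vals = [zc(chain_formula(ChainSpec("cc", n))) for n in range(2, 41)]
        assert all(a < b < -2 for a, b in zip(vals, vals[1:]))
        assert all(v == Fraction(-(2 * n + 1), n) for v, n in zip(vals, range(2, 41)))

    @given(st.integers(2, 40))
    def test_ether_more_reduced_than_ester_at_fixed_length(self, n):
        assert zc(chain_formula(ChainSpec("ether", n))) < zc(
            chain_formula(ChainSpec("ester", n))
        )


class TestAssemble:
    def test_diacyl_phosphatidylcholine(self):
        cf = assemble(parse_ipl_name("PC-DAG(32:0)"))
        assert cf.full == F("C40H81NO8P+")
        assert zc(cf.full) == Fraction(-33, 20)

    def test_glycosyl_tetraether(self):
        cf = assemble(parse_ipl_name("1G-GDGT(0)"))
        # C6H11O5 + H + 2xC3H5O3 + 4xC20H40 (monoglycosyl-caldarchaeol)
        assert cf.full == F("C92H182O11")
        assert cf.full.z == 0

    @pytest.mark.parametrize("code", sorted(set(HEADGROUPS) - {"H"}))
    def test_partition_exactness_across_registry(self, code):
        """Component formulae must sum exactly to the full formula."""
        backbone = next(
            bb for (hg, bb) in _RF_KEYS if hg == code
        )
        name = f"{code}-GDGT(2)" if backbone == "GDGT" else f"{code}-{backbone}(36:1)"
        if code == "DPG":
            name = "DPG(64:1)"
        cf = assemble(parse_ipl_name(name))
        total = None
        for part in cf.headgroups + cf.backbones + cf.chains:
            total = part if total is None else total + part
        assert total == cf.full

    def test_gdgt_headgroup_split_position_independent(self):
        two_plus_h = headgroup_formula("2G") + headgroup_formula("H")
        one_plus_one = headgroup_formula("1G") + headgroup_formula("1G")
        assert two_plus_h == one_plus_one == F("C12H22O10")

    def test_ether_for_ester_swap_lowers_full_lipid_zc(self):
        ester = assemble(parse_ipl_name("PI-DAG(32:0)")).full
        ether = assemble(parse_ipl_name("PI-DEG(32:0)")).full
        assert zc(ether) < zc(ester)


from lipidzc.quantify import RfTable  # noqa: E402

_RF_KEYS = sorted(RfTable.default().assignments)
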