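"""Response-factor assignment and mole-fraction normalization."""

import numpy as np
import pandas as pd
import pytest

from lipidzc.quantify import (
    IplRecord,
    RfTable,
    UnassignedResponseFactor,
    assign_response_factor,
    build_records,
    mole_fractions,
    quantify_dataset,
    read_abundance_csv,
)
from lipidzc.lipids import parse_ipl_name


class TestRfAssignment:
    def test_phosphatidylcholine_diacyl_standard(self):
        rft = RfTable.default()
        _, sid = assign_response_factor(parse_ipl_name("PC-DAG(32:0)"), rft)
        assert sid == 3

    @pytest.mark.parametrize("name", ["1G-GDGT(0)", "2G-GDGT(3)", "4G-GDGT(1)"])
    def test_all_tetraethers_share_one_standard(self, name):
        rft = RfTable.default()
        _, sid = assign_response_factor(parse_ipl_name(name), rft)
        assert sid == 2

    @pytest.mark.parametrize(
        "name", ["OL-FA-OH-FAm(32:0)", "TM-KL-FA-OH-FAm(32:0)", "BL-DAG(32:0)"]
    )
    def test_aminolipids_share_the_dgts_standard(self, name):
        rft = RfTable.default()
        _, sid = assign_response_factor(parse_ipl_name(name), rft)
        assert sid == 13

    def test_unlisted_combination_is_an_explicit_error(self):
        rft = RfTable.default()
        with pytest.raises(UnassignedResponseFactor):
            assign_response_factor(parse_ipl_name("PS-DEG(32:0)"), rft)

    def test_calibration_values_override_defaults(self):
        rft = RfTable.default(values={3: 2.5})
        rf, _ = assign_response_factor(parse_ipl_name("PC-DAG(32:0)"), rft)
        assert rf == 2.5
        assert rft.values[1] == 1.0

    def test_nonpositive_slopes_rejected(self):
        with pytest.raises(ValueError):
            RfTable.default(values={1: 0.0})


def _records(rows):
    return build_records(rows)


class TestMoleFractions:
    def test_single_lipid_gets_unit_fraction(self):
        (rec,) = mole_fractions(_records([("A", "PC-DAG(32:0)", 100.0)]))
        assert rec.x == 1.0

    def test_worked_two_lipid_example(self):
        recs = _records(
            [("A", "PC-DAG(32:0)", 1000.0), ("A", "PI-DAG(32:0)", 500.0)]
        )
        recs[0] = IplRecord("A", recs[0].spec, 1000.0, 10.0, 3, 800.0)
        recs[1] = IplRecord("A", recs[1].spec, 500.0, 5.0, 6, 400.0)
        out = mole_fractions(recs)
        assert out[0].x == pytest.approx(1 / 3)
        assert out[1].x == pytest.approx(2 / 3)

    def test_normalization_and_scale_invariance(self):
        rows = [("A", "PC-DAG(32:0)", 120.0), ("A", "1G-GDGT(2)", 45.0),
                ("A", "SQ-DAG(34:1)", 260.0)]
        out = mole_fractions(_records(rows))
        assert sum(r.x for r in out) == pytest.approx(1.0, abs=1e-12)
        scaled = mole_fractions(
            _records([(s, n, 7 * a) for s, n, a in rows])
        )
        for a, b in zip(out, scaled):
            assert a.x == pytest.approx(b.x, rel=1e-12)

    def test_doubling_rf_halves_preweight(self):
        rows = [("A", "PC-DAG(32:0)", 100.0), ("A", "PI-DAG(32:0)", 100.0)]
        base = mole_fractions(build_records(rows))
        boosted = mole_fractions(
            build_records(rows, RfTable.default(values={3: 2.0}))
        )
        ratio_base = base[0].x / base[1].x
        ratio_boost = boosted[0].x / boosted[1].x
        assert ratio_boost == pytest.approx(ratio_base / 2)

    def test_zero_intensity_retained_with_zero_fraction(self):
        out = mole_fractions(
            _records([("A", "PC-DAG(32:0)", 100.0), ("A", "PI-DAG(32:0)", 0.0)])
        )
        assert out[1].x == 0.0

    def test_all_zero_intensities_error(self):
        with pytest.raises(ValueError):
            mole_fractions(_records([("A", "PC-DAG(32:0)", 0.0)]))

    def test_mixed_samples_rejected(self):
        recs = _records([("A", "PC-DAG(32:0)", 1.0), ("B", "PC-DAG(32:0)", 1.0)])
        with pytest.raises(ValueError):
            mole_fractions(recs)

    def test_generated_intensities_round_trip(self):
        # I = x * RF * mi * k inverts exactly through the normalization
        rft = RfTable.default(values={3: 4.0, 6: 0.5})
        x_true = [0.25, 0.75]
        protos = build_records(
            [("A", "PC-DAG(32:0)", 1.0), ("A", "PI-DAG(32:0)", 1.0)], rft
        )
        recs = [
            IplRecord(r.sample_id, r.spec, x * r.rf * r.mi * 1e6,
                      r.rf, r.rf_standard, r.mi)
            for r, x in zip(protos, x_true)
        ]
        out = mole_fractions(recs)
        assert [r.x for r in out] == pytest.approx(x_true, rel=1e-12)


class TestRecordBuilding:
    def test_bad_annotation_reports_row_number(self):
        with pytest.raises(ValueError, match="row 2"):
            build_records(
                [("A", "PC-DAG(32:0)", 1.0), ("A", "NOT-A-LIPID", 1.0)]
            )

    def test_skip_bad_drops_offending_rows(self):
        recs = build_records(
            [("A", "PC-DAG(32:0)", 1.0), ("A", "NOT-A-LIPID", 1.0)],
            skip_bad=True,
        )
        assert len(recs) == 1

    def test_adduct_changes_parent_ion_mass(self):
        (h,) = build_records([("A", "PC-DAG(32:0)", 1.0)], adduct="proton")
        (nh4,) = build_records([("A", "PC-DAG(32:0)", 1.0)], adduct="ammonium")
        assert nh4.mi - h.mi == pytest.approx(17.026549, abs=1e-4)

    def test_quantify_dataset_groups_by_sample(self):
        recs = _records(
            [("A", "PC-DAG(32:0)", 1.0), ("B", "PI-DAG(32:0)", 2.0),
             ("B", "PC-DAG(32:0)", 1.0)]
        )
        q = quantify_dataset(recs)
        assert set(q) == {"A", "B"}
        assert sum(r.x for r in q["B"]) == pytest.approx(1.0)

    def test_read_abundance_csv_requires_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"sample_id": ["A"], "name": ["x"]}).to_csv(p, index=False)
        with pytest.raises(ValueError):
            read_abundance_csv(p)
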