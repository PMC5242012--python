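"""Concentration triage, plate layout and production reports."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venombank.bank_triage import (
    CONTROL_WELLS_PER_PLATE,
    PEPTIDES_PER_PLATE,
    ProductionRecord,
    assign_bin,
    bank_summary,
    layout_plates,
    percent,
    production_report,
    round_half_away,
)


def _decisions(concs):
    return [assign_bin(c, f"p{i}") for i, c in enumerate(concs)]


class TestAssignBin:
    def test_dilution_conserves_moles(self):
        d = assign_bin(25.0)
        assert d.bin == "adjust_to_10"
        assert d.stock_volume_ul == pytest.approx(100.0)
        assert d.water_ul == pytest.approx(150.0)
        assert d.stock_volume_ul * d.conc_um == pytest.approx(250.0 * 10.0)

    @pytest.mark.parametrize(
        "conc, expected",
        [
            (10.0, "bank10_asis"),
            (20.0, "bank10_asis"),  # boundary: exactly 20 stays as-is
            (20.01, "adjust_to_10"),
            (5.0, "bank10_asis"),   # boundary: exactly 5 in the 10 uM bank
            (4.99, "bank1"),
            (1.0, "bank1"),         # boundary: exactly 1 is kept
            (0.5, "discard"),
            (0.0, "discard"),
        ],
    )
    def test_boundary_semantics(self, conc, expected):
        assert assign_bin(conc).bin == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(-1.0)

    @given(st.floats(min_value=0, max_value=500, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_bins_partition_and_moles_never_increase(self, conc):
        d = assign_bin(conc)
        assert d.bin in ("adjust_to_10", "bank10_asis", "bank1", "discard")
        moles_in = conc * 250.0
        moles_out = d.final_conc_um * d.final_volume_ul
        assert moles_out <= moles_in + 1e-9


class TestLayoutPlates:
    def test_160_peptides_fill_two_plates(self):
        plates = layout_plates(_decisions([10.0] * 160))
        assert len(plates) == 2
        for p in plates:
            assert len(p.peptide_wells) == PEPTIDES_PER_PLATE
            controls = [w for w, v in p.wells.items() if v == "CONTROL"]
            assert len(controls) == CONTROL_WELLS_PER_PLATE
            assert all(w[1:] in ("1", "12") for w in controls)

    def test_library_bank_plate_counts(self):
        # 2174 in the 10 uM bank -> 28 plates; 562 in the 1 uM bank -> 8
        decisions = _decisions([25.0] * 1363 + [10.0] * 811 + [2.0] * 562)
        plates = layout_plates(decisions)
        assert sum(p.bank == "bank10" for p in plates) == 28
        assert sum(p.bank == "bank1" for p in plates) == 8

    def test_no_duplicates_and_complete_accounting(self):
        decisions = _decisions([30.0] * 85 + [3.0] * 10)
        plates = layout_plates(decisions)
        seen = [p.wells[w] for p in plates for w in p.peptide_wells]
        assert len(seen) == len(set(seen)) == 95

    def test_discards_cannot_be_plated(self):
        with pytest.raises(ValueError):
            layout_plates(_decisions([0.2]))

    def test_copy_feasibility(self):
        plate = layout_plates(_decisions([10.0] * 5))[0]
        assert plate.copy_count * plate.aliquot_ul <= 250.0


class TestBankSummary:
    def test_library_percentages(self):
        decisions = _decisions([25.0] * 1363 + [10.0] * 811 + [2.0] * 562)
        summary = bank_summary(decisions)
        assert summary["bank10"] == 2174
        assert summary["above_20_percent_of_bank10"] == 63
        assert summary["bank10_percent_of_produced"] == 79  # prints as ~80
        assert summary["bank1_percent_of_produced"] == 21  # prints as ~20

    def test_empty_input_all_zero(self):
        summary = bank_summary([])
        assert summary["total"] == 0
        assert all(v == 0 for v in summary["counts"].values())


class TestRounding:
    @pytest.mark.parametrize("x, expected", [(0.5, 1), (62.7, 63), (54.5, 55),
                                             (54.49, 54), (-0.5, -1)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected

    def test_percent_decimals(self):
        assert percent(3818, 4992, decimals=1) == 76.5
        assert percent(2736, 4992) == 55


def _records(n, produced, **kw):
    defaults = dict(taxon="spider", length=50, n_bridges_max=3,
                    odd_cysteines=False, pattern="C-C-CC-C-C", nterm="G")
    defaults.update(kw)
    return [ProductionRecord(peptide_id=f"r{i}{kw}{produced}", produced=produced,
                             conc_um=10.0 if produced else 0.0, **defaults)
            for i in range(n)]


class TestProductionReport:
    def test_one_bridge_success_rate(self):
        records = (_records(11, True, n_bridges_max=1)
                   + _records(28, False, n_bridges_max=1)
                   + _records(5, True, n_bridges_max=3))
        table = production_report(records, "n_bridges")
        row = table[table.group == 1].iloc[0]
        assert row.n == 39
        assert row.n_produced == 11
        assert row.success_pct == 28

    def test_snake_success_rate(self):
        records = (_records(34, True, taxon="snake")
                   + _records(66, False, taxon="snake")
                   + _records(10, True, taxon="spider"))
        table = production_report(records, "taxon")
        row = table[table.group == "snake"].iloc[0]
        assert row.success_pct == 34

    def test_all_produced_gives_100_everywhere(self):
        records = _records(5, True, taxon="spider") + _records(
            3, True, taxon="scorpion")
        table = production_report(records, "taxon")
        assert (table.success_pct == 100).all()

    def test_groups_ordered_by_size_descending(self):
        records = (_records(3, True, nterm="L") + _records(7, True, nterm="E")
                   + _records(5, False, nterm="G"))
        table = production_report(records, "nterm")
        assert list(table.group) == ["E", "G", "L"]

    def test_unknown_group_key_rejected(self):
        with pytest.raises(ValueError):
            production_report(_records(1, True), "color")

    def test_length_class_grouping(self):
        records = _records(4, True, length=40) + _records(2, False, length=110)
        table = production_report(records, "length_class")
        assert set(table.group) == {"35-49", "100-120"}
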