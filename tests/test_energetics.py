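"""Pyrophosphate budget, ATP accounting and the lysis calculation."""

import pytest
from hypothesis import given, settings, strategies as st

from ppiflux.energetics import (
    ANABOLIC_PPI_SOURCES,
    EnergeticsDefaults,
    anabolic_ppi_total,
    atp_requirement_with_ppi_credit,
    catabolic_ppi_demand,
    cellobiose_partition,
    lysis_implied_concentration,
    lysis_required_cell_mass,
    protein_atp_saving,
)


class TestAnabolicPPi:
    def test_macromolecule_defaults_sum_to_11(self):
        total = anabolic_ppi_total()
        assert total == pytest.approx(10.97, abs=1e-9)
        assert round(total) == 11

    def test_zero_and_single_component(self):
        assert anabolic_ppi_total({}) == 0.0
        assert anabolic_ppi_total({"protein": 7.67}) == 7.67

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            anabolic_ppi_total({"protein": -1.0})


class TestCellobiosePartition:
    def test_reference_partition(self):
        part = cellobiose_partition(0.16, 3.7, 0.16)
        assert part.total == pytest.approx(18.26, abs=0.01)  # 1 g cells / ~18.2 mmol
        assert part.catabolic == pytest.approx(11.64, abs=0.01)

    def test_no_sinks_means_all_catabolic(self):
        part = cellobiose_partition(0.16, 0.0, 0.0)
        assert part.catabolic == part.total

    def test_unaccounted_fraction_from_carbon_recovery(self):
        # 100 - 84.0 % recovery -> 0.16 unaccounted
        fraction = (100.0 - 84.0) / 100.0
        part = cellobiose_partition(0.16, 3.7, fraction)
        assert part.unaccounted == pytest.approx(0.16 * part.total)

    def test_infeasible_partition_rejected(self):
        with pytest.raises(ValueError):
            cellobiose_partition(0.16, 20.0, 0.16)  # anabolic exceeds total
        with pytest.raises(ValueError):
            cellobiose_partition(0.0)


class TestCatabolicDemand:
    def test_published_demand_with_printed_rounding(self):
        part = cellobiose_partition(0.16, 3.7, 0.16)
        budget = catabolic_ppi_demand(part, ppdk_fraction=2 / 3, quantize=True)
        assert budget.catabolic_pfk == pytest.approx(23.2, abs=1e-9)
        assert budget.catabolic_ppdk == pytest.approx(30.9, abs=1e-9)
        assert budget.catabolic_total == pytest.approx(54.1, abs=1e-9)

    def test_exact_demand_close_to_published(self):
        part = cellobiose_partition(0.16, 3.7, 0.16)
        budget = catabolic_ppi_demand(part, ppdk_fraction=2 / 3)
        assert budget.catabolic_total == pytest.approx(54.3, abs=0.05)

    def test_fraction_limits(self):
        part = cellobiose_partition(0.16, 3.7, 0.16)
        none = catabolic_ppi_demand(part, ppdk_fraction=0.0)
        assert none.catabolic_ppdk == 0.0
        assert none.catabolic_total == none.catabolic_pfk
        full = catabolic_ppi_demand(part, ppdk_fraction=1.0)
        assert full.catabolic_ppdk == pytest.approx(4.0 * part.catabolic)

    def test_anabolic_supply_below_catabolic_demand(self):
        """The budget's central imbalance: ~11 mmol anabolic PP_i cannot
        cover ~54 mmol catabolic demand."""
        part = cellobiose_partition()
        budget = catabolic_ppi_demand(part)
        assert budget.anabolic_total < budget.catabolic_total
        assert budget.anabolic_total == pytest.approx(10.97, abs=0.01)
        assert budget.deficit > 40

    @settings(derandomize=True, max_examples=40)
    @given(
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
        scale=st.floats(0.1, 3),
    )
    def test_monotone_in_ppdk_fraction_linear_in_catabolic(self, f1, f2, scale):
        part = cellobiose_partition(0.16, 3.7, 0.16)
        lo, hi = sorted([f1, f2])
        assert (
            catabolic_ppi_demand(part, lo).catabolic_total
            <= catabolic_ppi_demand(part, hi).catabolic_total + 1e-12
        )
        # linearity: scaling catabolic cellobiose scales the demand
        scaled = cellobiose_partition(0.16 / scale, 3.7 * scale, 0.16)
        d1 = catabolic_ppi_demand(part, f1)
        d2 = catabolic_ppi_demand(scaled, f1)
        assert d2.catabolic_total == pytest.approx(
            d1.catabolic_total / part.catabolic * scaled.catabolic, rel=1e-9, abs=1e-9
        )


class TestATPAccounting:
    def test_published_y_atp_values(self):
        acc = atp_requirement_with_ppi_credit(34.7, 11.0)
        assert acc.adjusted_requirement == pytest.approx(23.7)
        assert round(acc.y_atp_max, 1) == 42.2
        assert round(acc.y_atp_base, 1) == 28.8

    def test_no_credit_keeps_baseline(self):
        acc = atp_requirement_with_ppi_credit(34.7, 0.0)
        assert acc.y_atp_max == acc.y_atp_base

    @settings(derandomize=True, max_examples=40)
    @given(base=st.floats(5, 100))
    def test_half_credit_doubles_y_atp_max(self, base):
        acc = atp_requirement_with_ppi_credit(base, base / 2)
        assert acc.y_atp_max == pytest.approx(2 * acc.y_atp_base, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(base=st.floats(5, 100), frac=st.floats(0, 0.95))
    def test_product_identity(self, base, frac):
        acc = atp_requirement_with_ppi_credit(base, base * frac)
        assert acc.y_atp_max * acc.adjusted_requirement == pytest.approx(1000.0, rel=1e-12)

    def test_credit_exceeding_base_rejected(self):
        with pytest.raises(ValueError):
            atp_requirement_with_ppi_credit(34.7, 40.0)


class TestProteinATPSaving:
    def test_published_saving(self):
        assert protein_atp_saving() == 14
        # intermediate: 0.524 g protein / 110 g/mol -> ~4.8 mmol residues
        residues = 1000 * 0.524 / 110
        assert residues == pytest.approx(4.8, abs=0.05)

    def test_no_protein_no_saving(self):
        with pytest.raises(ValueError):
            protein_atp_saving(protein_fraction=0.0)
        assert protein_atp_saving(protein_fraction=1e-9, rounded=False) < 1e-6


class TestLysis:
    def test_required_cell_mass(self):
        assert round(lysis_required_cell_mass(100.0, 0.6)) == 167
        assert lysis_required_cell_mass(100.0, 1.0) == 100.0
        assert lysis_required_cell_mass(0.0, 0.6) == 0.0

    def test_implied_concentration_default_volume(self):
        # 0.9 mmol amino acids from 167 mg cells at 2 ml/g -> ~2.7 M
        conc = lysis_implied_concentration(100.0, 111.0, 0.6, 2.0)
        assert conc == pytest.approx(2.7, abs=0.01)

    def test_invariance_to_amino_acid_amount(self):
        # numerator and lysed volume scale together
        assert lysis_implied_concentration(50.0) == pytest.approx(
            lysis_implied_concentration(100.0), rel=1e-12
        )

    def test_inverse_scaling_with_cell_volume(self):
        at_2 = lysis_implied_concentration(specific_cell_volume=2.0)
        at_4 = lysis_implied_concentration(specific_cell_volume=4.0)
        assert at_4 == pytest.approx(at_2 / 2, rel=1e-12)


class TestDefaults:
    def test_packaged_defaults_file_round_trips(self):
        from importlib import resources

        with resources.as_file(
            resources.files("ppiflux.data").joinpath("energetics_defaults.yaml")
        ) as p:
            d = EnergeticsDefaults.from_yaml(p)
        assert d == EnergeticsDefaults()

    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("biomass_yield: 0.2\nnot_a_knob: 1\n")
        with pytest.raises(ValueError):
            EnergeticsDefaults.from_yaml(bad)

    def test_replace_overrides_one_constant(self):
        d = EnergeticsDefaults().replace(ppdk_fraction=0.5)
        assert d.ppdk_fraction == 0.5
        assert d.base_atp_requirement == 34.7
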