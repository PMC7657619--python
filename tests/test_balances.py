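"""CO2 inference and carbon/nitrogen balance closure."""

import pytest
from hypothesis import given, settings, strategies as st

from ppiflux import balances, io, synthetic
from ppiflux.balances import BalanceInconsistencyError
from ppiflux.registry import AminoAcidProfile, ChemostatCondition, ProteinComposition


def _condition(products, **kw):
    kw.setdefault("feed", {"cellobiose": 5000.0})
    return ChemostatCondition(products=products, **kw)


class TestInferCO2:
    def test_published_values(self, ct_condition, ts_condition):
        assert balances.infer_co2(ct_condition) == pytest.approx(1254.0, rel=5e-4)
        assert balances.infer_co2(ts_condition) == pytest.approx(1815.9, rel=5e-4)

    def test_all_zero_condition_gives_zero(self):
        cond = _condition({"acetate": 0.0, "ethanol": 0.0, "formate": 0.0})
        assert balances.infer_co2(cond) == 0.0

    def test_valine_flag_adds_one_mole_per_valine(self, registry):
        cond = _condition(
            {"acetate": 0.0, "ethanol": 0.0, "formate": 0.0},
            amino_acids=AminoAcidProfile({"valine": 117.148}),
        )
        with_val = balances.infer_co2(cond, include_valine=True)
        # one mmol valine -> one mmol CO2
        assert with_val == pytest.approx(44.009, abs=0.01)
        assert balances.infer_co2(cond, include_valine=False) == 0.0

    def test_excess_formate_raises(self):
        cond = _condition({"acetate": 10.0, "ethanol": 0.0, "formate": 500.0})
        with pytest.raises(BalanceInconsistencyError):
            balances.infer_co2(cond)

    @settings(derandomize=True, max_examples=40)
    @given(
        base=st.floats(10, 2000),
        scale=st.floats(0.1, 5),
        species=st.sampled_from(["acetate", "ethanol", "isobutanol"]),
    )
    def test_linearity_in_each_product(self, base, scale, species):
        """Scaling one product's concentration scales its CO2 contribution."""

        def products(extra):
            table = {"acetate": 100.0, "ethanol": 100.0}
            table[species] = table.get(species, 0.0) + extra
            return table

        cond0 = _condition(products(0.0))
        cond1 = _condition(products(base))
        cond2 = _condition(products(base * scale))
        baseline = balances.infer_co2(cond0)
        d1 = balances.infer_co2(cond1) - baseline
        d2 = balances.infer_co2(cond2) - baseline
        assert d2 == pytest.approx(d1 * scale, rel=1e-9)


class TestCarbonRecovery:
    def test_published_recoveries(self, ct_condition, ts_condition):
        rct = balances.carbon_recovery(ct_condition)
        rts = balances.carbon_recovery(ts_condition)
        assert round(rct.carbon_recovery, 1) == 84.0
        assert round(rts.carbon_recovery, 1) == 88.8
        assert rct.amino_acid_carbon_source == "declared"

    def test_recovery_identity(self, ct_condition):
        report = balances.carbon_recovery(ct_condition)
        assert report.carbon_recovery == pytest.approx(
            100.0 * report.carbon_out / report.carbon_in, rel=1e-12
        )
        assert all(v >= 0 for v in report.carbon_out_by_component.values())

    def test_closed_synthetic_balance_is_100(self):
        spec = synthetic.GeneratorSpec(noise_cv=0.0, missing_carbon_fraction=0.0)
        conds, _ = synthetic.generate(spec)
        report = balances.carbon_recovery(conds[0], convention=spec.convention)
        assert report.carbon_recovery == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("missing", [0.05, 0.16, 0.4])
    def test_missing_fraction_maps_to_recovery(self, missing):
        spec = synthetic.GeneratorSpec(noise_cv=0.0, missing_carbon_fraction=missing)
        conds, _ = synthetic.generate(spec)
        report = balances.carbon_recovery(conds[0], convention=spec.convention)
        assert report.carbon_recovery == pytest.approx(100.0 * (1 - missing), abs=0.1)

    def test_recovery_invariant_to_split_product_rows(self, tmp_path, ct_condition):
        # writing acetate as two rows that sum to the original leaves
        # the closure unchanged (the reader merges duplicates)
        path = tmp_path / "split.csv"
        text = io._data_path("table1_cthermocellum.csv").read_text()
        split = text.replace(
            "acetate,1062.4,product", "acetate,1000.0,product\nacetate,62.4,product"
        )
        path.write_text(split)
        merged = io.read_condition(path)
        r0 = balances.carbon_recovery(ct_condition)
        r1 = balances.carbon_recovery(merged)
        assert r1.carbon_recovery == pytest.approx(r0.carbon_recovery, rel=1e-12)

    def test_zero_feed_carbon_rejected(self):
        cond = ChemostatCondition(products={"acetate": 10.0, "ethanol": 0.0})
        with pytest.raises(ValueError):
            balances.carbon_recovery(cond)

    def test_report_serializations(self, ct_condition):
        report = balances.carbon_recovery(ct_condition, include_nitrogen=True)
        d = report.to_dict()
        assert d["carbon_recovery_percent"] == 84.0
        assert d["mass_convention"] == "anion"
        text = report.to_text()
        assert "recovery" in text and "84.0" in text


class TestNitrogenRecovery:
    def test_all_feed_nitrogen_in_cells_is_100(self, registry):
        # urea feed: 2 N per ~60.06 g/mol -> ~466 mg N/liter
        feed_n = 1000.0 * registry.nitrogen_fraction("urea")
        cond = ChemostatCondition(feed={"urea": 1000.0}, cell_nitrogen=feed_n)
        assert balances.nitrogen_recovery(cond) == pytest.approx(100.0, abs=1e-9)

    def test_half_feed_nitrogen_gives_50(self, registry):
        feed_n = 1000.0 * registry.nitrogen_fraction("urea")
        cond = ChemostatCondition(feed={"urea": 1000.0}, cell_nitrogen=feed_n / 2)
        assert balances.nitrogen_recovery(cond) == pytest.approx(50.0, abs=1e-9)

    def test_reference_condition_matches_hand_summation(self, ct_condition, registry):
        # (cell N + declared aa N + protein x 0.161) / feed N x 100
        feed_n = 2000.0 * registry.nitrogen_fraction("ammonium_chloride")
        expected = 100.0 * (102.0 + 20.6 + 103.5 * 0.161) / feed_n
        assert balances.nitrogen_recovery(ct_condition) == pytest.approx(
            expected, rel=1e-6
        )

    def test_zero_feed_nitrogen_rejected(self):
        cond = ChemostatCondition(feed={"cellobiose": 5000.0}, cell_nitrogen=100.0)
        with pytest.raises(ValueError):
            balances.nitrogen_recovery(cond)


class TestCNRatio:
    def test_reference_value(self, ct_condition):
        assert balances.cn_ratio(ct_condition) == pytest.approx(3.31, abs=0.005)

    def test_symmetry(self):
        cond = ChemostatCondition(cell_carbon=123.4, cell_nitrogen=123.4)
        assert balances.cn_ratio(cond) == 1.0

    def test_zero_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            balances.cn_ratio(ChemostatCondition(cell_carbon=1.0, cell_nitrogen=0.0))

    def test_regression_over_synthetic_series_recovers_slope_ratio(self):
        """Biomass series at several feed levels: the fitted C-vs-N slope
        ratio equals the generator's C/N ratio."""
        import numpy as np

        cn = 3.34
        levels = np.array([20.0, 40.0, 60.0, 80.0, 102.0])
        carbons = []
        for x_n in levels:
            spec = synthetic.GeneratorSpec(
                cell_nitrogen=float(x_n), cell_cn_ratio=cn, noise_cv=0.0
            )
            conds, _ = synthetic.generate(spec)
            carbons.append(conds[0].cell_carbon)
        slope_c = np.polyfit(levels, carbons, 1)[0]
        slope_n = np.polyfit(levels, levels, 1)[0]
        assert slope_c / slope_n == pytest.approx(cn, rel=1e-9)
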