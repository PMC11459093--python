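import numpy as np
import pandas as pd
import pytest

from chronophylo.biomass import (
    HERB_BOX_AREA_M2,
    LITTER_BOX_AREA_M2,
    AllometricModel,
    AllometryRegistry,
    HarvestSample,
    agb_table,
    density_from_boxes,
    individual_biomass,
    plot_agb,
)


@pytest.fixture
def registry():
    return AllometryRegistry([
        AllometricModel("default_woody", "power_d", 0.1, 2.4),
        AllometricModel("Pinus_demo", "power_d", 0.05, 2.5, "stem"),
        AllometricModel("Pinus_demo", "power_d", 0.02, 2.5, "branch"),
        AllometricModel("Quercus", "power_d2h", 0.05, 0.9),
    ])


class TestHarvestDensity:
    def test_mean_of_three_herb_boxes(self):
        boxes = [HarvestSample("p", "herb", m, HERB_BOX_AREA_M2) for m in (100, 120, 140)]
        assert density_from_boxes(boxes) == pytest.approx(120.0)

    def test_litter_box_area_conversion(self):
        box = HarvestSample("p", "litter", 10.0, LITTER_BOX_AREA_M2)
        assert density_from_boxes([box]) == pytest.approx(10 / 0.317**2, rel=1e-9)
        assert density_from_boxes([box]) == pytest.approx(99.51, abs=0.01)

    def test_empty_boxes_give_zero(self):
        boxes = [HarvestSample("p", "herb", 0.0, 1.0)] * 3
        assert density_from_boxes(boxes) == 0.0

    def test_mixed_kinds_rejected(self):
        boxes = [HarvestSample("p", "herb", 1, 1.0), HarvestSample("p", "litter", 1, 0.1)]
        with pytest.raises(ValueError, match="mixed"):
            density_from_boxes(boxes)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            HarvestSample("p", "herb", 1.0, 0.0)


class TestAllometry:
    def test_power_d_hand_value(self):
        m = AllometricModel("x", "power_d", 0.1, 2.4)
        assert m.predict(10.0) == pytest.approx(0.1 * 10**2.4)
        assert m.predict(10.0) == pytest.approx(25.12, abs=0.01)

    def test_d2h_hand_value(self):
        m = AllometricModel("x", "power_d2h", 0.05, 0.9)
        assert m.predict(10.0, 8.0) == pytest.approx(0.05 * 800**0.9)
        assert m.predict(10.0, 8.0) == pytest.approx(20.50, abs=0.01)

    def test_log_power_form(self):
        m = AllometricModel("x", "log_power", -2.0, 2.3)
        assert m.predict(5.0) == pytest.approx(np.exp(-2.0) * 5**2.3)

    def test_biomass_vanishes_with_diameter(self):
        m = AllometricModel("x", "power_d", 0.1, 2.4)
        assert m.predict(1e-6) < 1e-10

    def test_missing_height_rejected(self):
        m = AllometricModel("x", "power_d2h", 0.05, 0.9)
        with pytest.raises(ValueError, match="height"):
            m.predict(10.0)

    def test_components_summed(self, registry):
        total = registry.biomass("Pinus_demo", 10.0)
        assert total == pytest.approx((0.05 + 0.02) * 10**2.5)

    def test_fallback_chain_species_genus_default(self, registry):
        # unknown species of a known genus -> genus model
        v = registry.biomass("Quercus_mongolica", 10.0, H=8.0)
        assert v == pytest.approx(0.05 * 800**0.9)
        # unknown genus -> life-form default
        v = registry.biomass("Betula_platyphylla", 10.0)
        assert v == pytest.approx(0.1 * 10**2.4)

    def test_unknown_taxon_without_default_named_in_error(self):
        reg = AllometryRegistry([AllometricModel("OnlyThis", "power_d", 1, 1)])
        with pytest.raises(KeyError, match="Missing_taxon"):
            reg.biomass("Missing_taxon", 5.0)

    def test_registry_csv_round_trip(self, registry, tmp_path):
        path = tmp_path / "reg.csv"
        registry.to_frame().to_csv(path, index=False)
        again = AllometryRegistry.read_csv(path)
        assert again.biomass("Pinus_demo", 7.0) == pytest.approx(
            registry.biomass("Pinus_demo", 7.0))


class TestPlotAGB:
    def test_composed_worked_example(self, registry):
        """Two 25.12 kg trees on 400 m2 + herb 120 + litter 99.51 g/m2."""
        stems = pd.DataFrame({"plot_id": ["p"] * 2, "species": ["u1", "u2"],
                              "dbh_cm": [10.0, 10.0]})
        harvest = (
            [HarvestSample("p", "herb", m, 1.0) for m in (100, 120, 140)]
            + [HarvestSample("p", "litter", 10.0, LITTER_BOX_AREA_M2)]
        )
        rec = plot_agb("p", stems, harvest, registry, 400.0)
        assert rec.woody_density == pytest.approx(2 * 25.11886 * 1000 / 400, abs=0.01)
        assert rec.total_agb == pytest.approx(125.59 + 120 + 99.51, abs=0.05)
        assert rec.total_agb == rec.herb_density + rec.woody_density + rec.litter_density

    def test_farmland_plot_total_is_herb_density(self, registry):
        harvest = [HarvestSample("p", "herb", 80.0, 1.0)]
        rec = plot_agb("p", None, harvest, registry, 1.0)
        assert rec.total_agb == pytest.approx(80.0)

    def test_empty_plot_warns_and_zero(self, registry, caplog):
        with caplog.at_level("WARNING"):
            rec = plot_agb("p", None, [], registry, 1.0)
        assert rec.total_agb == 0.0
        assert any("zero aboveground biomass" in r.message for r in caplog.records)

    def test_doubling_stems_doubles_woody_density(self, registry):
        stems = pd.DataFrame({"plot_id": ["p"] * 3, "species": ["a", "b", "c"],
                              "dbh_cm": [5.0, 8.0, 12.0]})
        rec1 = plot_agb("p", stems, [], registry, 100.0)
        rec2 = plot_agb("p", pd.concat([stems, stems]), [], registry, 100.0)
        assert rec2.woody_density == pytest.approx(2 * rec1.woody_density, rel=1e-12)

    def test_order_invariance(self, registry):
        stems = pd.DataFrame({"plot_id": ["p"] * 4, "species": list("abcd"),
                              "dbh_cm": [5.0, 8.0, 12.0, 3.0]})
        boxes = [HarvestSample("p", "herb", m, 1.0) for m in (50, 70, 90)]
        a = plot_agb("p", stems, boxes, registry, 100.0)
        b = plot_agb("p", stems.iloc[::-1], list(reversed(boxes)), registry, 100.0)
        assert a.total_agb == pytest.approx(b.total_agb, rel=1e-12)

    def test_unit_round_trip_kg_per_ha(self, registry):
        """g/m2 -> kg/ha x10; converting back agrees to 1e-9 relative."""
        stems = pd.DataFrame({"plot_id": ["p"], "species": ["x"], "dbh_cm": [15.0]})
        rec = plot_agb("p", stems, [], registry, 250.0)
        kg_ha = rec.woody_density * 10.0
        assert kg_ha / 10.0 == pytest.approx(rec.woody_density, rel=1e-9)

    def test_negative_diameter_rejected(self, registry):
        stems = pd.DataFrame({"plot_id": ["p"], "species": ["x"], "dbh_cm": [-1.0]})
        with pytest.raises(ValueError, match="diameter"):
            plot_agb("p", stems, [], registry, 10.0)

    def test_agb_table_additivity(self, registry):
        plots = pd.DataFrame({"plot_id": ["p1", "p2"], "stage_years": [0, 40],
                              "plot_area_m2": [1.0, 100.0]})
        harvest = pd.DataFrame({
            "plot_id": ["p1"] * 3 + ["p2"] * 3,
            "kind": ["herb"] * 3 + ["litter"] * 3,
            "dry_mass_g": [100, 110, 90, 5, 6, 7],
            "box_area_m2": [1.0] * 3 + [LITTER_BOX_AREA_M2] * 3,
        })
        stems = pd.DataFrame({"plot_id": ["p2"] * 2, "species": ["s", "s"],
                              "dbh_cm": [6.0, 9.0]})
        out = agb_table(stems, harvest, registry, plots)
        assert len(out) == 2
        assert np.allclose(
            out["total_agb"],
            out[["herb_density", "woody_density", "litter_density"]].sum(axis=1),
        )
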