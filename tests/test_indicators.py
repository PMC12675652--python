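import math

import numpy as np
import pytest

from asymweb.asymmetry import AsymmetryGraph
from asymweb.indicators import (
    INDICATOR_COLUMNS,
    analyze_web,
    asymgraph_indicators,
    combined_ratios,
    foodweb_indicators,
    indicator_table,
    nonnetwork_indicators,
)
from asymweb.io import FoodWeb
from asymweb.synthgen import synthetic_collection
from asymweb.trophic import LinkClassification, trophic_levels


class TestFoodwebIndicators:
    def test_complete_graph(self, webs):
        out = foodweb_indicators(webs["complete-4"], None)
        assert out["Cfw"] == pytest.approx(1.0)
        assert out["Tfw"] == pytest.approx(1.0)
        assert out["avDISTfw"] == pytest.approx(1.0)

    def test_path_distances_and_transitivity(self, webs):
        out = foodweb_indicators(webs["path-3"], None)
        assert out["avDISTfw"] == pytest.approx(4 / 3)
        assert out["Tfw"] == 0.0

    def test_chain_trophic_summaries(self, webs):
        web = webs["chain-PHC"]
        out = foodweb_indicators(web, trophic_levels(web))
        assert out["avTLfw"] == pytest.approx(2.0)
        assert out["maxTLfw"] == pytest.approx(3.0)
        assert out["carn_ratio"] == pytest.approx(1 / 3)  # exact herbivores excluded

    def test_disconnected_pairs_excluded_from_distance(self):
        web = FoodWeb.from_edges("w", [("A", "B"), ("C", "D")])
        out = foodweb_indicators(web, None)
        assert out["avDISTfw"] == pytest.approx(1.0)

    def test_single_node_rejected(self):
        web = FoodWeb(web_id="w", nodes=["A"], undirected_edges=set())
        with pytest.raises(ValueError):
            foodweb_indicators(web, None)


class TestAsymgraphIndicators:
    def test_fork_counts(self):
        ag = AsymmetryGraph(["X", "Y", "Z"], [("X", "Y", 0.2), ("X", "Z", 0.1)], 0.01, 2)
        classes = LinkClassification(
            classes=[("X", "Y", "bottom-up"), ("X", "Z", "top-down")],
            bu_count=1,
            td_count=1,
            lateral_count=0,
        )
        out = asymgraph_indicators(ag, classes)
        assert out["Nag"] == 3 and out["Lag"] == 2 and out["COMPag"] == 1
        assert out["Nsoag"] == 1 and out["Nsiag"] == 2
        assert out["td_bu_ratio"] == pytest.approx(1.0)

    def test_empty_graph_all_zero_ratio_missing(self):
        ag = AsymmetryGraph([], [], 0.01, 1)
        classes = LinkClassification([], 0, 0, 0)
        out = asymgraph_indicators(ag, classes)
        assert out["Nag"] == out["Lag"] == out["COMPag"] == 0
        assert math.isnan(out["td_bu_ratio"])

    def test_ratio_missing_when_no_bottom_up(self):
        ag = AsymmetryGraph(["X", "Y"], [("X", "Y", 0.2)], 0.01, 1)
        classes = LinkClassification([("X", "Y", "top-down")], 0, 1, 0)
        assert math.isnan(asymgraph_indicators(ag, classes)["td_bu_ratio"])


class TestCombinedAndNonNetwork:
    def test_combined_ratios(self):
        out = combined_ratios({"Nfw": 67.0, "Lfw": 708.0}, {"Nag": 26.0, "Lag": 22.0})
        assert out["Nag_over_Nfw"] == pytest.approx(26 / 67)
        assert out["Lag_over_Lfw"] == pytest.approx(22 / 708)

    def test_empty_asymmetry_graph_ratios_zero(self):
        out = combined_ratios({"Nfw": 10.0, "Lfw": 12.0}, {"Nag": 0.0, "Lag": 0.0})
        assert out["Nag_over_Nfw"] == 0.0 and out["Lag_over_Lfw"] == 0.0

    def test_shannon_and_total_biomass(self):
        web = FoodWeb.from_edges("w", [("A", "B")]).with_attributes(
            {"A": {"biomass": 2.0}, "B": {"biomass": 3.0}}
        )
        out = nonnetwork_indicators(web)
        assert out["TB"] == pytest.approx(5.0)
        assert out["Sh"] == pytest.approx(-(0.4 * np.log(0.4) + 0.6 * np.log(0.6)))

    def test_equal_biomass_maximizes_shannon(self):
        web = FoodWeb.from_edges("w", [("A", "B"), ("B", "C")]).with_attributes(
            {n: {"biomass": 7.0} for n in "ABC"}
        )
        assert nonnetwork_indicators(web)["Sh"] == pytest.approx(np.log(3))

    def test_unrealistic_ee_omitted(self, caplog):
        web = FoodWeb.from_edges("w", [("A", "B"), ("B", "C")]).with_attributes(
            {"A": {"ee": 0.5}, "B": {"ee": 1.7}, "C": {"ee": 0.3}}
        )
        with caplog.at_level("INFO"):
            out = nonnetwork_indicators(web)
        assert out["EE"] == pytest.approx(0.4)
        assert "1.7" in caplog.text

    def test_missing_attributes_yield_missing_values(self, webs):
        out = nonnetwork_indicators(webs["path-3"])
        assert math.isnan(out["Sh"]) and math.isnan(out["TB"]) and math.isnan(out["EE"])


@pytest.fixture(scope="module")
def collection():
    return synthetic_collection(n_webs=3, seed=11, n_species_range=(20, 30))


class TestIndicatorTable:
    def test_shape_and_column_order(self, collection):
        table = indicator_table(collection)
        assert list(table.columns) == ["web_id"] + INDICATOR_COLUMNS
        assert len(table) == 3
        assert len(INDICATOR_COLUMNS) == 21

    def test_deterministic(self, collection):
        t1 = indicator_table(collection)
        t2 = indicator_table(collection)
        assert t1.equals(t2)

    def test_invariants_hold(self, collection):
        table = indicator_table(collection)
        assert ((table["Cfw"] >= 0) & (table["Cfw"] <= 1)).all()
        assert ((table["Tfw"] >= 0) & (table["Tfw"] <= 1)).all()
        assert (table["Nag"] <= table["Nfw"]).all()
        assert (table["BUag"] + table["TDag"] <= table["Lag"]).all()

    def test_web_without_attributes_gets_missing_cells(self, webs):
        table = indicator_table([webs["toy-8"]])
        row = table.iloc[0]
        assert math.isnan(row["Sh"]) and math.isnan(row["TB"]) and math.isnan(row["EE"])
        assert row["Nfw"] == 8 and row["Lfw"] == 9

    def test_failing_web_recorded_and_batch_continues(self, webs):
        bad = FoodWeb(web_id="bad", nodes=["A"], undirected_edges=set())
        table = indicator_table([bad, webs["toy-8"]])
        assert len(table) == 2
        assert math.isnan(table.iloc[0]["Nfw"])
        assert table.iloc[1]["Nfw"] == 8

    def test_relabeling_invariance(self, webs):
        web = webs["toy-8"]
        mapping = {n: f"sp_{n.lower()}" for n in web.nodes}
        relabeled = FoodWeb.from_edges(
            "relabeled",
            [(mapping[u], mapping[v]) for u, v in web.trophic_edges],
            directed=True,
        )
        a = analyze_web(web)
        b = analyze_web(relabeled)
        for key in INDICATOR_COLUMNS:
            if math.isnan(a[key]) and math.isnan(b[key]):
                continue
            assert a[key] == pytest.approx(b[key]), key
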