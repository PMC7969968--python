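"""Sign-consistency mapping, activity tallies, and the change graph."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonpulse.diffexpr import DEGSet
from regulonpulse.errors import UsageError
from regulonpulse.formats import RegulatoryNetwork
from regulonpulse.trnmap import activity_counts, build_graph, map_degs


def degset(up=(), down=()):
    return DEGSet("amp", "stat", frozenset(up), frozenset(down), 2.0, 0.1)


class TestMapDegs:
    def test_up_gene_with_two_sigmas_yields_two_records(self, tiny_network):
        recs = map_degs(degset(up=["g1"]), tiny_network)
        sigma = [r for r in recs if r.reg_class == "sigma"]
        assert {r.regulator for r in sigma} == {"RpoD", "RpoS"}

    def test_strict_rule_decision_table(self, tiny_network):
        # down gene + activator-only edges -> nothing (no derepression)
        assert map_degs(degset(down=["g1"]), tiny_network) == []
        # down gene + repressor TF edge -> exactly that record
        recs = map_degs(degset(down=["g3"]), tiny_network)
        assert [(r.regulator, r.direction) for r in recs] == [("Fur", "down")]
        # dual edges map either direction
        up = {r.regulator for r in map_degs(degset(up=["g2"]), tiny_network)}
        down = {r.regulator for r in map_degs(degset(down=["g2"]), tiny_network)}
        assert "OxyR" in up and "OxyR" in down

    def test_unknown_mode_maps_both_directions_with_warning(self, tiny_network, caplog):
        with caplog.at_level("WARNING"):
            up = map_degs(degset(up=["g4"]), tiny_network)
        assert ("IscR", "up") in [(r.regulator, r.direction) for r in up]
        assert "unknown-mode" in caplog.text
        down = map_degs(degset(down=["g4"]), tiny_network)
        assert ("IscR", "down") in [(r.regulator, r.direction) for r in down]

    def test_strict_records_subset_of_permissive(self, tiny_network):
        degs = degset(up=["g1", "g2"], down=["g3", "g4"])
        strict = set(map_degs(degs, tiny_network, "strict"))
        permissive = set(map_degs(degs, tiny_network, "permissive"))
        assert strict <= permissive

    def test_genes_absent_from_network_reported_not_fatal(self, tiny_network, caplog):
        with caplog.at_level("INFO"):
            recs = map_degs(degset(up=["ghost"]), tiny_network)
        assert recs == []
        assert "no regulator" in caplog.text

    def test_empty_network_is_an_error(self, tiny_degs):
        empty = RegulatoryNetwork(
            pd.DataFrame(columns=["regulator", "reg_class", "target", "mode"])
        )
        with pytest.raises(UsageError, match="empty network"):
            map_degs(tiny_degs, empty)


class TestActivityCounts:
    def test_three_up_targets_tally_to_one_sigma(self):
        net = RegulatoryNetwork(pd.DataFrame(
            [("S", "sigma", g, "activator") for g in ("a", "b", "c")],
            columns=["regulator", "reg_class", "target", "mode"],
        ))
        act = activity_counts(map_degs(degset(up=["a", "b", "c"]), net), net, "amp:stat")
        row = act.table.loc["S"]
        assert (row["up_count"], row["down_count"], row["regulon_size"]) == (3, 0, 3)

    def test_shared_gene_counts_once_per_regulator(self, tiny_network):
        act = activity_counts(map_degs(degset(up=["g1"]), tiny_network), tiny_network, "c")
        assert act.table.loc["RpoD", "up_count"] == 1
        assert act.table.loc["RpoS", "up_count"] == 1
        assert act.table.loc["MarA", "up_count"] == 1

    def test_zero_mapped_regulators_still_listed(self, tiny_network):
        act = activity_counts([], tiny_network, "c")
        assert set(act.table.index) == set(tiny_network.regulators)
        assert (act.table[["up_count", "down_count", "mapped_count"]] == 0).all().all()

    def test_counts_conserve_mapped_record_totals(self, tiny_network):
        mapped = map_degs(degset(up=["g1", "g2", "g4"], down=["g3"]), tiny_network)
        act = activity_counts(mapped, tiny_network, "c")
        n_up = sum(1 for r in mapped if r.direction == "up")
        n_down = sum(1 for r in mapped if r.direction == "down")
        assert act.table["up_count"].sum() == n_up
        assert act.table["down_count"].sum() == n_down

    def test_adding_an_edge_never_decreases_counts(self, tiny_network):
        degs = degset(up=["g1", "g2"], down=["g3"])
        before = activity_counts(map_degs(degs, tiny_network), tiny_network, "c").table
        grown = RegulatoryNetwork(pd.concat([
            tiny_network.edges,
            pd.DataFrame([("Fur", "TF", "g1", "activator")],
                         columns=["regulator", "reg_class", "target", "mode"]),
        ], ignore_index=True))
        after = activity_counts(map_degs(degs, grown), grown, "c").table
        for col in ("up_count", "down_count"):
            assert (after[col] >= before[col]).all()


@st.composite
def random_mapping_case(draw):
    n_genes = draw(st.integers(3, 12))
    genes = [f"g{i}" for i in range(n_genes)]
    n_edges = draw(st.integers(1, 30))
    rows = [
        (
            draw(st.sampled_from(["S1", "S2", "T1", "T2", "T3"])),
            None,
            draw(st.sampled_from(genes)),
            draw(st.sampled_from(["activator", "repressor", "dual", "unknown"])),
        )
        for _ in range(n_edges)
    ]
    rows = list({(r, "sigma" if r.startswith("S") else "TF", t, "activator" if r.startswith("S") else m)
                 for r, _, t, m in rows})
    up = draw(st.sets(st.sampled_from(genes)))
    down = draw(st.sets(st.sampled_from(genes)).map(lambda s: s - up))
    net = RegulatoryNetwork(pd.DataFrame(
        rows, columns=["regulator", "reg_class", "target", "mode"]))
    return net, degset(up, down)


@settings(derandomize=True, max_examples=100)
@given(random_mapping_case())
def test_mapping_invariants_on_random_fixtures(case):
    """Strict <= permissive; tallies conserve record totals; no invented ids."""
    net, degs = case
    strict = map_degs(degs, net, "strict")
    permissive = map_degs(degs, net, "permissive")
    assert set(strict) <= set(permissive)
    for recs in (strict, permissive):
        act = activity_counts(recs, net, "c")
        assert act.table["up_count"].sum() == sum(r.direction == "up" for r in recs)
        assert act.table["down_count"].sum() == sum(r.direction == "down" for r in recs)
        assert {r.regulator for r in recs} <= set(net.regulators)
        assert {r.gene for r in recs} <= degs.genes


class TestBuildGraph:
    def test_two_regulators_sharing_a_gene(self):
        recs = [("A", "TF", "x", "up", "activator"), ("B", "TF", "x", "up", "activator")]
        from regulonpulse.trnmap import MappedChange

        g = build_graph([MappedChange(*r) for r in recs]).graph
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g["A"]["x"]["direction"] == "up"

    def test_empty_input_gives_empty_graph(self):
        g = build_graph([]).graph
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_counts_equal_distinct_entities(self, tiny_network):
        mapped = map_degs(degset(up=["g1", "g2"], down=["g3"]), tiny_network)
        g = build_graph(mapped).graph
        assert g.number_of_edges() == len({(r.regulator, r.gene) for r in mapped})
        assert g.number_of_nodes() == len(
            {r.regulator for r in mapped} | {r.gene for r in mapped}
        )
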