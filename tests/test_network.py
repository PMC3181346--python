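"""DE gene sets, Fisher overlap against an exact rational oracle, network."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from pagenet import (
    Comparison,
    FoldChangeProfile,
    PagenetError,
    build_de_sets,
    build_network,
    export_network,
    fisher_overlap,
    select_annotation_nodes,
    signed_fold_change,
)
from pagenet.expression import GeneSetCatalog
from pagenet.network import read_category_table

from conftest import hypergeom_upper_tail


def profile(name, lfc: dict[str, float]) -> FoldChangeProfile:
    series = pd.Series(lfc, dtype=float)
    return FoldChangeProfile(
        Comparison(name, f"{name}_t", f"{name}_r"),
        series,
        pd.Series(signed_fold_change(series), index=series.index),
        float(series.mean()),
        float(series.std(ddof=0)),
    )


class TestBuildDESets:
    def test_eight_profiles_yield_sixteen_sets(self):
        rng = np.random.default_rng(0)
        profiles = [
            profile(f"c{i}", {f"g{j}": float(v) for j, v in enumerate(rng.normal(0, 1, 50))})
            for i in range(8)
        ]
        de = build_de_sets(profiles, 1.5)
        assert len(de) == 16
        assert {d.direction for d in de} == {"up", "down"}

    def test_flat_profile_gives_empty_sets(self):
        de = build_de_sets([profile("c", {"g1": 0.0, "g2": 0.0})], 1.5)
        assert all(len(d.members) == 0 for d in de)

    def test_threshold_applied_strictly_by_hand(self):
        # sfc = (2.0, -1.6, 1.2): up = {g1}, down = {g2}
        lfc = {"g1": 1.0, "g2": -np.log2(1.6), "g3": np.log2(1.2)}
        up, down = build_de_sets([profile("c", lfc)], 1.5)
        assert set(up.members) == {"g1"} and up.direction == "up"
        assert set(down.members) == {"g2"} and down.direction == "down"

    def test_up_and_down_are_disjoint_and_cutoff_validated(self):
        rng = np.random.default_rng(1)
        prof = profile("c", {f"g{j}": float(v) for j, v in enumerate(rng.normal(0, 2, 100))})
        up, down = build_de_sets([prof], 1.5)
        assert not (up.members & down.members)
        with pytest.raises(ValueError):
            build_de_sets([prof], 1.0)
        with pytest.raises(ValueError):
            build_de_sets([], 1.5)


class TestFisherOverlap:
    def test_b_equal_universe_is_the_certain_event(self):
        universe = {f"g{i}" for i in range(12)}
        a = {"g0", "g1", "g2"}
        test = fisher_overlap(a, universe, universe)
        assert test.k == len(a)
        assert test.p == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_n20_a5_b4_k4(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(4)}
        test = fisher_overlap(a, b, universe)
        assert test.k == 4
        assert test.p == pytest.approx(5 / 4845, rel=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exact_enumeration_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 26))
        universe = [f"g{i}" for i in range(n)]
        a = set(rng.choice(universe, size=int(rng.integers(0, n + 1)), replace=False))
        b = set(rng.choice(universe, size=int(rng.integers(0, n + 1)), replace=False))
        test = fisher_overlap(a, b, universe)
        exact = float(hypergeom_upper_tail(n, len(a), len(b), test.k))
        assert test.p == pytest.approx(exact, abs=1e-12, rel=1e-10)

    def test_p_monotone_non_increasing_in_k(self):
        universe = [f"g{i}" for i in range(40)]
        b = set(universe[:15])
        last = 1.1
        for k in range(0, 11):
            a = set(universe[:k]) | set(universe[15 : 15 + (10 - k)])
            test = fisher_overlap(a, b, universe)
            assert test.k == k
            assert test.p <= last + 1e-15
            last = test.p

    def test_members_outside_universe_rejected(self):
        with pytest.raises(PagenetError, match="gX"):
            fisher_overlap({"gX"}, {"g1"}, {"g1", "g2"})


class TestAnnotationSelection:
    def test_zero_overlap_set_never_selected(self):
        universe = {f"g{i}" for i in range(100)}
        de = build_de_sets(
            [profile("c", {f"g{i}": (2.0 if i < 10 else 0.0) for i in range(100)})], 1.5
        )
        catalog = GeneSetCatalog()
        catalog.add("disjoint", "", [f"g{i}" for i in range(50, 70)])
        chosen = select_annotation_nodes(de, catalog, {"measured": universe})
        assert chosen == []

    def test_perfectly_overlapping_set_selected(self):
        universe = {f"g{i}" for i in range(200)}
        de = build_de_sets(
            [profile("c", {f"g{i}": (2.0 if i < 15 else 0.0) for i in range(200)})], 1.5
        )
        catalog = GeneSetCatalog()
        catalog.add("hit", "", [f"g{i}" for i in range(15)])
        catalog.add("miss", "", [f"g{i}" for i in range(100, 120)])
        chosen = select_annotation_nodes(de, catalog, {"measured": universe})
        assert chosen == ["hit"]


class TestBuildNetwork:
    def _de(self, name, members, tag="measured"):
        from pagenet.network import DEGeneSet

        direction = "up" if name.endswith("up") else "down"
        return DEGeneSet(name, name.rsplit("_", 1)[0], direction, frozenset(members), tag)

    def test_disjoint_sets_produce_no_edge(self):
        universe = {f"g{i}" for i in range(50)}
        de = [
            self._de("c1_up", [f"g{i}" for i in range(10)]),
            self._de("c2_up", [f"g{i}" for i in range(20, 30)]),
        ]
        net = build_network(de, [], GeneSetCatalog(), {"measured": universe}, drop_isolated=False)
        assert net.n_edges == 0 and net.n_nodes == 2

    def test_identical_large_sets_connect(self):
        universe = {f"g{i}" for i in range(500)}
        members = [f"g{i}" for i in range(30)]
        de = [self._de("c1_up", members), self._de("c2_up", members)]
        net = build_network(de, [], GeneSetCatalog(), {"measured": universe})
        assert net.n_edges == 1
        attrs = net.graph.edges["c1_up", "c2_up"]
        assert attrs["k"] == 30
        assert attrs["overlap_genes"].split(",") == sorted(members)

    def test_drop_isolated_removes_unconnected_de_nodes(self):
        universe = {f"g{i}" for i in range(500)}
        members = [f"g{i}" for i in range(30)]
        de = [
            self._de("c1_up", members),
            self._de("c2_up", members),
            self._de("lonely_down", [f"g{i}" for i in range(300, 310)]),
        ]
        net = build_network(de, [], GeneSetCatalog(), {"measured": universe}, drop_isolated=True)
        assert "lonely_down" not in net.graph
        net2 = build_network(de, [], GeneSetCatalog(), {"measured": universe}, drop_isolated=False)
        assert "lonely_down" in net2.graph

    def test_edge_set_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(300)]
        de = [
            self._de(f"c{i}_up", rng.choice(universe, 40, replace=False)) for i in range(5)
        ]
        net1 = build_network(de, [], GeneSetCatalog(), {"measured": set(universe)}, drop_isolated=False)
        net2 = build_network(de[::-1], [], GeneSetCatalog(), {"measured": set(universe)}, drop_isolated=False)
        assert set(map(frozenset, net1.graph.edges())) == set(map(frozenset, net2.graph.edges()))

    def test_empty_node_list_warns(self):
        with pytest.raises(ValueError):
            build_de_sets([], 1.5)
        with pytest.warns(UserWarning, match="empty node list"):
            net = build_network([], [], GeneSetCatalog(), {"measured": {"g1"}})
        assert net.n_nodes == 0

    def test_category_table_attaches_functional_classes(self, tmp_path):
        path = tmp_path / "cats.tsv"
        path.write_text("hit\timmune/inflammation\n# comment\n")
        table = read_category_table(path)
        universe = {f"g{i}" for i in range(500)}
        members = [f"g{i}" for i in range(30)]
        de = [self._de("c1_up", members)]
        catalog = GeneSetCatalog()
        catalog.add("hit", "", members)
        net = build_network(de, ["hit"], catalog, {"measured": universe},
                            category_table=table, drop_isolated=False)
        assert net.graph.nodes["hit"]["category"] == "immune/inflammation"
        assert net.graph.nodes["c1_up"]["category"] == "unassigned"
        assert net.graph.nodes["hit"]["size"] == 30


class TestExport:
    def _toy_network(self):
        universe = {f"g{i}" for i in range(500)}
        members = [f"g{i}" for i in range(30)]
        de = [
            TestBuildNetwork()._de("c1_up", members),
            TestBuildNetwork()._de("c2_up", members),
        ]
        return build_network(de, [], GeneSetCatalog(), {"measured": universe})

    def test_empty_network_writes_valid_skeletons(self, tmp_path):
        with pytest.warns(UserWarning):
            net = build_network([], [], GeneSetCatalog(), {"measured": {"g1"}})
        export_network(net, tmp_path)
        assert (tmp_path / "network.sif").read_text() == ""
        back = nx.read_graphml(tmp_path / "network.graphml")
        assert back.number_of_nodes() == 0

    def test_two_node_one_edge_sif_text(self, tmp_path):
        export_network(self._toy_network(), tmp_path, formats=("sif",))
        assert (tmp_path / "network.sif").read_text() == "c1_up\toverlap\tc2_up\n"

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        net = self._toy_network()
        export_network(net, tmp_path, formats=("graphml",))
        back = nx.read_graphml(tmp_path / "network.graphml")
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges
        assert back.nodes["c1_up"]["node_class"] == "de_set"
        assert back.nodes["c1_up"]["size"] == 30
        assert back.edges["c1_up", "c2_up"]["k"] == 30

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            export_network(self._toy_network(), tmp_path, formats=("dot",))
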