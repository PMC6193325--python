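import itertools
import random

import networkx as nx
import pandas as pd
import pytest

from herbnet import netcore
from herbnet.io import Herb, Role

from conftest import brute_force_betweenness, make_compound


def _toy_net(toy_herbs):
    comps = {
        "M1": make_compound("M1", "alpha", {"HB_J"}),
        "M2": make_compound("M2", "beta", {"HB_J", "HB_C"}),
        "M3": make_compound("M3", "gamma", {"HB_Z"}),
    }
    assoc = pd.DataFrame(
        [
            {"compound_id": "M1", "target": "T1"},
            {"compound_id": "M1", "target": "T2"},
            {"compound_id": "M2", "target": "T2"},
            {"compound_id": "M2", "target": "T3"},
            {"compound_id": "M3", "target": "T4"},
        ]
    )
    return netcore.build_hbcct(toy_herbs, comps, assoc), comps, assoc


class TestBuildHbcct:
    def test_minimal_network(self):
        herbs = {Herb("HB_J", Role.JUN)}
        comps = {"M1": make_compound("M1", "alpha", {"HB_J"})}
        assoc = pd.DataFrame([{"compound_id": "M1", "target": "T1"}])
        g = netcore.build_hbcct(herbs, comps, assoc)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_compound_degree_decomposes_into_herbs_plus_targets(self, toy_herbs):
        g, comps, assoc = _toy_net(toy_herbs)
        for cid, c in comps.items():
            n_targets = (assoc["compound_id"] == cid).sum()
            assert g.degree(c.name) == len(c.herbs) + n_targets

    def test_shared_target_degree(self, toy_herbs):
        g, _, _ = _toy_net(toy_herbs)
        assert g.degree("T2") == 2

    def test_handshake_lemma(self, toy_herbs):
        g, _, _ = _toy_net(toy_herbs)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_association_to_unknown_compound_rejected(self, toy_herbs):
        comps = {"M1": make_compound("M1", "alpha", {"HB_J"})}
        assoc = pd.DataFrame([{"compound_id": "UNSCREENED", "target": "T1"}])
        with pytest.raises(KeyError, match="UNSCREENED"):
            netcore.build_hbcct(toy_herbs, comps, assoc)

    def test_forbidden_edge_detected(self):
        g = nx.Graph()
        g.add_node("HB", nodetype="HERB")
        g.add_node("T", nodetype="TARGET")
        g.add_edge("HB", "T")
        with pytest.raises(ValueError, match="forbidden"):
            netcore.validate_tripartite(g)


class TestRestrictToDisease:
    def test_disjoint_disease_set_gives_empty_network(self, toy_herbs):
        g, _, _ = _toy_net(toy_herbs)
        with pytest.warns(UserWarning, match="empty"):
            sub = netcore.restrict_to_disease(g, {"NOPE"})
        assert sub.number_of_nodes() == 0

    def test_compounds_without_disease_edges_dropped(self, toy_herbs):
        g, _, _ = _toy_net(toy_herbs)
        sub = netcore.restrict_to_disease(g, {"T1", "T2"})
        kinds = nx.get_node_attributes(sub, "nodetype")
        assert {n for n, k in kinds.items() if k == "COMPOUND"} == {"alpha", "beta"}
        assert "gamma" not in sub and "HB_Z" not in sub

    def test_idempotent(self, toy_herbs):
        g, _, _ = _toy_net(toy_herbs)
        once = netcore.restrict_to_disease(g, {"T1", "T2"})
        twice = netcore.restrict_to_disease(once, {"T1", "T2"})
        assert set(once.nodes()) == set(twice.nodes())
        assert set(map(frozenset, once.edges())) == set(map(frozenset, twice.edges()))


class TestBetweenness:
    def test_path_graph_middle_node(self):
        g = nx.path_graph(["a", "b", "c"])
        btw = netcore.betweenness_centrality(g)
        assert btw["b"] == pytest.approx(1.0)
        assert btw["a"] == btw["c"] == 0.0

    def test_complete_graph_all_zero(self):
        btw = netcore.betweenness_centrality(nx.complete_graph(4))
        assert all(v == 0.0 for v in btw.values())

    def test_matches_brute_force_on_random_graphs(self):
        rng = random.Random(11)
        for _ in range(60):
            n = rng.randint(2, 12)
            p = rng.uniform(0.1, 0.9)
            g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 10**6))
            expect = brute_force_betweenness(list(g.edges()), list(g.nodes()))
            got = netcore.betweenness_centrality(g)
            for v in g.nodes():
                assert got[v] == pytest.approx(expect[v], abs=1e-12)


class TestTopK:
    records = pd.DataFrame(
        [
            {"node": "b", "nodetype": "TARGET", "degree": 5, "betweenness": 0.1},
            {"node": "a", "nodetype": "TARGET", "degree": 5, "betweenness": 0.1},
            {"node": "c", "nodetype": "TARGET", "degree": 5, "betweenness": 0.3},
            {"node": "d", "nodetype": "TARGET", "degree": 2, "betweenness": 0.9},
        ]
    )

    def test_ties_break_by_other_indicator_then_label(self):
        top = netcore.top_k(self.records, "degree", 4)
        assert list(top["node"]) == ["c", "a", "b", "d"]

    def test_k_larger_than_table_returns_full_ranking(self):
        assert len(netcore.top_k(self.records, "betweenness", 99)) == 4

    def test_stable_under_shuffling(self):
        shuffled = self.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = netcore.top_k(self.records, "degree", 3)
        b = netcore.top_k(shuffled, "degree", 3)
        assert list(a["node"]) == list(b["node"])

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            netcore.top_k(self.records, "degree", 0)


class TestPtF:
    def test_single_membership(self):
        ann = pd.DataFrame([{"gene": "TGFB1", "term": "apoptosis"}])
        g = netcore.build_pt_f({"TGFB1"}, ann)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_per_node_counts(self):
        ann = pd.DataFrame(
            [{"gene": "TGFB1", "term": f"bp{i}"} for i in range(9)]
            + [{"gene": f"G{i}", "term": "apoptosis"} for i in range(25)]
        )
        targets = {"TGFB1"} | {f"G{i}" for i in range(25)}
        g = netcore.build_pt_f(targets, ann)
        assert g.degree("TGFB1") == 9
        assert g.degree("apoptosis") == 25

    def test_unannotated_targets_ignored(self):
        ann = pd.DataFrame([{"gene": "A", "term": "t"}])
        g = netcore.build_pt_f({"A", "B"}, ann)
        assert "B" not in g


class TestDockingFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["compound_id", "target", "libdock_score", "reference_score"]
        )

    def test_strictly_above_reference_retained(self):
        dock = self._table([("M1", "AKT1", 120.0, 100.0)])
        assert len(netcore.docking_filter(dock)) == 1

    def test_equal_to_reference_dropped(self):
        dock = self._table([("M1", "AKT1", 100.0, 100.0)])
        assert len(netcore.docking_filter(dock)) == 0

    def test_hand_counted_retention(self):
        dock = self._table(
            [
                ("M1", "A", 110, 100),
                ("M2", "A", 90, 100),
                ("M3", "B", 101, 100),
                ("M4", "B", 100, 100),
                ("M5", "C", 130, 100),
            ]
        )
        kept = netcore.docking_filter(dock)
        assert len(kept) == 3
        assert set(kept["compound_id"]) == {"M1", "M3", "M5"}
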