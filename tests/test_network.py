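"""Regulatory graph construction, betweenness centrality, hubs, idealized vector."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from balfrepo import (
    betweenness,
    build_graph,
    idealized_vector,
    select_hubs,
)
from balfrepo.diffexpr import DOWN, UP
from balfrepo.network import CentralityTable
from oracles import brute_force_betweenness


def _edges(pairs, sign=1, refs=1):
    return pd.DataFrame(
        [(u, v, sign, refs) for u, v in pairs],
        columns=["source", "target", "sign", "refs"],
    )


class TestBuildGraph:
    def test_empty_edge_list_leaves_all_nodes_isolated(self):
        rg = build_graph(_edges([]), {"A": UP, "B": DOWN})
        assert rg.n_isolated == 2
        assert rg.connectivity_report()["largest_component_size"] <= 1

    def test_triangle_has_no_isolated_nodes(self):
        rg = build_graph(
            _edges([("A", "B"), ("B", "C"), ("C", "A")]),
            {"A": UP, "B": DOWN, "C": UP},
        )
        assert rg.n_isolated == 0
        assert rg.graph.number_of_edges() == 3

    def test_unknown_entity_edges_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            rg = build_graph(
                _edges([("A", "B"), ("A", "X")]), {"A": UP, "B": DOWN}
            )
        assert rg.skipped_edges == [("A", "X")]
        assert rg.graph.number_of_edges() == 1

    def test_parallel_edges_collapse_and_sum_refs(self):
        edges = _edges([("A", "B"), ("B", "A")], refs=3)
        rg = build_graph(edges, {"A": UP, "B": DOWN})
        assert rg.graph.number_of_edges() == 1
        assert rg.graph["A"]["B"]["refs"] == 6

    def test_self_loops_removed(self):
        rg = build_graph(_edges([("A", "A"), ("A", "B")]), {"A": UP, "B": DOWN})
        assert rg.graph.number_of_edges() == 1

    def test_isolated_count_matches_generator_truth(self, study):
        rg = build_graph(study.edges, study.truth["de_directions"])
        assert rg.isolated == study.truth["isolated"]


class TestBetweenness:
    def test_path_center_scores_one(self):
        g = nx.path_graph(["a", "b", "c"])
        ct = betweenness(g)
        assert ct.table.at["b", "Cb"] == pytest.approx(1.0)
        assert ct.table.at["a", "Cb"] == 0.0 and ct.table.at["c", "Cb"] == 0.0
        assert ct.table.at["b", "Cb_norm"] == 1.0

    def test_star_center_scores_all_leaf_pairs(self):
        g = nx.star_graph(5)  # center 0 + 5 leaves -> C(5,2) = 10
        ct = betweenness(g)
        assert ct.table.at[0, "Cb"] == pytest.approx(10.0)
        assert (ct.table.drop(index=0)["Cb"] == 0).all()

    def test_complete_graph_has_zero_betweenness_everywhere(self):
        ct = betweenness(nx.complete_graph(6))
        assert (ct.table["Cb"] == 0).all()
        assert (ct.table["Cb_norm"] == 0).all()

    def test_matches_brute_force_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(2, 13))
            p = float(rng.uniform(0.15, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            ct = betweenness(g)
            oracle = brute_force_betweenness(g)
            for node, expect in oracle.items():
                assert ct.table.at[node, "Cb"] == pytest.approx(expect, abs=1e-9)

    def test_adding_edge_to_isolated_node_never_decreases_its_centrality(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.relabel_nodes(
                nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31))), str
            )
            g.add_node("iso")
            before = betweenness(g).table.at["iso", "Cb"]
            g.add_edge("iso", str(rng.integers(8)))
            g.add_edge("iso", str(rng.integers(8)))
            after = betweenness(g).table.at["iso", "Cb"]
            assert after >= before

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            betweenness(nx.Graph())


class TestHubSelection:
    def _ct(self, values: dict) -> CentralityTable:
        raw = pd.Series(values, dtype=float)
        norm = raw / raw.max() if raw.max() > 0 else raw * 0
        return CentralityTable(
            pd.DataFrame(
                {
                    "Cb": raw,
                    "Cb_norm": norm,
                    "is_hub": False,
                    "desired_effect": "none",
                }
            )
        )

    def test_quarter_of_max_rule(self):
        ct = select_hubs(self._ct({"a": 10.0, "b": 5.0, "c": 2.0}), threshold=0.25)
        assert ct.hubs == ["a", "b"]

    def test_threshold_one_keeps_only_the_maximum(self):
        ct = select_hubs(self._ct({"a": 10.0, "b": 5.0, "c": 2.0}), threshold=1.0)
        assert ct.hubs == ["a"]

    def test_all_zero_centrality_warns_and_selects_nothing(self):
        with pytest.warns(UserWarning, match="no hubs"):
            ct = select_hubs(self._ct({"a": 0.0, "b": 0.0}))
        assert ct.hubs == []

    def test_gap_rule_cuts_at_superlinear_drop(self):
        # profile 1.0, 0.9, 0.3, 0.2, 0.1: deepest super-linear drop after rank 2
        ct = select_hubs(
            self._ct({"a": 1.0, "b": 0.9, "c": 0.3, "d": 0.2, "e": 0.1}),
            rule="gap",
        )
        assert ct.hubs == ["a", "b"]

    def test_planted_hubs_recovered_on_synthetic_graph(self, study):
        rg = build_graph(study.edges, study.truth["de_directions"])
        ct = select_hubs(
            betweenness(rg), threshold=0.25, de_directions=rg.de_directions
        )
        assert set(ct.hubs) >= set(study.truth["hubs"])

    def test_desired_effect_annotation(self):
        ct = self._ct({"a": 10.0, "b": 1.0})
        ct = select_hubs(ct, threshold=0.25, de_directions={"a": UP, "b": DOWN})
        assert ct.table.at["a", "desired_effect"] == "inhibit"
        assert ct.table.at["b", "desired_effect"] == "none"  # not a hub


class TestIdealizedVector:
    def test_signs_oppose_disease_direction(self):
        m = idealized_vector(
            ["down_hub", "up_hub"],
            {"down_hub": DOWN, "up_hub": UP, "other": UP},
            ["down_hub", "up_hub", "other"],
        )
        assert m.values["down_hub"] == 1    # depressed in disease -> promote
        assert m.values["up_hub"] == -1     # elevated in disease -> inhibit
        assert m.values["other"] == 0

    def test_hub_without_direction_rejected(self):
        with pytest.raises(ValueError, match="no differential direction"):
            idealized_vector(["h"], {}, ["h"])

    def test_hub_outside_entity_order_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            idealized_vector(["h"], {"h": UP}, ["x"])

    def test_matches_generator_truth(self, study):
        rg = build_graph(study.edges, study.truth["de_directions"])
        m = idealized_vector(
            study.truth["hubs"], study.truth["de_directions"], rg.nodes
        )
        expect = study.truth["idealized_vector"]
        for hub, sign in expect.items():
            assert m.values[hub] == sign
        assert int(np.abs(m.values).sum()) == len(expect)
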