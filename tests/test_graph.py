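"""Positive-weight graphs, centralities, participation, hub rules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sentnet.cluster import ConnectivityMatrix, Partition
from sentnet.config import AnalysisConfig
from sentnet.graph import (
    betweenness_centrality,
    classify_hubs,
    degree_centrality,
    participation_index,
    positive_graph,
    summarize_and_classify,
)
from sentnet import reference


def _mat(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"n{i}" for i in range(values.shape[0])]
    return ConnectivityMatrix(values, names)


def brute_force_betweenness(g: nx.Graph, alpha: float = 1.0) -> dict:
    """Exhaustive enumeration of all simple paths per node pair."""
    bc = {n: 0.0 for n in g.nodes}
    cost = {
        (u, v): d["weight"] ** (-alpha) for u, v, d in g.edges(data=True)
    }
    cost.update({(v, u): c for (u, v), c in cost.items()})
    for s, t in itertools.combinations(g.nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        lengths = [
            sum(cost[(a, b)] for a, b in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        geodesics = [
            p for p, l in zip(paths, lengths) if l <= best + 1e-12
        ]
        for p in geodesics:
            for node in p[1:-1]:
                bc[node] += 1.0 / len(geodesics)
    return bc


class TestPositiveGraph:
    def test_all_negative_gives_empty_graph(self):
        vals = np.full((3, 3), -0.4)
        np.fill_diagonal(vals, 0.0)
        g = positive_graph(_mat(vals))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_single_positive_edge(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.5
        g = positive_graph(_mat(vals))
        assert list(g.edges(data="weight")) == [("n0", "n1", 0.5)]

    def test_mixed_signs_match_sign_filter(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(-0.9, 0.9, (4, 4))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0.0)
        g = positive_graph(_mat(vals))
        expected = {
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if vals[i, j] > 0
        }
        got = {
            (int(u[1:]), int(v[1:])) for u, v in g.edges
        }
        got = {(min(a, b), max(a, b)) for a, b in got}
        assert got == expected


class TestDegree:
    def test_triangle(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0.0)
        dc = degree_centrality(positive_graph(_mat(vals)))
        assert all(v == pytest.approx(1.0) for v in dc.values())

    def test_isolated_node_zero(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.5
        dc = degree_centrality(positive_graph(_mat(vals)))
        assert dc["n2"] == 0.0

    def test_matches_row_sums(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(-0.5, 0.9, (8, 8))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0.0)
        dc = degree_centrality(positive_graph(_mat(vals)))
        pos = np.where(vals > 0, vals, 0.0)
        for i in range(8):
            assert dc[f"n{i}"] == pytest.approx(pos[i].sum())


class TestBetweenness:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=0.5)
        bc = betweenness_centrality(g)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_triangle_zero(self):
        g = nx.Graph()
        for u, v in itertools.combinations("abc", 2):
            g.add_edge(u, v, weight=0.5)
        bc = betweenness_centrality(g)
        assert all(v == 0.0 for v in bc.values())

    def test_matches_enumeration_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 8))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.6:
                    g.add_edge(i, j, weight=float(rng.uniform(0.05, 0.95)))
            got = betweenness_centrality(g)
            expected = brute_force_betweenness(g)
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-9)

    def test_scaling_leaves_bc_and_hubs_invariant(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.05, 0.9, (10, 10))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0.0)
        m1 = _mat(vals)
        m2 = _mat(vals * 0.5)
        g1, g2 = positive_graph(m1), positive_graph(m2)
        bc1, bc2 = betweenness_centrality(g1), betweenness_centrality(g2)
        dc1, dc2 = degree_centrality(g1), degree_centrality(g2)
        names = list(g1.nodes)
        for n in names:
            assert bc1[n] == pytest.approx(bc2[n])
            assert dc2[n] == pytest.approx(0.5 * dc1[n])
        h1 = classify_hubs(
            [dc1[n] for n in names], [bc1[n] for n in names], names
        )[2]
        h2 = classify_hubs(
            [dc2[n] for n in names], [bc2[n] for n in names], names
        )[2]
        assert h1 == h2


class TestParticipation:
    def _graph(self, edges):
        g = nx.Graph()
        g.add_weighted_edges_from(edges)
        return g

    def test_all_within_module_zero(self):
        g = self._graph([("a", "b", 0.5), ("b", "c", 0.3), ("a", "c", 0.2)])
        part = {"a": "M1", "b": "M1", "c": "M1"}
        p = participation_index(g, part)
        assert all(v == pytest.approx(0.0) for v in p.values())

    def test_even_split_two_modules(self):
        g = self._graph([("x", "a", 0.4), ("x", "b", 0.4)])
        part = {"x": "M1", "a": "M1", "b": "M2"}
        p = participation_index(g, part)
        assert p["x"] == pytest.approx(0.5)

    def test_even_split_three_modules(self):
        g = self._graph(
            [("x", "a", 0.4), ("x", "b", 0.4), ("x", "c", 0.4)]
        )
        part = {"x": "M1", "a": "M1", "b": "M2", "c": "M3"}
        p = participation_index(g, part)
        assert p["x"] == pytest.approx(2.0 / 3.0)

    def test_isolated_node_zero(self):
        g = self._graph([("a", "b", 0.5)])
        g.add_node("z")
        p = participation_index(g, {"a": "M1", "b": "M1", "z": "M1"})
        assert p["z"] == 0.0


class TestHubClassification:
    def test_reference_table_thresholds(self):
        """Feeding the published 18-region centrality means reproduces the
        printed mean + SD thresholds within 1%."""
        tab = reference.CORE_CENTRALITY
        dc_thr, bc_thr, _ = classify_hubs(
            tab["dc_mean"], tab["bc_mean"], list(tab["abbreviation"])
        )
        assert dc_thr == pytest.approx(5.55, rel=0.01)
        assert bc_thr == pytest.approx(10.26, rel=0.01)

    def test_reference_table_hub_set(self):
        tab = reference.CORE_CENTRALITY
        _, _, hubs = classify_hubs(
            tab["dc_mean"], tab["bc_mean"], list(tab["abbreviation"])
        )
        assert sorted(hubs) == ["F3t", "STS3", "STS4"]

    def test_zero_spread_gives_no_hubs(self):
        with pytest.warns(UserWarning, match="no hubs"):
            _, _, hubs = classify_hubs(
                [1.0, 1.0, 1.0], [2.0, 2.0, 2.0], ["a", "b", "c"]
            )
        assert hubs == []

    def test_connector_fraction_of_full_set(self):
        """ceil(0.15 * 32) = 5 connector hubs from the full selected set."""
        rng = np.random.default_rng(4)
        dc = pd.DataFrame(
            rng.uniform(1, 5, (10, 6)), columns=list("abcdef")
        )
        bc = pd.DataFrame(
            rng.uniform(0, 4, (10, 6)), columns=list("abcdef")
        )
        pindex = {f"r{i}": i / 32 for i in range(32)}
        gm = summarize_and_classify(
            dc, bc, pindex, AnalysisConfig(), n_total_regions=32
        )
        assert len(gm.connector_hubs) == 5
        assert gm.connector_hubs == [f"r{i}" for i in range(31, 26, -1)]
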