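"""Planar network construction, module hierarchy, hubs and neighborhoods."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import toy_edges
from dimorphnet.coexnet import (ConnectivityProfile, build_pmfg,
                                correlation_edges, detect_modules,
                                intramodular_connectivity,
                                l_layer_neighborhood, nominate_knds)


class TestCorrelationEdges:
    def test_perfect_pair_sorts_first(self, rng):
        base = rng.normal(size=20)
        matrix = pd.DataFrame(
            [base, 2 * base + 1, rng.normal(size=20), rng.normal(size=20)],
            index=["a", "b", "c", "d"])
        edges = correlation_edges(matrix)
        top = edges.iloc[0]
        assert {top.gene_a, top.gene_b} == {"a", "b"}
        assert top.rho == pytest.approx(1.0)

    def test_anticorrelated_pair_sorts_by_magnitude(self, rng):
        base = rng.normal(size=20)
        matrix = pd.DataFrame([base, -base, rng.normal(size=20)],
                              index=["a", "b", "c"])
        edges = correlation_edges(matrix)
        assert edges.iloc[0].rho == pytest.approx(-1.0)

    def test_constant_gene_pairs_dropped(self, rng):
        matrix = pd.DataFrame([np.ones(10), rng.normal(size=10),
                               rng.normal(size=10)], index=["a", "b", "c"])
        edges = correlation_edges(matrix, fdr_max=1.0)
        assert "a" not in set(edges.gene_a) | set(edges.gene_b)

    def test_null_matrix_keeps_few_edges(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(50, 100)),
                              index=[f"g{i}" for i in range(50)])
        edges = correlation_edges(matrix, fdr_max=0.05)
        assert len(edges) <= 0.05 * (50 * 49 / 2) + 10


class TestBuildPMFG:
    def complete(self, n, rng):
        rows = [(f"n{i}", f"n{j}", rng.uniform(0.1, 1.0))
                for i, j in itertools.combinations(range(n), 2)]
        return toy_edges(rows), [f"n{i}" for i in range(n)]

    def test_k4_is_kept_entirely(self, rng):
        edges, nodes = self.complete(4, rng)
        G = build_pmfg(edges, nodes)
        assert G.number_of_edges() == 6

    def test_k5_drops_exactly_the_weakest_edge(self, rng):
        edges, nodes = self.complete(5, rng)
        G = build_pmfg(edges, nodes)
        assert G.number_of_edges() == 9
        weakest = edges.iloc[-1]
        assert not G.has_edge(weakest.gene_a, weakest.gene_b)

    def test_tree_input_is_kept_entirely(self, rng):
        rows = [(f"n{i}", f"n{i+1}", rng.uniform(0.1, 1.0))
                for i in range(9)]
        edges = toy_edges(rows)
        G = build_pmfg(edges, [f"n{i}" for i in range(10)])
        assert G.number_of_edges() == 9

    def test_empty_input_gives_empty_graph(self):
        G = build_pmfg(toy_edges([]), ["a", "b", "c"])
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 3

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_planar_with_saturated_edge_count(self, n, rng):
        edges, nodes = self.complete(n, rng)
        G = build_pmfg(edges, nodes)
        assert G.number_of_edges() == 3 * (n - 2)
        planar, embedding = nx.check_planarity(G)
        assert planar
        embedding.check_structure()


def two_clique_bridge(rng, size=15, w_in=(0.7, 0.95), w_bridge=0.2):
    rows = []
    for block, prefix in ((range(size), "a"), (range(size), "b")):
        names = [f"{prefix}{i:02d}" for i in block]
        for u, v in itertools.combinations(names, 2):
            rows.append((u, v, rng.uniform(*w_in)))
    rows.append(("a00", "b00", w_bridge))
    edges = toy_edges(rows)
    nodes = [f"a{i:02d}" for i in range(size)] + \
            [f"b{i:02d}" for i in range(size)]
    return build_pmfg(edges, nodes)


class TestDetectModules:
    def test_two_cliques_with_bridge_split_exactly(self, rng):
        G = two_clique_bridge(rng)
        hierarchy = detect_modules(G, min_size=10, seed=0)
        leaves = [m for m in hierarchy.nonroot()
                  if not hierarchy.children(m.id)]
        parts = {frozenset(m.members) for m in leaves}
        expected = {frozenset(f"a{i:02d}" for i in range(15)),
                    frozenset(f"b{i:02d}" for i in range(15))}
        assert parts == expected

    def test_min_size_guard_prevents_split(self, rng):
        rows = [(u, v, rng.uniform(0.5, 1.0)) for u, v in
                itertools.combinations([f"n{i}" for i in range(12)], 2)]
        G = build_pmfg(toy_edges(rows), [f"n{i}" for i in range(12)])
        hierarchy = detect_modules(G, min_size=10, seed=0)
        assert [len(m.members) for m in hierarchy.nonroot()] == [12]

    def test_hierarchy_invariants_and_determinism(self, rng):
        G = two_clique_bridge(rng)
        h1 = detect_modules(G, min_size=5, seed=3)
        h2 = detect_modules(G, min_size=5, seed=3)
        assert h1.to_frame().equals(h2.to_frame())
        by_id = h1.by_id
        root = by_id["M0"]
        assert root.members == frozenset(G.nodes)
        for mod in h1.nonroot():
            assert mod.members <= by_id[mod.parent].members
            children = h1.children(mod.id)
            total = sum(len(c.members) for c in children)
            assert total <= len(mod.members)


class TestConnectivity:
    def star(self):
        G = nx.Graph()
        for leaf in "bcde":
            G.add_edge("a", leaf, weight=1.0)
        return G

    def test_star_center_is_the_only_hub(self):
        profile = intramodular_connectivity(self.star(), list("abcde"))
        assert profile.k["a"] == 4
        assert profile.mean_k == pytest.approx(1.6)
        assert profile.sd_k == pytest.approx(1.342, abs=1e-3)
        assert profile.threshold == pytest.approx(2.942, abs=1e-3)
        assert nominate_knds(profile) == {"a"}

    def test_uniform_clique_has_no_hub(self):
        G = nx.complete_graph(5)
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in range(5)})
        nx.set_edge_attributes(G, 1.0, "weight")
        profile = intramodular_connectivity(G, list(G.nodes))
        assert nominate_knds(profile) == frozenset()

    def test_mean_plus_sd_rule_on_known_values(self):
        profile = ConnectivityProfile(
            module_id="m", k=pd.Series({"a": 1.0, "b": 1.0, "c": 1.0,
                                        "d": 5.0}),
            mean_k=2.0, sd_k=2.0)
        assert profile.threshold == 4.0
        assert nominate_knds(profile) == {"d"}

    def test_matches_brute_force_recomputation(self, rng):
        G = nx.gnm_random_graph(20, 60, seed=1)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in range(20)})
        for _, _, d in G.edges(data=True):
            d["weight"] = rng.uniform(-1, 1)
        members = sorted(G.nodes)[:12]
        profile = intramodular_connectivity(G, members)
        for g in members:
            expected = sum(abs(G[g][h]["weight"]) for h in G[g]
                           if h in members)
            assert profile.k[g] == pytest.approx(expected)
        expected_knds = {g for g in members
                         if profile.k[g] > profile.k.mean()
                         + profile.k.std(ddof=1)}
        assert nominate_knds(profile) == expected_knds

    def test_singleton_module_raises(self):
        with pytest.raises(ValueError):
            intramodular_connectivity(self.star(), ["a"])


class TestNeighborhood:
    def path(self):
        G = nx.path_graph(["a", "b", "c", "d", "e"])
        return G

    def test_l_zero_base_case(self):
        G = self.path()
        assert l_layer_neighborhood(G, "a", 0) == frozenset()
        assert l_layer_neighborhood(G, "a", 0, include_self=True) == {"a"}

    def test_path_metric(self):
        assert l_layer_neighborhood(self.path(), "a", 3) == {"b", "c", "d"}

    def test_saturation_at_diameter(self):
        G = self.path()
        assert l_layer_neighborhood(G, "a", 10) == {"b", "c", "d", "e"}

    def test_nesting(self):
        G = self.path()
        for L in range(4):
            assert l_layer_neighborhood(G, "c", L) <= \
                l_layer_neighborhood(G, "c", L + 1)

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            l_layer_neighborhood(self.path(), "z", 2)
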