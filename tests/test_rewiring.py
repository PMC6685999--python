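import networkx as nx
import numpy as np
import pandas as pd
import pytest

from noarewire.iotypes import InteractomeGraph
from noarewire.rewiring import (
    HubRecord,
    cross_run_gene_summary,
    degree_preserving_permutation,
    identify_noa_hubs,
    jaccard_index,
    map_module_to_interactome,
    neighbor_overlap_null_test,
    pairwise_overlap_matrix,
    rank_modules_by_activation,
    rewiring_degree,
)


def _interactome(edges, cutoff=0.156):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, score=0.9)
    return InteractomeGraph(graph=g, score_cutoff=cutoff)


def _de(rows):
    """rows: gene -> (log2fc, q)"""
    return pd.DataFrame(
        {"log2fc": [v[0] for v in rows.values()],
         "q_value": [v[1] for v in rows.values()]},
        index=pd.Index(rows.keys(), name="gene"),
    )


class TestModuleMapping:
    def test_connected_path_retained(self):
        # 10-gene module; 6 genes form an induced path, 4 are absent/isolated
        path = [(f"m{i}", f"m{i+1}") for i in range(5)]
        graph = _interactome(path + [("x", "y")])
        module = {f"m{i}" for i in range(10)}
        ms = map_module_to_interactome(module, graph, module=1)
        assert ms is not None
        assert ms.connected_member_count == 6

    def test_edgeless_module_rejected(self):
        graph = _interactome([("a", "b")])
        assert map_module_to_interactome({"p", "q", "r"}, graph) is None

    def test_five_connected_members_is_inclusive_boundary(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        graph = _interactome(edges)
        ms = map_module_to_interactome({"a", "b", "c", "d", "e"}, graph)
        assert ms is not None and ms.connected_member_count == 5


class TestRewiringDegree:
    def _setup(self):
        edges = [("hub", f"n{i}") for i in range(5)]
        graph = _interactome(edges)
        de = _de({
            "hub": (1.0, 0.001),
            "n0": (0.5, 0.01), "n1": (-0.7, 0.02), "n2": (0.1, 0.04),
            "n3": (2.0, 0.5), "n4": (0.9, 0.05),   # q exactly 0.05 -> not DE
        })
        return graph.graph, de

    def test_counts_de_neighbors_in_both_directions(self):
        sub, de = self._setup()
        deg, nbrs = rewiring_degree("hub", sub, de)
        assert deg == 3
        assert set(nbrs) == {"n0", "n1", "n2"}

    def test_isolated_gene_has_degree_zero(self):
        g = nx.Graph()
        g.add_node("solo")
        de = _de({"solo": (1.0, 0.001)})
        assert rewiring_degree("solo", g, de)[0] == 0

    def test_missing_de_entry_rejected(self):
        sub, de = self._setup()
        with pytest.raises(KeyError):
            rewiring_degree("ghost", sub, de.drop(index="hub"))


class TestHubRule:
    def _subgraph(self, genes, edges):
        graph = _interactome(edges)
        return map_module_to_interactome(genes, graph, module=1)

    def test_planted_hub_detected_and_single_criterion_decoys_rejected(self):
        # each decoy fails exactly one of the four criteria
        genes = {"hub", "fc_low", "q_high", "few", "down"} | {f"n{i}" for i in range(5)}
        edges = (
            [("hub", f"n{i}") for i in range(5)]
            + [("fc_low", f"n{i}") for i in range(5)]
            + [("q_high", f"n{i}") for i in range(5)]
            + [("few", "n0"), ("few", "n1")]
            + [("down", f"n{i}") for i in range(5)]
        )
        de = _de({
            "hub": (1.0, 0.001),
            "fc_low": (0.4, 0.001),
            "q_high": (1.0, 0.06),
            "few": (1.0, 0.001),
            "down": (-1.2, 1e-8),
            **{f"n{i}": (0.8, 0.01) for i in range(5)},
        })
        hubs = identify_noa_hubs([self._subgraph(genes, edges)], de, run="t")
        assert {h.gene_id for h in hubs} >= {"hub"}
        names = {h.gene_id for h in hubs}
        assert {"fc_low", "q_high", "few", "down"}.isdisjoint(names)

    def test_boundary_log2fc_half_is_hub(self):
        genes = {"g"} | {f"n{i}" for i in range(4)}
        edges = [("g", f"n{i}") for i in range(4)]
        de = _de({"g": (0.5, 0.01), **{f"n{i}": (0.6, 0.01) for i in range(4)}})
        hubs = identify_noa_hubs([self._subgraph(genes, edges)], de)
        assert [h.gene_id for h in hubs if h.gene_id == "g"]

    def test_hub_record_invariants_enforced(self):
        with pytest.raises(AssertionError):
            HubRecord("g", "r", 1, log2fc=0.3, q_value=0.01,
                      rewiring_degree=5, neighbor_genes=frozenset())


class TestModuleRanking:
    def test_hand_counted_fraction(self):
        genes = [f"g{i}" for i in range(10)]
        modules = pd.Series([1] * 10, index=pd.Index(genes, name="gene"))
        edges = [(genes[i], genes[i + 1]) for i in range(4)]  # g0..g4 connected
        graph = _interactome(edges)
        ms = map_module_to_interactome(set(genes), graph, module=1)
        de = _de({
            **{g: (1.0, 0.01) for g in genes[:4]},     # upregulated, connected
            **{g: (0.0, 0.9) for g in genes[4:]},
        })
        ranking = rank_modules_by_activation(modules, [ms], de)
        assert ranking.loc[0, "fraction"] == pytest.approx(0.4)

    def test_zero_and_full_activation(self):
        genes = ["a", "b", "c"]
        modules = pd.Series([1, 1, 1], index=pd.Index(genes, name="gene"))
        graph = _interactome([("a", "b"), ("b", "c"), ("a", "c")])
        ms = map_module_to_interactome(set(genes), graph, module=1, min_connected=3)
        full = rank_modules_by_activation(modules, [ms], _de({g: (1.0, 0.01) for g in genes}))
        none = rank_modules_by_activation(modules, [ms], _de({g: (-1.0, 0.9) for g in genes}))
        assert full.loc[0, "fraction"] == 1.0
        assert none.loc[0, "fraction"] == 0.0


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({"x"}, {"x"}, 1.0), ({"x"}, {"y"}, 0.0),
         ({"a", "b", "c"}, {"b", "c", "d"}, 0.5), (set(), set(), 0.0)],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_index(a, b) == pytest.approx(expected)

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(0)
        universe = list("abcdefghij")
        for _ in range(50):
            a = {x for x in universe if rng.random() < 0.5}
            b = {x for x in universe if rng.random() < 0.5}
            assert jaccard_index(a, b) == jaccard_index(b, a)
            if a or b:
                assert (jaccard_index(a, b) == 1.0) == (a == b)

    def test_pairwise_matrix_hand_values(self):
        result = pairwise_overlap_matrix(
            {"r1": {"a", "b"}, "r2": {"b", "c"}, "r3": {"c", "d"}}
        )
        m = result.matrix
        assert m.loc["r1", "r2"] == pytest.approx(1 / 3)
        assert m.loc["r1", "r3"] == 0.0
        assert m.loc["r2", "r3"] == pytest.approx(1 / 3)
        assert result.average_offdiag == pytest.approx(2 / 9)
        assert m.loc["r1", "r1"] == 2  # diagonal carries set sizes

    def test_identical_and_disjoint_sets(self):
        same = pairwise_overlap_matrix({"a": {"x"}, "b": {"x"}})
        assert same.average_offdiag == 1.0
        disjoint = pairwise_overlap_matrix({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert disjoint.average_offdiag == 0.0


class TestDegreePreservingPermutation:
    def test_degree_multiset_preserved(self):
        g = nx.gnp_random_graph(60, 0.1, seed=1)
        before = sorted(d for _, d in g.degree())
        for seed in range(20):
            mapping = degree_preserving_permutation(g, seed)
            h = nx.relabel_nodes(g, mapping)
            assert sorted(d for _, d in h.degree()) == before
            # every label keeps its degree exactly
            degrees = dict(g.degree())
            assert all(degrees[old] == degrees[new] for old, new in mapping.items())

    def test_regular_graph_permutes_all_nodes_freely(self):
        g = nx.cycle_graph(10)  # 2-regular
        mapping = degree_preserving_permutation(g, 3)
        assert set(mapping.values()) == set(g.nodes)

    def test_log2_binning_preserves_degrees_up_to_bin(self):
        g = nx.gnp_random_graph(80, 0.08, seed=2)
        degrees = dict(g.degree())
        mapping = degree_preserving_permutation(g, 5, degree_binning="log2")
        moved = sum(1 for a, b in mapping.items() if a != b)
        assert moved > 0
        for old, new in mapping.items():
            bin_old = degrees[old].bit_length() if degrees[old] else 0
            bin_new = degrees[new].bit_length() if degrees[new] else 0
            assert bin_old == bin_new

    def test_unknown_binning_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            degree_preserving_permutation(g, 0, degree_binning="sqrt")

    def test_all_singleton_classes_is_identity(self, caplog):
        # in a simple graph with >= 2 nodes some pair always shares a degree,
        # so the only all-singleton case is a single node
        g = nx.Graph()
        g.add_node("solo")
        with caplog.at_level("WARNING"):
            mapping = degree_preserving_permutation(g, 0)
        assert mapping == {"solo": "solo"}
        assert "identity" in caplog.text


class TestNeighborOverlapNull:
    def _planted_graph(self, n_shared=8, n_background=200, n_decoys=40, seed=0):
        """Two hubs in different 'runs' wired to one shared neighbor block,
        plus degree-matched decoy hubs wired to random background nodes (so
        a within-degree permutation can actually displace the hubs)."""
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        shared = [f"shared{i}" for i in range(n_shared)]
        nodes = [f"bg{i}" for i in range(n_background)]
        for hub in ("hubA", "hubB"):
            for nb in shared:
                g.add_edge(hub, nb, score=0.9)
        for d in range(n_decoys):
            targets = rng.choice(nodes, n_shared, replace=False)
            for nb in targets:
                g.add_edge(f"decoy{d}", nb, score=0.9)
        for _ in range(n_background * 2):
            u, v = rng.choice(nodes, 2, replace=False)
            g.add_edge(u, v, score=0.9)
        return InteractomeGraph(graph=g)

    def test_planted_shared_neighborhood_is_significant(self):
        graph = self._planted_graph()
        de_genes = {f"shared{i}" for i in range(8)}
        result = neighbor_overlap_null_test(
            {"runA": {"hubA"}, "runB": {"hubB"}},
            graph,
            {"runA": de_genes, "runB": de_genes},
            n_networks=200, seed=1,
        )
        assert result.average_offdiag == 1.0
        assert result.permutation_p <= 0.01

    def test_single_network_beats_gives_half(self):
        graph = self._planted_graph()
        de_genes = {f"shared{i}" for i in range(8)}
        result = neighbor_overlap_null_test(
            {"runA": {"hubA"}, "runB": {"hubB"}},
            graph, {"runA": de_genes, "runB": de_genes},
            n_networks=1, seed=2,
        )
        assert result.permutation_p in (0.5, 1.0)

    def test_empty_hub_sets_rejected(self):
        graph = self._planted_graph()
        with pytest.raises(ValueError):
            neighbor_overlap_null_test(
                {"a": set(), "b": set()}, graph, {"a": set(), "b": set()}, 10, 0
            )


class TestCrossRunSummary:
    def test_flag_thresholds(self):
        runs = {f"r{i}": {"g"} for i in range(7)}
        de = {r: _de({"g": (0.6, 0.01)}) for r in runs}
        out = cross_run_gene_summary(runs, de)
        assert out.loc["g", "run_count"] == 7
        assert bool(out.loc["g", "flagged"])

        runs6 = {f"r{i}": {"g"} for i in range(6)}
        out6 = cross_run_gene_summary(runs6, {r: de["r0"] for r in runs6})
        assert not bool(out6.loc["g", "flagged"])  # "more than six" is strict

    def test_single_run_median_is_that_run(self):
        out = cross_run_gene_summary({"r0": {"g"}}, {"r0": _de({"g": (0.42, 0.2)})})
        assert out.loc["g", "run_count"] == 1
        assert out.loc["g", "median_log2fc"] == pytest.approx(0.42)
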