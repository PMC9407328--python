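"""Module network export, annotation filter, centralities, hub selection."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import hubs as ch
from coexnet import network as cn
from coexnet.datatypes import AnnotationTable
from coexnet.errors import CoexnetError, ValidationError
from coexnet.modules import assign_colors


def net_from_edges(edges, nodes=None, module="blue"):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return ch.WeightedNetwork(graph=g, module=module)


def annotation_for(genes):
    return AnnotationTable(
        pd.DataFrame(
            {
                "swissprot_id": [f"P{i:05d}" for i in range(len(genes))],
                "description": [f"protein {g}" for g in genes],
            },
            index=pd.Index(list(genes), name="gene_id"),
        )
    )


def uniform_tom(genes, value=0.5):
    n = len(genes)
    m = np.full((n, n), value)
    np.fill_diagonal(m, 1.0)
    return cn.TOMMatrix(matrix=m, gene_ids=list(genes))


class TestExportModuleNetwork:
    def setup_method(self):
        self.genes = ["a", "b", "c"]
        self.assign = assign_colors(self.genes, [1, 1, 1])
        self.color = self.assign.label_to_color[1]

    def test_threshold_above_max_gives_edgeless(self):
        tom = uniform_tom(self.genes, 0.5)
        net = ch.export_module_network(tom, self.assign, self.color, threshold=0.6)
        assert net.n_nodes == 3 and net.n_edges == 0

    def test_three_edges_at_threshold_below(self):
        tom = uniform_tom(self.genes, 0.5)
        net = ch.export_module_network(tom, self.assign, self.color, threshold=0.4)
        assert net.n_edges == 3

    def test_zero_threshold_complete_graph(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(6)]
        m = rng.uniform(0.05, 0.9, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        tom = cn.TOMMatrix(matrix=m, gene_ids=genes)
        assign = assign_colors(genes, [1] * 6)
        net = ch.export_module_network(tom, assign, assign.label_to_color[1], 0.0)
        assert net.n_edges == 15

    def test_missing_module_errors(self):
        tom = uniform_tom(self.genes)
        with pytest.raises(KeyError):
            ch.export_module_network(tom, self.assign, "magenta", 0.1)


class TestFilterAnnotated:
    def test_identity_when_all_annotated(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.5)])
        out = ch.filter_annotated(net, annotation_for(["a", "b", "c"]))
        assert out.edges() == net.edges()

    def test_complete_graph_loses_incident_edges(self):
        genes = list("abcde")
        edges = [
            (u, v, 0.5) for i, u in enumerate(genes) for v in genes[i + 1 :]
        ]
        net = net_from_edges(edges)
        out = ch.filter_annotated(net, annotation_for(["a", "b", "c"]))
        assert out.n_nodes == 3 and out.n_edges == 3
        for u, v, _ in out.edges():
            assert u in "abc" and v in "abc"

    def test_no_annotated_nodes_is_error(self):
        net = net_from_edges([("a", "b", 0.5)])
        with pytest.raises(CoexnetError):
            ch.filter_annotated(net, annotation_for(["x"]))


class TestDegree:
    def test_isolated_node(self):
        net = net_from_edges([("a", "b", 0.5)], nodes=["a", "b", "c"])
        assert ch.degree(net)["c"] == 0.0
        assert ch.degree(net, weighted=True)["c"] == 0.0

    def test_weighted_vs_unweighted(self):
        net = net_from_edges([("a", "b", 0.5), ("a", "c", 0.5)])
        assert ch.degree(net)["a"] == 2.0
        assert ch.degree(net, weighted=True)["a"] == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(15, 0.4, seed=2)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        net = ch.WeightedNetwork(graph=nx.relabel_nodes(g, str), module="m")
        deg = ch.degree(net)
        wdeg = ch.degree(net, weighted=True)
        for node in net.node_ids:
            count, total = 0, 0.0
            for u, v, w in net.edges():
                if node in (u, v):
                    count += 1
                    total += w
            assert deg[node] == count
            assert wdeg[node] == pytest.approx(total, abs=1e-12)


class TestTopKSubnetwork:
    def test_k_at_least_n_keeps_everything(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.5)])
        out = ch.top_k_subnetwork(net, k=10)
        assert out.edges() == net.edges()

    def test_star_with_tie_rule(self):
        edges = [("hub", leaf, 0.2) for leaf in "abcde"]
        # leaf 'a' gets extra weight so it wins the weighted-degree tie-break
        edges[0] = ("hub", "a", 0.9)
        net = net_from_edges(edges)
        out = ch.top_k_subnetwork(net, k=2)
        assert set(out.node_ids) == {"hub", "a"}
        assert out.n_edges == 1

    def test_induced_subgraph_property(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(20, 0.3, seed=5)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        net = ch.WeightedNetwork(graph=nx.relabel_nodes(g, str), module="m")
        out = ch.top_k_subnetwork(net, k=8)
        keep = set(out.node_ids)
        expected = {
            (u, v, w) for u, v, w in net.edges() if u in keep and v in keep
        }
        assert set(out.edges()) == expected

    def test_idempotent_when_k_covers(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.4)])
        once = ch.top_k_subnetwork(net, k=3)
        twice = ch.top_k_subnetwork(once, k=3)
        assert once.edges() == twice.edges()


class TestEigenvectorCentrality:
    def test_complete_graph_all_equal(self):
        genes = list("abcd")
        edges = [(u, v, 0.7) for i, u in enumerate(genes) for v in genes[i + 1 :]]
        ec = ch.eigenvector_centrality(net_from_edges(edges))
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in ec.values())

    def test_star_closed_form(self):
        leaves = list("abcde")
        net = net_from_edges([("hub", leaf, 0.3) for leaf in leaves])
        ec = ch.eigenvector_centrality(net)
        assert ec["hub"] == pytest.approx(1.0)
        expected_leaf = 1.0 / math.sqrt(len(leaves))
        for leaf in leaves:
            assert ec[leaf] == pytest.approx(expected_leaf, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_eigensolver_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(12, 0.5, seed=seed + 10)
        while not nx.is_connected(g):
            g = nx.gnp_random_graph(12, 0.5, seed=rng.integers(1000))
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        net = ch.WeightedNetwork(graph=nx.relabel_nodes(g, str), module="m")
        ec = ch.eigenvector_centrality(net)
        nodes = net.node_ids
        A = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
        w, v = np.linalg.eigh(A)
        principal = np.abs(v[:, np.argmax(w)])
        principal = principal / principal.max()
        for node, expected in zip(nodes, principal):
            assert ec[node] == pytest.approx(expected, abs=1e-8)

    def test_disconnected_largest_component(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", 0.5), ("x", "y", 0.5)])
        with pytest.warns(UserWarning, match="disconnected"):
            ec = ch.eigenvector_centrality(net)
        assert ec["x"] == 0.0 and ec["y"] == 0.0
        assert ec["b"] == 1.0


class TestBetweenness:
    def test_complete_graph_is_zero(self):
        genes = list("abcdef")
        edges = [(u, v, 0.5) for i, u in enumerate(genes) for v in genes[i + 1 :]]
        bc = ch.betweenness(net_from_edges(edges))
        assert all(v == 0.0 for v in bc.values())

    def test_path_center(self):
        bc = ch.betweenness(net_from_edges([("a", "b", 0.9), ("b", "c", 0.1)]))
        assert bc["b"] == 1.0 and bc["a"] == 0.0 and bc["c"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_path_enumeration(self, seed):
        g = nx.gnp_random_graph(10, 0.35, seed=seed)
        nx.set_edge_attributes(g, 0.5, "weight")
        net = ch.WeightedNetwork(graph=nx.relabel_nodes(g, str), module="m")
        bc = ch.betweenness(net)
        nodes = net.node_ids
        oracle = {n: 0.0 for n in nodes}
        for i, s in enumerate(nodes):
            for t in nodes[i + 1 :]:
                paths = _all_shortest_paths(net.graph, s, t)
                if not paths:
                    continue
                for mid in nodes:
                    if mid in (s, t):
                        continue
                    through = sum(1 for p in paths if mid in p)
                    oracle[mid] += through / len(paths)
        for n in nodes:
            assert bc[n] == pytest.approx(oracle[n], abs=1e-9)


def _all_shortest_paths(graph, s, t):
    """Exhaustive unweighted shortest-path enumeration by depth-limited DFS."""
    try:
        dist = nx.shortest_path_length(graph, s, t)
    except nx.NetworkXNoPath:
        return []
    paths = []

    def walk(node, seen):
        if len(seen) - 1 > dist:
            return
        if node == t and len(seen) - 1 == dist:
            paths.append(list(seen))
            return
        for nb in graph[node]:
            if nb not in seen:
                walk(nb, seen + [nb])

    walk(s, [s])
    return paths


class TestSelectHubsAndCompare:
    def build_table(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        nodes = [f"g{i:02d}" for i in range(n)]
        table = pd.DataFrame(
            {
                "degree": rng.integers(1, n, size=n).astype(float),
                "weighted_degree": rng.uniform(0, 10, size=n),
                "eigenvector": rng.uniform(0, 1, size=n),
                "betweenness": np.zeros(n),
            },
            index=nodes,
        )
        return ch.CentralityTable(table=table, module="blue")

    def test_fraction_counts(self):
        ct100 = self.build_table(100)
        assert len(ch.select_hubs(ct100, hub_fraction=0.10)) == 10
        ct7 = self.build_table(7)
        assert len(ch.select_hubs(ct7, hub_fraction=0.10)) == 1
        assert len(ch.select_hubs(ct7, hub_fraction=1.0)) == 7

    def test_sorted_by_key_descending(self):
        ct = self.build_table(30)
        hubs = ch.select_hubs(ct, sort_key="weighted_degree", hub_fraction=0.2)
        vals = hubs["weighted_degree"].to_numpy()
        assert np.all(np.diff(vals) <= 0)
        assert list(hubs["hub_rank"]) == list(range(1, len(hubs) + 1))

    def test_compare_identical_and_reversed(self):
        order = [f"g{i}" for i in range(15)]
        same, disp = ch.compare_rankings(order, order, top_n=10)
        assert same and all(v == 0 for v in disp.values())
        reversed_top = order[:10][::-1] + order[10:]
        same, disp = ch.compare_rankings(order, reversed_top, top_n=10)
        assert same
        assert disp["g0"] == -9 and disp["g9"] == 9

    def test_compare_requires_same_universe(self):
        with pytest.raises(ValidationError):
            ch.compare_rankings(["a", "b"], ["a", "c"])


class TestScreenOnPreset:
    def test_planted_hubs_recovered(self, preset_data, preset_result):
        from conftest import detected_to_true

        _, _, _, truth = preset_data
        res = preset_result
        mapping = detected_to_true(res.assignment, truth, res.expression.gene_ids)
        assert len(res.hub_report.modules) == 2
        for color, df in res.hub_report.modules.items():
            planted = set(truth.planted_hub_ids[mapping[color]])
            assert len(planted & set(df.index)) >= 8
            assert res.hub_report.comparisons[color]["same_set"]

    def test_hub_count_conservation(self, preset_result):
        res = preset_result
        cfg = res.config
        expected = 0
        for color in res.significant_modules:
            net = ch.export_module_network(
                res.tom, res.assignment, color, threshold=cfg.export_threshold
            )
            net = ch.filter_annotated(net, res.annotations)
            stage1 = min(cfg.top_k, net.n_nodes)
            expected += math.ceil(cfg.hub_fraction * stage1)
        assert res.hub_report.total_hubs == expected

    def test_weighted_degree_order_matches_tom_row_sums(self, preset_result):
        """On a complete module network the weighted-degree order equals the
        order of TOM row sums restricted to the module."""
        res = preset_result
        color = res.significant_modules[0]
        genes = res.assignment.genes_of_color(color)
        net = ch.export_module_network(res.tom, res.assignment, color, threshold=0.0)
        wdeg = ch.degree(net, weighted=True)
        index = {g: i for i, g in enumerate(res.tom.gene_ids)}
        rows = {
            g: res.tom.matrix[index[g], [index[h] for h in genes if h != g]].sum()
            for g in genes
        }
        order_net = sorted(genes, key=lambda g: (-wdeg[g], g))
        order_tom = sorted(genes, key=lambda g: (-rows[g], g))
        assert order_net == order_tom
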