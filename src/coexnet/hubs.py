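"""Two-stage centrality screen for hub genes in trait-associated modules.

A module's TOM subnetwork is exported at an edge threshold, unannotated
nodes are removed, the induced subgraph of the top-k nodes by unweighted
degree is taken (stage 1), and the top fraction by a weighted centrality
(weighted degree by default, eigenvector as the cross-check) are the hubs
(stage 2). Rankings under weighted degree and eigenvector centrality are
compared per module.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AnnotationTable
from .errors import ConvergenceError, CoexnetError, ParameterError, ValidationError
from .modules import ModuleAssignment
from .network import TOMMatrix

__all__ = [
    "WeightedNetwork",
    "CentralityTable",
    "HubReport",
    "export_module_network",
    "filter_annotated",
    "degree",
    "top_k_subnetwork",
    "eigenvector_centrality",
    "betweenness",
    "centrality_table",
    "select_hubs",
    "compare_rankings",
    "screen_hubs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected weighted network (TOM-unit weights) tagged with a module color."""

    graph: nx.Graph
    module: str = "unknown"

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight")
            if w is None or not np.isfinite(w) or w <= 0:
                raise ValidationError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        """Deterministically ordered (u, v, weight) triples with u < v."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = (u, v) if str(u) <= str(v) else (v, u)
            out.append((a, b, float(data["weight"])))
        return sorted(out)


@dataclass(frozen=True)
class CentralityTable:
    """Per-node centralities and ranks (rank 1 = most central)."""

    table: pd.DataFrame  # index: node; columns: degree, weighted_degree,
    # eigenvector, betweenness, *_rank
    module: str = "unknown"


@dataclass(frozen=True)
class HubReport:
    """Per-module hub lists plus the DC-vs-EC rank-agreement summary."""

    modules: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)

    @property
    def total_hubs(self) -> int:
        return sum(len(df) for df in self.modules.values())

    def all_hubs(self) -> pd.DataFrame:
        frames = []
        for color, df in self.modules.items():
            d = df.copy()
            d.insert(0, "module", color)
            frames.append(d)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, axis=0)


def export_module_network(
    tom: TOMMatrix,
    assign: ModuleAssignment,
    module: str,
    threshold: float = 0.02,
) -> WeightedNetwork:
    """Build the weighted network of one module: edges where TOM >= threshold."""
    if not 0 <= threshold < 1:
        raise ParameterError("threshold must be in [0, 1)")
    genes = assign.genes_of_color(module)
    if not genes:
        raise CoexnetError(f"module {module!r} is empty")
    index = {g: i for i, g in enumerate(tom.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValidationError(f"module genes absent from TOM: {missing[:3]}")
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    m = tom.matrix
    for a in range(len(genes)):
        ia = index[genes[a]]
        for b in range(a + 1, len(genes)):
            w = float(m[ia, index[genes[b]]])
            if w >= threshold and w > 0:
                graph.add_edge(genes[a], genes[b], weight=w)
    return WeightedNetwork(graph=graph, module=module)


def filter_annotated(net: WeightedNetwork, ann: AnnotationTable) -> WeightedNetwork:
    """Keep only Swiss-Prot-annotated nodes (and edges among them)."""
    keep = [n for n in net.graph.nodes if ann.is_annotated(n)]
    if not keep:
        raise CoexnetError(f"module {net.module!r} has no annotated nodes")
    return WeightedNetwork(graph=net.graph.subgraph(keep).copy(), module=net.module)


def degree(net: WeightedNetwork, weighted: bool = False) -> dict[str, float]:
    """Unweighted degree (neighbor count) or weighted degree (incident weight sum)."""
    if weighted:
        return {n: float(d) for n, d in net.graph.degree(weight="weight")}
    return {n: float(d) for n, d in net.graph.degree()}


def top_k_subnetwork(net: WeightedNetwork, k: int = 100) -> WeightedNetwork:
    """Induced subgraph on the k nodes of largest unweighted degree.

    Ties are broken by higher weighted degree, then lexicographic node ID.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    deg = degree(net, weighted=False)
    wdeg = degree(net, weighted=True)
    ranked = sorted(net.graph.nodes, key=lambda n: (-deg[n], -wdeg[n], str(n)))
    keep = ranked[:k]
    return WeightedNetwork(graph=net.graph.subgraph(keep).copy(), module=net.module)


def eigenvector_centrality(
    net: WeightedNetwork, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, normalized to max 1.

    Computed by power iteration on the largest connected component; nodes of
    other components score 0 (with a warning).
    """
    nodes = net.node_ids
    if not nodes:
        return {}
    components = sorted(nx.connected_components(net.graph), key=len, reverse=True)
    scores = {n: 0.0 for n in nodes}
    if not components:
        return scores
    if len(components) > 1:
        warnings.warn(
            "network is disconnected; eigenvector centrality computed on the "
            "largest component, others set to 0"
        )
    comp = sorted(components[0])
    if len(comp) == 1:
        scores[comp[0]] = 1.0
        return scores
    A = nx.to_numpy_array(net.graph, nodelist=comp, weight="weight")
    # Shift by +I: same eigenvectors, but the principal eigenvalue becomes
    # strictly dominant, so power iteration converges on bipartite graphs too.
    A = A + np.eye(len(comp))
    x = np.full(len(comp), 1.0 / math.sqrt(len(comp)))
    for iteration in range(1, max_iter + 1):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y = y / norm
        if np.max(np.abs(y - x)) < tol * max(np.max(np.abs(y)), 1e-300):
            x = y
            break
        x = y
    else:
        raise ConvergenceError(
            f"eigenvector centrality did not converge in {max_iter} iterations"
        )
    x = np.abs(x)
    x = x / x.max()
    for n, v in zip(comp, x):
        scores[n] = float(v)
    return scores


def betweenness(net: WeightedNetwork) -> dict[str, float]:
    """Node betweenness with unweighted shortest paths (edges count as hops),
    equal splitting among equally short paths, each unordered pair counted once."""
    bc = nx.betweenness_centrality(net.graph, normalized=False, weight=None)
    return {n: float(v) for n, v in bc.items()}


def _rank(series: pd.Series, secondary: pd.Series) -> pd.Series:
    """Dense 1-based ranking, descending, ties by secondary then node ID."""
    order = sorted(
        series.index, key=lambda n: (-series[n], -secondary[n], str(n))
    )
    return pd.Series({n: i + 1 for i, n in enumerate(order)}, name=None)


def centrality_table(net: WeightedNetwork) -> CentralityTable:
    """All four centralities plus deterministic ranks for each node."""
    nodes = net.node_ids
    deg = pd.Series(degree(net, weighted=False)).reindex(nodes)
    wdeg = pd.Series(degree(net, weighted=True)).reindex(nodes)
    ec = pd.Series(eigenvector_centrality(net)).reindex(nodes)
    bc = pd.Series(betweenness(net)).reindex(nodes)
    table = pd.DataFrame(
        {
            "degree": deg,
            "weighted_degree": wdeg,
            "eigenvector": ec,
            "betweenness": bc,
        }
    )
    table["degree_rank"] = _rank(deg, wdeg)
    table["weighted_degree_rank"] = _rank(wdeg, ec)
    table["eigenvector_rank"] = _rank(ec, wdeg)
    table["betweenness_rank"] = _rank(bc, wdeg)
    table.index.name = "node"
    return CentralityTable(table=table, module=net.module)


def select_hubs(
    ct: CentralityTable,
    sort_key: str = "weighted_degree",
    hub_fraction: float = 0.10,
) -> pd.DataFrame:
    """Top ceil(hub_fraction * n) nodes by the sort key, deterministically tied.

    Ties are broken by the other weighted centrality (eigenvector for
    weighted-degree sorting and vice versa), then lexicographic node ID.
    """
    if not 0 < hub_fraction <= 1:
        raise ParameterError("hub_fraction must be in (0, 1]")
    if sort_key not in ("weighted_degree", "eigenvector"):
        raise ParameterError("sort_key must be 'weighted_degree' or 'eigenvector'")
    other = "eigenvector" if sort_key == "weighted_degree" else "weighted_degree"
    t = ct.table
    n_hubs = math.ceil(hub_fraction * len(t))
    order = sorted(
        t.index, key=lambda node: (-t.loc[node, sort_key], -t.loc[node, other], str(node))
    )
    hubs = t.loc[order[:n_hubs]].copy()
    hubs.insert(0, "hub_rank", np.arange(1, len(hubs) + 1))
    return hubs


def compare_rankings(
    dc_rank: list[str], ec_rank: list[str], top_n: int = 10
) -> tuple[bool, dict[str, int]]:
    """Compare the top-n gene sets and per-gene rank displacement of two rankings.

    Displacement is (position under DC) - (position under EC) for genes in the
    union of the two top-n lists; positive means the gene ranks higher (closer
    to 1) under EC.
    """
    if set(dc_rank) != set(ec_rank):
        raise ValidationError("rankings must cover the identical node universe")
    top_dc = list(dc_rank[:top_n])
    top_ec = list(ec_rank[:top_n])
    same_set = set(top_dc) == set(top_ec)
    pos_dc = {g: i for i, g in enumerate(dc_rank)}
    pos_ec = {g: i for i, g in enumerate(ec_rank)}
    displacement = {
        g: pos_dc[g] - pos_ec[g] for g in sorted(set(top_dc) | set(top_ec))
    }
    return same_set, displacement


def screen_hubs(
    tom: TOMMatrix,
    assign: ModuleAssignment,
    annotations: AnnotationTable,
    modules: list[str],
    threshold: float = 0.02,
    top_k: int = 100,
    hub_fraction: float = 0.10,
    sort_key: str = "weighted_degree",
) -> HubReport:
    """Run the full two-stage screen over the given modules.

    Per module: export the TOM subnetwork, drop unannotated nodes, take the
    induced top-k subgraph by unweighted degree, compute weighted centralities,
    and keep the top hub_fraction by the sort key. The report also records
    whether the top hub sets under weighted degree and eigenvector centrality
    coincide.
    """
    report_modules: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, dict] = {}
    for color in modules:
        net = export_module_network(tom, assign, color, threshold=threshold)
        net = filter_annotated(net, annotations)
        sub = top_k_subnetwork(net, k=top_k)
        ct = centrality_table(sub)
        hubs = select_hubs(ct, sort_key=sort_key, hub_fraction=hub_fraction)
        hubs["description"] = [
            annotations.description(g) or "NA" for g in hubs.index
        ]
        report_modules[color] = hubs
        t = ct.table
        dc_order = sorted(
            t.index,
            key=lambda n: (-t.loc[n, "weighted_degree"], -t.loc[n, "eigenvector"], str(n)),
        )
        ec_order = sorted(
            t.index,
            key=lambda n: (-t.loc[n, "eigenvector"], -t.loc[n, "weighted_degree"], str(n)),
        )
        same_set, displacement = compare_rankings(dc_order, ec_order, top_n=len(hubs))
        comparisons[color] = {"same_set": same_set, "displacement": displacement}
        logger.info(
            "module %s: %d nodes after annotation filter, %d in top-%d subnetwork, "
            "%d hubs (DC/EC top sets %s)",
            color,
            net.n_nodes,
            sub.n_nodes,
            top_k,
            len(hubs),
            "identical" if same_set else "different",
        )
    return HubReport(modules=report_modules, comparisons=comparisons)
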