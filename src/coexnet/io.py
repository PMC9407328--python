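"""Readers and writers for every table the pipeline touches.

Dialect: tab-separated, UTF-8, "." decimal, no quoting. Expression tables are
genes-in-rows on disk; correlation work transposes internally. Network files
use the Cytoscape edge/node layout (fromNode, toNode, weight, direction,
fromAltName, toAltName / nodeName, altName, nodeAttr).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AnnotationTable, ExpressionMatrix, TraitTable
from .errors import FormatError, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_trait",
    "write_trait",
    "read_annotation",
    "write_annotation",
    "write_cytoscape_network",
    "read_cytoscape_edges",
    "read_module_assignment",
    "write_module_assignment",
]

_SEP = "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=_SEP, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            # numpy's parser round-trips float64 exactly (pd.to_numeric does not)
            out[col] = df[col].to_numpy(dtype=str).astype(np.float64)
        except ValueError:
            for row, value in df[col].items():
                try:
                    float(value)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value in column {col!r}, row {row!r}"
                    ) from None
            raise FormatError(f"{path}: non-numeric column {col!r}") from None
    return pd.DataFrame(out, index=df.index)


def read_expression(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read an expression table; one header row of IDs, one ID column."""
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _to_numeric(_read_table(path), path)
    if orientation == "samples-in-rows":
        df = df.T
    idx = pd.Index(df.index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    cols = pd.Index(df.columns)
    if cols.has_duplicates:
        dup = cols[cols.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep=_SEP, index_label="gene_id")


def read_trait(path) -> TraitTable:
    """Read a two-column TSV (sample_id, wax secretion in mg/individual)."""
    df = _to_numeric(_read_table(path), path)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: trait table must have exactly two columns")
    series = df.iloc[:, 0]
    series.name = df.columns[0]
    return TraitTable(series)


def write_trait(trait: TraitTable, path) -> None:
    name = trait.values.name or "wax_secretion"
    trait.values.rename(name).to_csv(path, sep=_SEP, index_label="sample_id")


def read_annotation(path) -> AnnotationTable:
    df = _read_table(path)
    if not {"swissprot_id", "description"} <= set(df.columns):
        raise FormatError(
            f"{path}: annotation table needs columns swissprot_id, description"
        )
    idx = pd.Index(df.index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    return AnnotationTable(df[["swissprot_id", "description"]])


def write_annotation(ann: AnnotationTable, path) -> None:
    ann.data.to_csv(path, sep=_SEP, index_label="gene_id")


def write_cytoscape_network(net, edge_path, node_path, annotations: AnnotationTable) -> None:
    """Write Cytoscape-importable edge and node files for a weighted network.

    Edge columns: fromNode, toNode, weight, direction, fromAltName, toAltName
    (direction is always "undirected"; AltName is the annotation description or
    "NA"). Node columns: nodeName, altName, nodeAttr (the module color).
    """
    from .hubs import WeightedNetwork  # local import to avoid a cycle

    if not isinstance(net, WeightedNetwork):
        raise TypeError("net must be a WeightedNetwork")

    def alt(gene: str) -> str:
        desc = annotations.description(gene)
        return desc if desc is not None else "NA"

    with open(edge_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("fromNode\ttoNode\tweight\tdirection\tfromAltName\ttoAltName\n")
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{float(w)!r}\tundirected\t{alt(u)}\t{alt(v)}\n")
    with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("nodeName\taltName\tnodeAttr\n")
        for node in net.node_ids:
            fh.write(f"{node}\t{alt(node)}\t{net.module}\n")


def read_cytoscape_edges(edge_path, node_path=None, module: str = "unknown"):
    """Rebuild a WeightedNetwork from its exported edge (and optional node) file."""
    from .hubs import WeightedNetwork

    edges = pd.read_csv(edge_path, sep=_SEP, dtype={"fromNode": str, "toNode": str})
    required = {"fromNode", "toNode", "weight"}
    if not required <= set(edges.columns):
        raise FormatError(f"{edge_path}: edge file needs columns {sorted(required)}")
    graph = nx.Graph()
    if node_path is not None:
        nodes = pd.read_csv(node_path, sep=_SEP, dtype=str)
        if "nodeName" not in nodes.columns:
            raise FormatError(f"{node_path}: node file needs a nodeName column")
        graph.add_nodes_from(nodes["nodeName"])
        if "nodeAttr" in nodes.columns and len(nodes):
            module = str(nodes["nodeAttr"].iloc[0])
    for u, v, w in edges[["fromNode", "toNode", "weight"]].itertuples(index=False):
        graph.add_edge(str(u), str(v), weight=float(w))
    return WeightedNetwork(graph=graph, module=module)


def read_module_assignment(path):
    """Read a gene -> (label, color) table written by write_module_assignment."""
    from .modules import ModuleAssignment

    df = pd.read_csv(path, sep=_SEP, dtype={"gene_id": str, "label": int, "color": str})
    for col in ("gene_id", "label", "color"):
        if col not in df.columns:
            raise FormatError(f"{path}: module table needs column {col!r}")
    label_to_color = {}
    for lab, col in zip(df["label"], df["color"]):
        label_to_color[int(lab)] = str(col)
    label_to_color.setdefault(0, "grey")
    return ModuleAssignment(
        gene_ids=list(df["gene_id"]),
        labels=df["label"].to_numpy(dtype=int),
        label_to_color=label_to_color,
    )


def write_module_assignment(assign, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": assign.gene_ids,
            "label": assign.labels,
            "color": [assign.label_to_color[int(l)] for l in assign.labels],
        }
    )
    df.to_csv(path, sep=_SEP, index=False)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
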