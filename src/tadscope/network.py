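"""Typed miRNA-mRNA-lncRNA regulatory network assembly and ranking.

Nodes are RNA features (class + DE direction); edges are typed:
``mirna_target`` (directed, always miRNA -> target), ``lnc_coexpr``
(undirected lncRNA-mRNA co-expression) and optional ``ppi`` (undirected).
The same node pair may carry edges of several types. Degree ranking, module
subnetwork extraction and SIF/GraphML/TSV export round out the published
network workflow (layout/visualization is out of scope — files are written
for external viewers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_TYPES = ("mirna_target", "lnc_coexpr", "ppi")
DIRECTED_TYPES = frozenset({"mirna_target"})


def _canonical(src: str, dst: str, etype: str) -> tuple[str, str, str]:
    if etype in DIRECTED_TYPES:
        return (src, dst, etype)
    a, b = sorted((src, dst))
    return (a, b, etype)


@dataclass
class RegNetwork:
    """Typed node/edge container with set semantics (no parallel duplicates
    of the same (src, dst, type), no self-loops)."""

    nodes: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (class, direction)
    edges: set = field(default_factory=set)  # {(src, dst, etype)}

    def add_node(self, node: str, rna_class: str, direction: str = "none") -> None:
        if node in self.nodes and self.nodes[node][0] != rna_class:
            raise ValueError(
                f"class conflict for node {node!r}: {self.nodes[node][0]} vs {rna_class}"
            )
        self.nodes[node] = (rna_class, direction)

    def add_edge(self, src: str, dst: str, etype: str) -> None:
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        if src == dst:
            raise ValueError(f"self-loop on {src!r}")
        if src not in self.nodes or dst not in self.nodes:
            raise ValueError("edge endpoints must be added as nodes first")
        if etype == "mirna_target" and self.nodes[src][0] != "miRNA":
            raise ValueError(f"mirna_target source {src!r} is not a miRNA")
        self.edges.add(_canonical(src, dst, etype))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[str, str, str]]:
        return sorted(self.edges)

    def components(self) -> list[set]:
        """Connected components of the undirected view, largest first."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((s, d) for s, d, _ in self.edges)
        comps = [set(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))


# ----------------------------------------------------------------------
# construction


def build_mirna_edges(
    de_mirnas, de_genes, target_table: pd.DataFrame, restrict_to_de: bool = False
) -> set:
    """miRNA-target edges for DE miRNAs.

    By default all targets of a DE miRNA are kept (DE genes are mapped onto
    the network afterwards); ``restrict_to_de`` keeps only targets that are
    themselves DE genes. Malformed rows are skipped with their line logged.
    """
    de_mirnas = set(de_mirnas)
    de_genes = set(de_genes)
    edges = set()
    for i, row in enumerate(target_table.itertuples(index=False)):
        mir, tgt = getattr(row, "miRNA_id", None), getattr(row, "target_id", None)
        if not isinstance(mir, str) or not isinstance(tgt, str) or not mir or not tgt:
            logger.warning("build_mirna_edges: skipping malformed row %d", i)
            continue
        if mir not in de_mirnas:
            continue
        if restrict_to_de and tgt not in de_genes:
            continue
        if mir != tgt:
            edges.add((mir, tgt, "mirna_target"))
    return edges


def merge_network(
    mirna_edges: set,
    pcc_pairs: pd.DataFrame | None = None,
    ppi_edges: pd.DataFrame | None = None,
    classes: dict | pd.Series | None = None,
    directions: dict | pd.Series | None = None,
) -> RegNetwork:
    """Union of typed edge sets into one RegNetwork.

    ``classes`` maps node id -> RNA class (required for every endpoint;
    conflicting classes for one id raise). ``directions`` maps node id ->
    up/down (anything absent is "none").
    """
    classes = dict(classes or {})
    directions = dict(directions or {})
    net = RegNetwork()

    def ensure(node: str, fallback_class: str | None = None):
        cls = classes.get(node, fallback_class)
        if cls is None:
            raise ValueError(f"no RNA class known for node {node!r}")
        net.add_node(node, cls, directions.get(node, "none"))

    for src, dst, etype in sorted(mirna_edges):
        ensure(src, "miRNA")
        ensure(dst, "mRNA")
        net.add_edge(src, dst, etype)
    if pcc_pairs is not None:
        for row in pcc_pairs.itertuples(index=False):
            ensure(row.lnc_id, "lncRNA")
            ensure(row.mrna_id, "mRNA")
            net.add_edge(row.lnc_id, row.mrna_id, "lnc_coexpr")
    if ppi_edges is not None:
        for row in ppi_edges.itertuples(index=False):
            a, b = row[0], row[1]
            if a == b:
                continue
            ensure(a, "mRNA")
            ensure(b, "mRNA")
            net.add_edge(a, b, "ppi")
    return net


# ----------------------------------------------------------------------
# analysis


def degree_ranking(net: RegNetwork, top_n: int = 20) -> pd.DataFrame:
    """Nodes ranked by total degree (descending, ties by node id).

    in/out degrees count directed (mirna_target) edges only; undirected
    edges contribute to the total degree of both endpoints.
    """
    deg = {node: 0 for node in net.nodes}
    indeg = {node: 0 for node in net.nodes}
    outdeg = {node: 0 for node in net.nodes}
    for src, dst, etype in net.edges:
        deg[src] += 1
        deg[dst] += 1
        if etype in DIRECTED_TYPES:
            outdeg[src] += 1
            indeg[dst] += 1
    rows = [
        {
            "node_id": node,
            "rna_class": net.nodes[node][0],
            "degree": deg[node],
            "in_degree": indeg[node],
            "out_degree": outdeg[node],
        }
        for node in sorted(net.nodes, key=lambda x: (-deg[x], x))
    ]
    return pd.DataFrame(
        rows, columns=["node_id", "rna_class", "degree", "in_degree", "out_degree"]
    ).head(top_n)


def extract_module_subnetwork(
    net: RegNetwork, labels: dict | pd.Series, selected
) -> tuple[RegNetwork, list[set]]:
    """Edges touching a selected co-expression module, plus incident miRNAs.

    ``labels`` covers mRNA/lncRNA nodes (miRNAs are unlabelled); an edge is
    kept when at least one endpoint belongs to a selected module. Returns
    the subnetwork and its connected components (the published picture is
    several small subnetworks rather than one giant component).
    """
    labels = dict(labels)
    known = set(labels.values())
    unknown = [m for m in selected if m not in known]
    if unknown:
        raise ValueError(f"unknown module name(s): {unknown}")
    selected = set(selected)

    def in_selected(node: str) -> bool:
        return labels.get(node) in selected

    sub = RegNetwork()
    for src, dst, etype in net.sorted_edges():
        if in_selected(src) or in_selected(dst):
            for node in (src, dst):
                cls, direction = net.nodes[node]
                sub.add_node(node, cls, direction)
            sub.add_edge(src, dst, etype)
    return sub, sub.components()


# ----------------------------------------------------------------------
# export / import


def export_graph(net: RegNetwork, path, format: str = "graphml") -> None:
    """Write the network as SIF, GraphML or an edge TSV.

    GraphML is lossless for nodes, edges and their types; SIF uses the edge
    type as relation token (edges only); the TSV carries src/etype/dst.
    """
    if format == "sif":
        with open(path, "w") as fh:
            for src, dst, etype in net.sorted_edges():
                fh.write(f"{src}\t{etype}\t{dst}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("src\tetype\tdst\n")
            for src, dst, etype in net.sorted_edges():
                fh.write(f"{src}\t{etype}\t{dst}\n")
    elif format == "graphml":
        g = nx.MultiDiGraph()
        for node in sorted(net.nodes):
            cls, direction = net.nodes[node]
            g.add_node(node, rna_class=cls, de_direction=direction)
        for src, dst, etype in net.sorted_edges():
            g.add_edge(src, dst, etype=etype, directed=etype in DIRECTED_TYPES)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml(path) -> RegNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    net = RegNetwork()
    for node, data in g.nodes(data=True):
        net.add_node(node, data.get("rna_class", "mRNA"), data.get("de_direction", "none"))
    for src, dst, data in g.edges(data=True):
        net.add_edge(src, dst, data.get("etype", "ppi"))
    return net


def read_sif(path) -> set:
    """Edge triples (src, dst, etype) from a SIF file (canonicalized)."""
    edges = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            src, etype, dst = line.rstrip("\n").split("\t")
            edges.add(_canonical(src, dst, etype))
    return edges
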