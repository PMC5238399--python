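"""Tripartite gene–process–pathway graph and its six weighted projections.

The tripartite graph has three disjoint node layers — genes, GO
biological-process terms and KEGG pathways — and only inter-layer edges: a
gene connects to each of its annotated processes and pathways, and a process
connects to a pathway whenever at least one gene carries both.

A one-mode projection ``<linking>-<node>`` keeps every entity of the node
layer (isolated nodes included — they are findings, not artefacts) and joins
two of them with an edge weighted by the number of linking-layer entities
they share. For instance the ``pathway-gene`` network connects two genes by
the number of pathways common to both, while the ``gene-pathway`` network
connects two pathways by their number of shared genes. Projections are
simple weighted graphs: no self-loops, no multi-edges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import AnnotationMap

__all__ = [
    "LAYERS",
    "PROJECTION_NAMES",
    "build_tripartite",
    "project",
    "network_stats",
    "NetworkStats",
    "powerlaw_slope",
    "export_network",
    "read_network",
]

LAYERS = ("gene", "process", "pathway")

#: The six supported projections, named "<linking-layer>-<node-layer>".
PROJECTION_NAMES = (
    "pathway-gene",
    "process-gene",
    "gene-pathway",
    "process-pathway",
    "gene-process",
    "pathway-process",
)


def build_tripartite(genes: set[str], annotations: AnnotationMap) -> nx.Graph:
    """Build the three-layer annotation graph for a gene set.

    Nodes carry a ``layer`` attribute; genes without any annotation appear
    as degree-0 gene nodes. Process and pathway identifiers are prefixed
    internally only through the layer attribute, so callers must not reuse
    one identifier across layers.
    """
    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, layer="gene")
    for gene in genes:
        processes = annotations.gene_to_processes.get(gene, set())
        pathways = annotations.gene_to_pathways.get(gene, set())
        for proc in processes:
            g.add_node(proc, layer="process")
            g.add_edge(gene, proc)
        for pw in pathways:
            g.add_node(pw, layer="pathway")
            g.add_edge(gene, pw)
        # a process meets a pathway whenever one gene carries both
        for proc in processes:
            for pw in pathways:
                g.add_edge(proc, pw)
    return g


def _layer_nodes(graph: nx.Graph, layer: str) -> list[str]:
    return [n for n, d in graph.nodes(data=True) if d.get("layer") == layer]


def project(graph: nx.Graph, node_layer: str, linking_layer: str) -> nx.Graph:
    """One-mode projection of the tripartite graph.

    Every node of ``node_layer`` is kept; two nodes are joined with weight
    equal to the number of ``linking_layer`` entities adjacent to both.
    """
    for layer in (node_layer, linking_layer):
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    if node_layer == linking_layer:
        raise ValueError("node layer and linking layer must differ")

    proj = nx.Graph(name=f"{linking_layer}-{node_layer}")
    nodes = _layer_nodes(graph, node_layer)
    proj.add_nodes_from((n, {"layer": node_layer}) for n in nodes)

    # accumulate shared-link weights through each linking-layer node
    for link in _layer_nodes(graph, linking_layer):
        members = sorted(n for n in graph.neighbors(link) if graph.nodes[n].get("layer") == node_layer)
        for a, b in combinations(members, 2):
            if proj.has_edge(a, b):
                proj[a][b]["weight"] += 1
            else:
                proj.add_edge(a, b, weight=1)
    return proj


@dataclass
class NetworkStats:
    """Summary statistics of a weighted projection network.

    Both mean-degree conventions are reported: ``mean_degree`` is the usual
    sum-of-degrees over nodes (2E/N) and ``mean_degree_edges_per_node`` is
    E/N; published network summaries mix the two, so both are kept explicit.
    """

    node_count: int
    edge_count: int
    degree_sequence: list[int]
    mean_degree: float  # 2E/N
    mean_degree_edges_per_node: float  # E/N
    isolated_nodes: list[str]
    max_weight_edge: tuple[str, str, int] | None
    degree_histogram: dict[int, int]


def network_stats(net: nx.Graph) -> NetworkStats:
    n = net.number_of_nodes()
    e = net.number_of_edges()
    degrees = dict(net.degree())
    seq = [degrees[v] for v in net.nodes]
    hist: dict[int, int] = {}
    for d in seq:
        hist[d] = hist.get(d, 0) + 1
    isolated = sorted(v for v, d in degrees.items() if d == 0)
    max_edge = None
    if e:
        a, b, w = max(
            net.edges(data="weight", default=1), key=lambda t: (t[2], tuple(sorted(t[:2])))
        )
        a, b = sorted((a, b))
        max_edge = (a, b, int(w))
    return NetworkStats(
        node_count=n,
        edge_count=e,
        degree_sequence=seq,
        mean_degree=(2.0 * e / n) if n else 0.0,
        mean_degree_edges_per_node=(e / n) if n else 0.0,
        isolated_nodes=isolated,
        max_weight_edge=max_edge,
        degree_histogram=hist,
    )


def powerlaw_slope(degree_histogram: dict[int, int]) -> float | None:
    """Least-squares slope of log10(frequency) vs log10(degree).

    Zero-degree nodes are excluded; returns ``None`` (undefined-result
    signal) when fewer than three non-empty positive-degree bins remain.
    """
    pts = [(d, f) for d, f in degree_histogram.items() if d > 0 and f > 0]
    if len(pts) < 3:
        return None
    logd = np.log10([d for d, _ in pts])
    logf = np.log10([f for _, f in pts])
    slope, _ = np.polyfit(logd, logf, 1)
    return float(slope)


def export_network(net: nx.Graph, path: str | Path, fmt: str = "tsv") -> None:
    """Write a projection as a TSV edge list or GraphML.

    The TSV format is ``node_a<TAB>node_b<TAB>weight`` with a header line;
    isolated nodes are preserved in a trailing comment block so a round trip
    reproduces the node set exactly.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'graphml'")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_a", "node_b", "weight"])
        for a, b, w in sorted(net.edges(data="weight", default=1)):
            writer.writerow([a, b, int(w)])
        for v in sorted(v for v in net.nodes if net.degree(v) == 0):
            fh.write(f"#isolated\t{v}\n")


def read_network(path: str | Path, fmt: str = "tsv") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        # GraphML stringifies numeric attributes on some round trips
        for _, _, d in g.edges(data=True):
            d["weight"] = int(d.get("weight", 1))
        return g
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'graphml'")
    g = nx.Graph()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["node_a", "node_b", "weight"]:
            raise ValueError(f"{path}: unexpected edge-list header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#isolated\t"):
                g.add_node(line.split("\t", 1)[1])
                continue
            a, b, w = line.split("\t")
            g.add_edge(a, b, weight=int(w))
    return g


def all_projections(graph: nx.Graph) -> dict[str, nx.Graph]:
    """All six one-mode projections of a tripartite graph, by name."""
    out = {}
    for name in PROJECTION_NAMES:
        linking, node = name.split("-")
        out[name] = project(graph, node_layer=node, linking_layer=linking)
    return out
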