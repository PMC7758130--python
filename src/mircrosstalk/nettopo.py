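"""Annotation-driven network assembly (PPI, TF->target, miRNA->target,
miR-DEG-pathway) and NetworkAnalyzer-style node topology statistics.

All topology metrics are computed on the undirected simple-graph view;
directionality of TF and miRNA edges is kept only as an edge attribute.
Disconnected graphs are handled per connected component: average shortest
path length and closeness are within-component, betweenness is Brandes
normalized by (m-1)(m-2)/2 with m the component size.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from mircrosstalk.errors import InputError

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "degree",
    "avg_shortest_path_length",
    "betweenness",
    "closeness",
    "topological_coefficient",
]


def assemble_ppi(
    de_direction: Mapping[str, str], edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """PPI subnetwork: DE genes plus their direct interaction partners.

    Nodes are the DE genes and every gene adjacent to a DE gene; edges are all
    interaction pairs whose both endpoints are included.  Node attributes:
    role='gene', de_status in {'up','down','non-DE'}.
    """
    degs = set(de_direction)
    if not degs:
        logger.warning("empty DE table: PPI network is empty")
        return nx.Graph()
    edges = [(a, b) for a, b in edges if a != b]
    nodes = set(degs)
    for a, b in edges:
        if a in degs:
            nodes.add(b)
        if b in degs:
            nodes.add(a)
    g = nx.Graph()
    for node in nodes:
        g.add_node(node, role="gene", de_status=de_direction.get(node, "non-DE"))
    for a, b in edges:
        if a in nodes and b in nodes:
            g.add_edge(a, b)
    # drop DE genes with no interactions at all? keep them: they are part of
    # the DE node set; isolated nodes get the degree-0 conventions.
    return g


def assemble_tf(
    de_direction: Mapping[str, str], tf_edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """TF->target network restricted to DE targets.

    Only edges whose target is DE are kept.  TFs that are themselves DE carry
    both tags (role='TF', de_status set), mirroring 'Downregulated DEG_TF'
    style annotations.
    """
    degs = set(de_direction)
    g = nx.Graph()
    for tf, target in tf_edges:
        if target not in degs or tf == target:
            continue
        g.add_node(tf, role="TF", de_status=de_direction.get(tf, "non-DE"))
        if g.nodes.get(target, {}).get("role") != "TF":
            g.add_node(target, role="gene", de_status=de_direction[target])
        g.add_edge(tf, target, source=tf)
    return g


def merge_targets(
    validated: Iterable[tuple[str, str]], predicted: Iterable[tuple[str, str]]
) -> dict[str, frozenset[str]]:
    """Union of validated and predicted miRNA->target pairs, per miRNA."""
    merged: dict[str, set[str]] = {}
    for mirna, gene in list(validated) + list(predicted):
        merged.setdefault(mirna, set()).add(gene)
    return {m: frozenset(gs) for m, gs in merged.items()}


def mirna_detargets(
    de_mirnas: Iterable[str],
    merged_targets: Mapping[str, frozenset[str]],
    de_genes: Iterable[str],
) -> dict[str, frozenset[str]]:
    """Per-DEmiRNA sets of targets that are themselves DE (miRNA-DEtarget pairs)."""
    de_genes = frozenset(de_genes)
    return {
        m: frozenset(merged_targets.get(m, frozenset()) & de_genes)
        for m in sorted(set(de_mirnas))
    }


def assemble_mirna_target(
    de_mirnas: Mapping[str, str],
    merged_targets: Mapping[str, frozenset[str]],
    de_direction: Mapping[str, str],
    de_targets_only: bool = False,
) -> nx.Graph:
    """DEmiRNA->target network over the merged (validated | predicted) table.

    With de_targets_only=True the targets are restricted to DE genes, giving
    the miRNA-DEtarget pair network.
    """
    g = nx.Graph()
    for mirna in sorted(set(de_mirnas)):
        targets = merged_targets.get(mirna, frozenset())
        if de_targets_only:
            targets = targets & set(de_direction)
        g.add_node(mirna, role="miRNA", de_status=de_mirnas[mirna])
        for gene in targets:
            if gene == mirna:
                continue
            g.add_node(
                gene, role="gene", de_status=de_direction.get(gene, "non-DE")
            )
            g.add_edge(mirna, gene, source=mirna)
    return g


def assemble_network(
    de_direction: Mapping[str, str],
    edges: Iterable[tuple[str, str]],
    mode: str,
    de_mirnas: Mapping[str, str] | None = None,
    predicted_edges: Iterable[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Dispatcher over the three assembly modes: 'ppi', 'tf', 'mirna_target'."""
    if mode == "ppi":
        return assemble_ppi(de_direction, edges)
    if mode == "tf":
        return assemble_tf(de_direction, edges)
    if mode == "mirna_target":
        if de_mirnas is None:
            raise InputError("mirna_target mode requires de_mirnas")
        merged = merge_targets(edges, predicted_edges or [])
        return assemble_mirna_target(de_mirnas, merged, de_direction)
    raise InputError(f"unknown network mode {mode!r}")


def _topological_coefficient(g: nx.Graph, v) -> float:
    """Mean over partners m of J(v,m)/degree(v); 0 for degree <= 1.

    Partners are nodes (other than v) sharing at least one neighbor with v or
    adjacent to v; J(v,m) = |shared neighbors| + 1 if v and m are adjacent.
    """
    k = g.degree(v)
    if k <= 1:
        return 0.0
    nv = set(g.neighbors(v))
    partners = set()
    for u in nv:
        partners.add(u)
        partners.update(g.neighbors(u))
    partners.discard(v)
    vals = []
    for m in partners:
        j = len(nv & set(g.neighbors(m)))
        if g.has_edge(v, m):
            j += 1
        if j > 0:
            vals.append(j / k)
    return sum(vals) / len(vals) if vals else 0.0


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, avg shortest path length, betweenness, closeness, and
    topological coefficient per node (undirected view).

    Conventions: isolated nodes (and size-1 components) get aspl=0,
    closeness=0; betweenness is normalized within each connected component by
    (m-1)(m-2)/2; closeness = 1/aspl inside components of size >= 2.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("cannot compute metrics on an empty graph")
    g = nx.Graph(graph)
    rows = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        btw = (
            nx.betweenness_centrality(sub, normalized=True)
            if m > 2
            else {v: 0.0 for v in comp}
        )
        for v in comp:
            if m == 1:
                aspl = 0.0
                clo = 0.0
            else:
                dists = nx.single_source_shortest_path_length(sub, v)
                aspl = sum(dists.values()) / (m - 1)
                clo = 1.0 / aspl
            rows[v] = {
                "degree": g.degree(v),
                "avg_shortest_path_length": aspl,
                "betweenness": btw[v],
                "closeness": clo,
                "topological_coefficient": _topological_coefficient(g, v),
            }
    out = pd.DataFrame.from_dict(rows, orient="index")[METRIC_COLUMNS]
    out.index.name = "node"
    return out.sort_index()


def rank_nodes(metrics: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k nodes by descending degree, ties broken by node id."""
    if k <= 0:
        raise InputError(f"k must be positive (got {k})")
    out = metrics.sort_index().sort_values(
        "degree", ascending=False, kind="mergesort"
    )  # stable sort on a sorted index -> ties resolve lexicographically
    return out.head(k)


def mir_deg_pathway_network(
    detargets: Mapping[str, frozenset[str]],
    enriched_terms: Mapping[str, Mapping[str, frozenset[str]]],
) -> nx.Graph:
    """Tripartite miRNA -> DE target -> enriched pathway network.

    enriched_terms maps miRNA -> {term -> member gene set} for the terms
    enriched in that miRNA's DE targets; a target links to a term only if the
    term contains it.
    """
    g = nx.Graph()
    for mirna in sorted(detargets):
        g.add_node(mirna, role="miRNA")
        terms = enriched_terms.get(mirna, {})
        for gene in sorted(detargets[mirna]):
            g.add_node(gene, role="gene")
            g.add_edge(mirna, gene, source=mirna)
            for term, members in terms.items():
                if gene in members:
                    g.add_node(term, role="pathway")
                    g.add_edge(gene, term)
    return g


def metrics_report(
    graph: nx.Graph, annotation: Mapping[str, str] | None = None, k: int | None = None
) -> pd.DataFrame:
    """Node-metric table in the published layout, ranked by degree.

    An optional annotation column (e.g. 'Downregulated DEG_TF' style tags) is
    derived from node role/de_status attributes when not given explicitly.
    """
    met = node_metrics(graph)
    ranked = rank_nodes(met, k if k is not None else len(met))
    if annotation is None:
        annotation = {}
        for v in ranked.index:
            attrs = graph.nodes[v]
            role = attrs.get("role", "gene")
            de = attrs.get("de_status", "non-DE")
            if role == "TF":
                tag = "TF" if de == "non-DE" else f"{de.capitalize()}regulated DEG_TF"
            elif role == "miRNA":
                tag = "DEmiRNA" if de != "non-DE" else "miRNA"
            elif de == "non-DE":
                tag = "non-DEG"
            else:
                tag = f"{de.capitalize()}regulated DEG"
            annotation[v] = tag
    out = ranked.reset_index()
    out.insert(1, "annotation", out["node"].map(annotation))
    return out
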