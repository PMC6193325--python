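"""Disease protein network: hub collection and first-neighbor PPI expansion.

Curated disease-gene lists (therapeutic-target and Mendelian-inheritance
style extracts) are unioned into a hub set; the hubs are expanded one hop
through a confidence-weighted PPI graph and the induced subgraph over the
retained nodes forms the disease-specific protein interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import netcore
from .io import normalize_symbol

__all__ = [
    "DiseaseGeneSet",
    "collect_hubs",
    "ppi_graph",
    "expand_first_neighbors",
    "rank_disease_proteins",
]


@dataclass
class DiseaseGeneSet:
    hubs: set[str]
    sources: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def collect_hubs(lists: dict[str, list[str]]) -> DiseaseGeneSet:
    """Union tagged symbol lists into a deduplicated hub set.

    ``lists`` maps a source tag (e.g. "TTD-like") to its symbols.  Symbols
    are normalized; a symbol occurring in several lists keeps every tag.
    """
    hubs: set[str] = set()
    sources: dict[str, list[str]] = {}
    warns: list[str] = []
    for tag, symbols in lists.items():
        seen_here: set[str] = set()
        for s in symbols:
            sym = normalize_symbol(s)
            if not sym:
                continue
            if sym in seen_here:
                warns.append(f"duplicate symbol {sym!r} within list {tag!r}")
                continue
            seen_here.add(sym)
            hubs.add(sym)
            sources.setdefault(sym, []).append(tag)
    if not hubs:
        raise ValueError("all hub lists are empty")
    return DiseaseGeneSet(hubs=hubs, sources=sources, warnings=warns)


def ppi_graph(ppi: pd.DataFrame) -> nx.Graph:
    """Build an undirected confidence-weighted graph from a PPI table."""
    g = nx.Graph()
    for _, row in ppi.iterrows():
        g.add_edge(row["protein_a"], row["protein_b"], confidence=float(row["confidence"]))
    return g


def expand_first_neighbors(
    hubs: DiseaseGeneSet | set[str], ppi: nx.Graph, conf_min: float = 0.4
) -> nx.Graph:
    """One-hop hub expansion with induced-subgraph edges.

    Nodes: the hubs plus every protein adjacent to a hub through an edge of
    confidence >= ``conf_min``.  Edges: all PPI edges of confidence >=
    ``conf_min`` between retained nodes (so neighbor-neighbor edges are
    kept).  Hubs absent from the PPI graph remain as isolated nodes,
    flagged in the node attribute ``missing_from_ppi``.
    """
    if not 0.0 <= conf_min <= 1.0:
        raise ValueError("conf_min must lie in [0, 1]")
    hub_set = hubs.hubs if isinstance(hubs, DiseaseGeneSet) else set(hubs)
    hub_set = {normalize_symbol(h) for h in hub_set}

    strong = nx.Graph()
    strong.add_nodes_from(ppi.nodes())
    for u, v, d in ppi.edges(data=True):
        if d.get("confidence", 1.0) >= conf_min:
            strong.add_edge(u, v, confidence=d.get("confidence", 1.0))

    nodes = set(hub_set)
    for h in hub_set & set(strong.nodes()):
        nodes |= set(strong[h])
    net = strong.subgraph(nodes & set(strong.nodes())).copy()
    for h in hub_set:
        if h not in net:
            net.add_node(h)
    for n in net.nodes():
        net.nodes[n]["hub"] = n in hub_set
        net.nodes[n]["missing_from_ppi"] = n in hub_set and n not in ppi
        net.nodes[n]["nodetype"] = netcore.TARGET
    return net


def rank_disease_proteins(net: nx.Graph, k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k disease proteins by degree and by betweenness."""
    if k <= 0:
        raise ValueError("k must be positive")
    if net.number_of_nodes() == 0:
        raise ValueError("empty disease network")
    records = netcore.centrality_table(net)
    return {
        "degree": netcore.top_k(records, "degree", k),
        "betweenness": netcore.top_k(records, "betweenness", k),
    }
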