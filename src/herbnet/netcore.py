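"""Construction and centrality analysis of the pipeline's networks.

Five networks are analysed: the tripartite herb-compound-target network
built from screened compounds, its restriction to disease-specific targets,
the disease PPI network (built in :mod:`herbnet.disease`), the bipartite
target-process network, and the docking-validated compound-target network.
Node importance is measured by degree (incident-edge count over the whole
typed graph, so a compound's degree = herb memberships + target
associations) and by normalized shortest-path betweenness.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .io import Compound, Herb, normalize_symbol

__all__ = [
    "build_hbcct",
    "restrict_to_disease",
    "degree_centrality",
    "betweenness_centrality",
    "centrality_table",
    "top_k",
    "build_pt_f",
    "docking_filter",
    "validate_tripartite",
]

HERB, COMPOUND, TARGET, PROCESS = "HERB", "COMPOUND", "TARGET", "PROCESS"


def build_hbcct(
    herbs: set[Herb],
    compounds: dict[str, Compound],
    assoc: pd.DataFrame,
) -> nx.Graph:
    """Build the tripartite herb / compound / target network.

    Nodes carry ``nodetype`` in {HERB, COMPOUND, TARGET}; herb-compound
    edges encode membership and compound-target edges the associations.
    Targets with no association edge are not instantiated.  Compound node
    labels are chemical names; association compound ids must resolve to
    the (screened) compound dict.
    """
    g = nx.Graph()
    herb_names = {h.name for h in herbs}
    for h in herbs:
        g.add_node(h.name, nodetype=HERB, role=h.role.value)
    label_of = {}
    for cid, c in compounds.items():
        label_of[cid] = c.name
        g.add_node(c.name, nodetype=COMPOUND, compound_id=cid)
        for h in c.herbs:
            if h not in herb_names:
                raise KeyError(f"compound {cid!r}: unknown herb {h!r}")
            g.add_edge(h, c.name, kind="membership")
    for _, row in assoc.iterrows():
        cid = row["compound_id"]
        if cid not in compounds:
            raise KeyError(f"association references unscreened compound {cid!r}")
        t = normalize_symbol(row["target"])
        if t not in g:
            g.add_node(t, nodetype=TARGET)
        g.add_edge(label_of[cid], t, kind="association")
    validate_tripartite(g)
    return g


def validate_tripartite(g: nx.Graph) -> None:
    allowed = {frozenset({HERB, COMPOUND}), frozenset({COMPOUND, TARGET})}
    for u, v in g.edges():
        tu, tv = g.nodes[u]["nodetype"], g.nodes[v]["nodetype"]
        if frozenset({tu, tv}) not in allowed:
            raise ValueError(f"forbidden edge {u!r}({tu}) -- {v!r}({tv})")
    for n, d in g.nodes(data=True):
        if d["nodetype"] == COMPOUND and not any(
            g.nodes[m]["nodetype"] == HERB for m in g[n]
        ):
            raise ValueError(f"compound node {n!r} has no herb membership edge")


def restrict_to_disease(g: nx.Graph, disease_targets: set[str]) -> nx.Graph:
    """Restrict a tripartite network to disease-specific targets.

    Keeps TARGET nodes in ``disease_targets``, COMPOUND nodes retaining at
    least one target edge, and HERB nodes retaining at least one compound
    edge.  Idempotent; an empty intersection yields an empty graph with a
    warning.
    """
    keep_targets = {normalize_symbol(t) for t in disease_targets}
    targets = {
        n for n, d in g.nodes(data=True) if d["nodetype"] == TARGET and n in keep_targets
    }
    compounds = {
        n
        for n, d in g.nodes(data=True)
        if d["nodetype"] == COMPOUND and any(m in targets for m in g[n])
    }
    herbs = {
        n
        for n, d in g.nodes(data=True)
        if d["nodetype"] == HERB and any(m in compounds for m in g[n])
    }
    sub = g.subgraph(herbs | compounds | targets).copy()
    # drop edges to pruned neighbors are handled by subgraph; nothing more.
    if not sub:
        warnings.warn("disease restriction produced an empty network", stacklevel=2)
    return sub


def degree_centrality(g: nx.Graph) -> dict:
    """Integer incident-edge counts over the whole (multi-type) graph."""
    return dict(g.degree())


def betweenness_centrality(g: nx.Graph) -> dict:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2 with n the
    whole graph's node count; shortest-path pairs contribute only within
    their connected component."""
    return nx.betweenness_centrality(g, normalized=True)


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree and betweenness records."""
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    rows = [
        {
            "node": n,
            "nodetype": g.nodes[n].get("nodetype", ""),
            "degree": int(deg[n]),
            "betweenness": float(btw[n]),
        }
        for n in g.nodes()
    ]
    return pd.DataFrame(rows, columns=["node", "nodetype", "degree", "betweenness"])


def top_k(records: pd.DataFrame, indicator: str, k: int) -> pd.DataFrame:
    """Top-k ranking by one indicator with deterministic tie-breaking.

    Descending by ``indicator``; ties broken by the other indicator
    (descending), then lexicographically by node label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if indicator not in ("degree", "betweenness"):
        raise ValueError(f"unknown indicator {indicator!r}")
    other = "betweenness" if indicator == "degree" else "degree"
    out = records.sort_values(
        by=[indicator, other, "node"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(k)


def build_pt_f(targets: set[str], annotation: pd.DataFrame) -> nx.Graph:
    """Bipartite target-process membership network.

    ``annotation`` has columns gene, term; only rows whose gene is in
    ``targets`` contribute.  TARGET and PROCESS node types are attached.
    """
    keep = {normalize_symbol(t) for t in targets}
    g = nx.Graph()
    for _, row in annotation.iterrows():
        gene = normalize_symbol(row["gene"])
        if gene not in keep:
            continue
        term = str(row["term"])
        g.add_node(gene, nodetype=TARGET)
        g.add_node(term, nodetype=PROCESS)
        g.add_edge(gene, term, kind="membership")
    return g


def docking_filter(dock: pd.DataFrame) -> pd.DataFrame:
    """Retain (compound, target) pairs whose docking score strictly exceeds
    the target's original-ligand reference score.

    The retained pairs are the edges of the docking-validated
    compound-target network.
    """
    if dock["reference_score"].isna().any():
        bad = dock[dock["reference_score"].isna()]["target"].unique()
        raise ValueError(f"targets without reference score: {sorted(bad)}")
    kept = dock[dock["libdock_score"] > dock["reference_score"]]
    return kept[["compound_id", "target"]].reset_index(drop=True)
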