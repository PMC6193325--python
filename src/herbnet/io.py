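"""Input tables and graph exchange formats.

The pipeline consumes plain tabular text (TSV by default, CSV on request):
a herb formulary with per-herb role labels and the six ADME descriptors,
compound-target association tables, confidence-weighted PPI edge lists,
docking score tables, and gene-to-process annotation edges.  Networks are
written as SIF, GraphML (with a ``nodetype`` attribute) or paired node/edge
TSV, all of which round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "Role",
    "Herb",
    "Compound",
    "SchemaError",
    "ReferentialError",
    "read_formulary",
    "read_edge_list",
    "write_graph",
    "read_graph",
    "normalize_symbol",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = ["MW", "nHdon", "nHacc", "AlogP", "OB", "DL"]


class Role(str, Enum):
    """Classical herb roles: monarch, minister, adjuvant/guide."""

    JUN = "JUN"
    CHEN = "CHEN"
    ZUO_SHI = "ZUO_SHI"


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ReferentialError(ValueError):
    """A record references an entity that does not exist."""


@dataclass(frozen=True)
class Herb:
    name: str
    role: Role
    botanical_name: str = ""


@dataclass
class Compound:
    """A chemical record with ADME descriptors and herb memberships.

    Descriptors: MW (daltons), nHdon/nHacc (H-bond donor/acceptor counts),
    AlogP (octanol-water partition), OB (oral bioavailability, percent),
    DL (drug-likeness index in [0, 1]).
    """

    id: str
    name: str
    MW: float
    nHdon: float
    nHacc: float
    AlogP: float
    OB: float
    DL: float
    herbs: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if not self.herbs:
            raise ReferentialError(f"compound {self.id!r} belongs to no herb")
        if self.nHdon < 0 or self.nHacc < 0:
            raise ValueError(f"compound {self.id!r}: negative H-bond count")
        if self.OB < 0:
            raise ValueError(f"compound {self.id!r}: OB < 0")
        if not 0.0 <= self.DL <= 1.0:
            raise ValueError(f"compound {self.id!r}: DL outside [0, 1]")


def normalize_symbol(s: str) -> str:
    """Uppercase and strip a gene symbol.  Idempotent; no alias resolution."""
    return str(s).strip().upper()


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)


_ROLE_ALIASES = {
    "JUN": Role.JUN,
    "CHEN": Role.CHEN,
    "ZUO_SHI": Role.ZUO_SHI,
    "ZUO-SHI": Role.ZUO_SHI,
    "ZUOSHI": Role.ZUO_SHI,
}


def read_formulary(
    path: str | Path, sep: str = "\t"
) -> tuple[set[Herb], dict[str, Compound]]:
    """Read a formulary table into herbs and merged compounds.

    One row per (herb, compound) listing.  Required columns: ``herb``,
    ``role``, ``compound_id``, ``name``, and the six descriptors.  Rows
    sharing a chemical name (case-insensitive) are merged into a single
    compound carrying every herb membership; the first record's descriptor
    values win and a warning is emitted if later records disagree.
    """
    df = _read_table(path, sep=sep)
    required = ["herb", "role", "compound_id", "name"] + DESCRIPTOR_COLUMNS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"formulary {path}: missing required column {col!r}")

    herbs: dict[str, Herb] = {}
    for _, row in df.drop_duplicates(subset=["herb"]).iterrows():
        role_key = str(row["role"]).strip().upper()
        if role_key not in _ROLE_ALIASES:
            raise SchemaError(
                f"herb {row['herb']!r}: unknown role {row['role']!r} "
                f"(expected one of JUN, CHEN, ZUO_SHI)"
            )
        botanical = str(row.get("botanical_name", "") or "")
        herbs[row["herb"]] = Herb(row["herb"], _ROLE_ALIASES[role_key], botanical)

    # Same herb listed under two roles is a data error.
    roles_per_herb = df.groupby("herb")["role"].apply(
        lambda s: {_ROLE_ALIASES.get(str(v).strip().upper()) for v in s}
    )
    conflicted = roles_per_herb[roles_per_herb.apply(len) > 1]
    if len(conflicted):
        raise SchemaError(f"herbs with conflicting roles: {list(conflicted.index)}")

    compounds: dict[str, Compound] = {}
    by_name: dict[str, str] = {}  # lowercase name -> compound id
    merged: list[str] = []
    for _, row in df.iterrows():
        key = str(row["name"]).strip().lower()
        try:
            desc = {c: float(row[c]) for c in DESCRIPTOR_COLUMNS}
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"compound {row['compound_id']!r}: non-numeric descriptor ({exc})"
            ) from None
        if key in by_name:
            comp = compounds[by_name[key]]
            comp.herbs.add(row["herb"])
            merged.append(comp.name)
            if any(abs(getattr(comp, c) - desc[c]) > 1e-9 for c in DESCRIPTOR_COLUMNS):
                warnings.warn(
                    f"compound {comp.name!r}: descriptor values differ across "
                    f"herb entries; keeping the first record",
                    stacklevel=2,
                )
        else:
            comp = Compound(
                id=str(row["compound_id"]),
                name=str(row["name"]).strip(),
                herbs={row["herb"]},
                **desc,
            )
            if comp.id in compounds:
                raise SchemaError(f"duplicate compound id {comp.id!r} for distinct names")
            compounds[comp.id] = comp
            by_name[key] = comp.id

    for comp in compounds.values():
        comp.validate()
        unknown = comp.herbs - set(herbs)
        if unknown:
            raise ReferentialError(f"compound {comp.id!r}: unknown herbs {unknown}")
    if merged:
        warnings.warn(
            f"merged {len(merged)} duplicate chemical-name rows across herbs",
            stacklevel=2,
        )
    return set(herbs.values()), compounds


def read_edge_list(path: str | Path, kind: str, sep: str = "\t") -> pd.DataFrame:
    """Read a typed edge table.

    kind='ppi'         columns (protein_a, protein_b[, confidence]); symbols
                       uppercased, self-loops dropped, duplicate undirected
                       edges collapsed keeping the maximum confidence.
    kind='association' columns (compound_id, target[, score]); duplicate
                       (compound, target) pairs dropped.
    kind='docking'     columns (compound_id, target, libdock_score,
                       reference_score); every target must carry a reference.
    kind='annotation'  columns (gene, term): gene-to-process membership edges.
    """
    df = _read_table(path, sep=sep)
    if kind == "ppi":
        need = ["protein_a", "protein_b"]
        _require(df, need, path)
        df["protein_a"] = df["protein_a"].map(normalize_symbol)
        df["protein_b"] = df["protein_b"].map(normalize_symbol)
        if "confidence" in df.columns:
            df["confidence"] = _numeric(df["confidence"], path, "confidence")
        else:
            df["confidence"] = 1.0
        df = df[df["protein_a"] != df["protein_b"]]
        key = df.apply(
            lambda r: tuple(sorted((r["protein_a"], r["protein_b"]))), axis=1
        )
        df = df.assign(_key=key)
        idx = df.groupby("_key")["confidence"].idxmax()
        df = df.loc[idx].drop(columns="_key").reset_index(drop=True)
        return df[["protein_a", "protein_b", "confidence"]]
    if kind == "association":
        _require(df, ["compound_id", "target"], path)
        df["target"] = df["target"].map(normalize_symbol)
        if "score" in df.columns:
            df["score"] = _numeric(df["score"], path, "score")
        n0 = len(df)
        df = df.drop_duplicates(subset=["compound_id", "target"]).reset_index(drop=True)
        if len(df) < n0:
            warnings.warn(
                f"{path}: dropped {n0 - len(df)} duplicate association pairs",
                stacklevel=2,
            )
        return df
    if kind == "docking":
        _require(df, ["compound_id", "target", "libdock_score", "reference_score"], path)
        df["target"] = df["target"].map(normalize_symbol)
        df["libdock_score"] = _numeric(df["libdock_score"], path, "libdock_score")
        df["reference_score"] = _numeric(df["reference_score"], path, "reference_score")
        missing = df[df["reference_score"].isna()]["target"].unique()
        if len(missing):
            raise SchemaError(
                f"{path}: targets without a reference-ligand score: {sorted(missing)}"
            )
        per_target = df.groupby("target")["reference_score"].nunique()
        bad = per_target[per_target > 1]
        if len(bad):
            raise SchemaError(
                f"{path}: inconsistent reference scores for targets {list(bad.index)}"
            )
        return df.reset_index(drop=True)
    if kind == "annotation":
        _require(df, ["gene", "term"], path)
        df["gene"] = df["gene"].map(normalize_symbol)
        return df.drop_duplicates().reset_index(drop=True)
    raise ValueError(f"unknown edge-list kind {kind!r}")


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def _numeric(col: pd.Series, path, name: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SchemaError(f"{path}: non-numeric {name} value at line {line}")
    return out


# ---------------------------------------------------------------------------
# graph exchange


def write_graph(net: nx.Graph, path: str | Path, format: str = "graphml") -> list[Path]:
    """Write a network as SIF, GraphML, or paired node/edge TSV.

    Returns the list of files written.  Round-trip via :func:`read_graph`
    reconstructs identical node/edge sets and the ``nodetype`` attribute.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
        return [path]
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, data in net.edges(data=True):
                fh.write(f"{u}\t{data.get('interaction', 'interacts')}\t{v}\n")
            for n in nx.isolates(net):
                fh.write(f"{n}\n")
        return [path]
    if format == "tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        nodes = pd.DataFrame(
            [
                {"node": n, "nodetype": d.get("nodetype", "")}
                for n, d in net.nodes(data=True)
            ],
            columns=["node", "nodetype"],
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **{k: v2 for k, v2 in d.items()}}
                for u, v, d in net.edges(data=True)
            ]
        )
        if edges.empty:
            edges = pd.DataFrame(columns=["source", "target"])
        nodes.to_csv(node_path, sep="\t", index=False)
        edges.to_csv(edge_path, sep="\t", index=False)
        return [node_path, edge_path]
    raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Inverse of :func:`write_graph`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.Graph(g)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) >= 3:
                    g.add_edge(parts[0], parts[2], interaction=parts[1])
        return g
    if format == "tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        g = nx.Graph()
        nodes = pd.read_csv(node_path, sep="\t", dtype=str).fillna("")
        for _, r in nodes.iterrows():
            g.add_node(r["node"], nodetype=r["nodetype"])
        edges = pd.read_csv(edge_path, sep="\t", dtype=str)
        if len(edges):
            for _, r in edges.iterrows():
                attrs = {
                    k: r[k]
                    for k in edges.columns
                    if k not in ("source", "target") and pd.notna(r[k])
                }
                g.add_edge(r["source"], r["target"], **attrs)
        return g
    raise ValueError(f"unknown graph format {format!r}")
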