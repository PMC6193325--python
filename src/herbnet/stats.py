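"""Statistical kernels: hypergeometric over-representation with FDR control
and the one-way ANOVA backend shared with the descriptor comparison.

Enrichment follows the classic over-representation model: for a query set
of n genes drawn from a universe of N, a term containing K genes with k of
them in the query has upper-tail probability P(X >= k) under
X ~ Hypergeom(N, K, n).  An optional EASE-style conservative variant
(scoring k-1 successes) is available.  FDR is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationCollection",
    "read_gmt",
    "hypergeom_enrich",
    "bh_fdr",
    "one_way_anova",
]


@dataclass
class AnnotationCollection:
    """term id -> (name, gene set), with a background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        self.terms = {
            tid: (name, frozenset(str(g).strip().upper() for g in genes))
            for tid, (name, genes) in self.terms.items()
        }
        self.universe = frozenset(str(g).strip().upper() for g in self.universe)
        if not self.universe:
            u: set[str] = set()
            for _, genes in self.terms.values():
                u |= set(genes)
            self.universe = frozenset(u)
        for tid, (_, genes) in self.terms.items():
            if not set(genes) <= self.universe:
                raise ValueError(f"term {tid!r} has genes outside the universe")

    @classmethod
    def from_edges(cls, edges: pd.DataFrame, universe=None) -> "AnnotationCollection":
        """Build from a (gene, term) edge table."""
        terms = {
            str(t): (str(t), frozenset(g["gene"]))
            for t, g in edges.groupby("term")
        }
        return cls(terms=terms, universe=frozenset(universe) if universe else frozenset())


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file (term <tab> description <tab> gene...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], frozenset(g.strip().upper() for g in parts[2:] if g.strip()))
    return AnnotationCollection(terms=terms)


def hypergeom_enrich(
    query: set[str],
    ann: AnnotationCollection,
    ease: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation probabilities, sorted by p.

    Query genes outside the universe are dropped with a warning.  Columns:
    term, name, k (query hits), K (term size), n (query size), N (universe
    size), p, fdr.  With ``ease`` the conservative k-1 convention is used.
    """
    if not ann.universe:
        raise ValueError("empty annotation universe")
    query = {str(g).strip().upper() for g in query}
    outside = query - set(ann.universe)
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query genes outside the universe", stacklevel=2
        )
        query = query & set(ann.universe)
    N, n = len(ann.universe), len(query)
    rows = []
    for tid, (name, genes) in ann.terms.items():
        K = len(genes)
        k = len(query & set(genes))
        k_eff = max(k - 1, 0) if ease else k
        p = float(sps.hypergeom.sf(k_eff - 1, N, K, n))  # P(X >= k_eff)
        rows.append({"term": tid, "name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >=2 groups of >=2 values.

    Zero between-group variance returns (0, 1) even when the within-group
    variance is also zero (identical constant groups).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    grand = np.mean(np.concatenate(arrays))
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ssb == 0.0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = sps.f_oneway(*arrays)
    return float(F), float(p)
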