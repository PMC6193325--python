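"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, without any database access: a role-structured
formulary (monarch/minister/adjuvant-guide herbs with role-shifted oral
bioavailability), heavy-tailed compound-target association degrees with a
handful of promiscuous hub targets, a scale-free confidence-weighted PPI
graph, degree-preferential disease hub genes, annotation collections with
one planted enriched term, and a docking score table.  One global seed
drives every generator through independent sub-streams, so a fixed seed
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import Compound, Herb, Role

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate", "write_bundle"]

_ROLE_ORDER = [Role.JUN, Role.CHEN, Role.ZUO_SHI]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults echo an 11-herb formula: 2 monarch, 3 minister, 6
    adjuvant/guide herbs; 162 compounds; a 285-protein target universe
    drawn from a 500-node scale-free PPI; 21 disease hub genes.  OB is
    drawn in percent with an upward monarch-role shift; DL from a Beta
    shaped to mean ~0.48.
    """

    seed: int = 0
    n_herbs_per_role: tuple[int, int, int] = (2, 3, 6)
    n_compounds: int = 162
    multi_role_fraction: float = 0.06  # extra herb memberships across roles
    mw_mean: float = 370.0
    mw_sd: float = 90.0
    nhdon_lam: float = 2.5
    nhacc_lam: float = 5.4
    alogp_mean: float = 3.3
    alogp_sd: float = 2.5
    ob_mean: float = 47.0
    ob_sd: float = 15.0
    jun_ob_shift: float = 8.0
    dl_beta: tuple[float, float] = (4.8, 5.2)
    n_genes: int = 2000  # gene-symbol namespace; PPI and targets are slices of it
    n_targets: int = 285
    assoc_exponent: float = 1.8
    n_hub_targets: int = 8
    hub_target_weight: float = 30.0
    ppi_n: int = 500
    ppi_m: int = 12
    conf_low: float = 0.15
    conf_high: float = 1.0
    n_hubs: int = 21
    n_terms: int = 30
    term_size: int = 30
    planted_odds: float = 20.0
    dock_above_fraction: float = 0.35

    def __post_init__(self) -> None:
        if min(self.n_herbs_per_role) < 1 or self.n_compounds < 1:
            raise ValueError("counts must be positive")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


@dataclass
class SyntheticBundle:
    """Everything the pipeline reads, as in-memory objects."""

    herbs: set[Herb]
    compounds: dict[str, Compound]
    formulary: pd.DataFrame
    assoc: pd.DataFrame
    ppi: pd.DataFrame
    hub_lists: dict[str, list[str]]
    annotation: pd.DataFrame
    docking: pd.DataFrame
    targets: list[str] = field(default_factory=list)
    disease_targets: list[str] = field(default_factory=list)


def gen_formulary(cfg: SyntheticConfig) -> tuple[set[Herb], dict[str, Compound], pd.DataFrame]:
    """Role-structured herbs and descriptor-bearing compounds.

    Each compound gets one primary herb (uniform over herbs); a
    ``multi_role_fraction`` of compounds receive an extra herb, preferably
    of a different role, populating the Venn intersection regions.  OB is
    shifted upward by ``jun_ob_shift`` for compounds contained in any
    monarch-role herb.
    """
    rng = cfg._rng(0)
    herbs: list[Herb] = []
    for role, n in zip(_ROLE_ORDER, cfg.n_herbs_per_role):
        for i in range(n):
            herbs.append(Herb(f"HB_{role.value}_{i + 1}", role))
    role_of = {h.name: h.role for h in herbs}
    herb_names = [h.name for h in herbs]

    compounds: dict[str, Compound] = {}
    rows = []
    n = cfg.n_compounds
    primary = rng.integers(0, len(herbs), size=n)
    extra_mask = rng.random(n) < cfg.multi_role_fraction
    mw = np.clip(rng.normal(cfg.mw_mean, cfg.mw_sd, n), 60.0, None)
    nhdon = rng.poisson(cfg.nhdon_lam, n).astype(float)
    nhacc = rng.poisson(cfg.nhacc_lam, n).astype(float)
    alogp = rng.normal(cfg.alogp_mean, cfg.alogp_sd, n)
    dl = rng.beta(*cfg.dl_beta, n)
    ob_base = np.clip(rng.normal(cfg.ob_mean, cfg.ob_sd, n), 0.0, None)

    for i in range(n):
        members = {herb_names[primary[i]]}
        if extra_mask[i]:
            other_role = [h for h in herb_names if role_of[h] != role_of[herb_names[primary[i]]]]
            members.add(other_role[rng.integers(0, len(other_role))])
            if rng.random() < 0.3:  # a few triple-role compounds
                third = [h for h in herb_names if role_of[h] not in {role_of[m] for m in members}]
                if third:
                    members.add(third[rng.integers(0, len(third))])
        is_jun = any(role_of[m] is Role.JUN for m in members)
        ob = ob_base[i] + (cfg.jun_ob_shift if is_jun else 0.0)
        comp = Compound(
            id=f"Mol {i + 1}",
            name=f"compound-{i + 1:04d}",
            MW=float(mw[i]),
            nHdon=float(nhdon[i]),
            nHacc=float(nhacc[i]),
            AlogP=float(alogp[i]),
            OB=float(ob),
            DL=float(dl[i]),
            herbs=members,
        )
        compounds[comp.id] = comp
        for m in sorted(members):
            rows.append(
                {
                    "herb": m,
                    "role": role_of[m].value,
                    "compound_id": comp.id,
                    "name": comp.name,
                    "MW": comp.MW,
                    "nHdon": comp.nHdon,
                    "nHacc": comp.nHacc,
                    "AlogP": comp.AlogP,
                    "OB": comp.OB,
                    "DL": comp.DL,
                }
            )
    return set(herbs), compounds, pd.DataFrame(rows)


def _namespace(cfg: SyntheticConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(cfg.n_genes)]


def gen_ppi(cfg: SyntheticConfig) -> tuple[pd.DataFrame, list[str]]:
    """Preferential-attachment PPI with uniform confidences.

    The graph occupies a ``ppi_n``-gene slice of the ``n_genes`` symbol
    namespace, so downstream intersections with the (separately sampled)
    target universe are partial, as with real curated interactomes.  With
    attachment parameter m the edge count is m*(n-m), the same order as a
    dense hub-centric disease interactome.
    """
    rng = cfg._rng(1)
    g = nx.barabasi_albert_graph(cfg.ppi_n, cfg.ppi_m, seed=int(rng.integers(2**31)))
    names = sorted(
        rng.choice(_namespace(cfg), size=min(cfg.ppi_n, cfg.n_genes), replace=False)
    )
    conf = rng.uniform(cfg.conf_low, cfg.conf_high, g.number_of_edges())
    rows = [
        {"protein_a": names[u], "protein_b": names[v], "confidence": round(float(c), 4)}
        for (u, v), c in zip(g.edges(), conf)
    ]
    return pd.DataFrame(rows), names


def gen_targets(cfg: SyntheticConfig, ppi_nodes: list[str] | None = None) -> list[str]:
    """Target universe sampled from the full gene namespace."""
    rng = cfg._rng(2)
    pool = _namespace(cfg)
    k = min(cfg.n_targets, len(pool))
    return sorted(rng.choice(pool, size=k, replace=False).tolist())


def gen_assoc(
    cfg: SyntheticConfig, compounds: dict[str, Compound], targets: list[str]
) -> pd.DataFrame:
    """Compound-target associations with a truncated power-law out-degree
    and a handful of promiscuous hub targets drawing elevated in-degree."""
    rng = cfg._rng(3)
    targets = list(targets)
    weights = np.ones(len(targets))
    hub_idx = rng.choice(len(targets), size=min(cfg.n_hub_targets, len(targets)), replace=False)
    weights[hub_idx] = cfg.hub_target_weight
    weights = weights / weights.sum()
    rows = []
    for cid in compounds:
        deg = int(np.ceil(rng.pareto(cfg.assoc_exponent - 1.0) + 1.0))
        deg = min(deg, len(targets))
        chosen = rng.choice(len(targets), size=deg, replace=False, p=weights)
        for t in chosen:
            rows.append({"compound_id": cid, "target": targets[t]})
    return pd.DataFrame(rows).drop_duplicates(["compound_id", "target"]).reset_index(drop=True)


def gen_hubs(cfg: SyntheticConfig, ppi: pd.DataFrame) -> dict[str, list[str]]:
    """Disease hub genes sampled preferentially from high-degree PPI nodes,
    split across two curated-list-style sources with some overlap."""
    rng = cfg._rng(4)
    deg = pd.concat([ppi["protein_a"], ppi["protein_b"]]).value_counts()
    w = deg.to_numpy(dtype=float) ** 2
    hubs = rng.choice(deg.index.to_numpy(), size=min(cfg.n_hubs, len(deg)), replace=False, p=w / w.sum())
    hubs = sorted(hubs.tolist())
    split = max(1, len(hubs) * 2 // 3)
    return {"TTD-like": hubs[:split], "OMIM-like": hubs[split - max(1, len(hubs) // 5):]}


def gen_annotations(
    cfg: SyntheticConfig, targets: list[str], disease_targets: list[str]
) -> pd.DataFrame:
    """Gene-term edges: background terms sample the target universe
    uniformly; one planted term over-samples disease targets at
    ``planted_odds``.  Returned as a (gene, term) edge table; the planted
    term is named ``PLANTED``."""
    rng = cfg._rng(5)
    targets = list(targets)
    disease = set(disease_targets)
    rows = []
    for t in range(cfg.n_terms - 1):
        size = min(cfg.term_size, len(targets))
        genes = rng.choice(targets, size=size, replace=False)
        for g in genes:
            rows.append({"gene": g, "term": f"BP{t + 1:04d}"})
    w = np.array([cfg.planted_odds if g in disease else 1.0 for g in targets])
    size = min(cfg.term_size, len(targets))
    genes = rng.choice(targets, size=size, replace=False, p=w / w.sum())
    for g in genes:
        rows.append({"gene": g, "term": "PLANTED"})
    return pd.DataFrame(rows)


def gen_docking(cfg: SyntheticConfig, assoc: pd.DataFrame) -> pd.DataFrame:
    """Docking score table over the association pairs.

    Reference (original-ligand) scores per target ~ Normal(100, 10);
    candidate scores sit above the reference for roughly
    ``dock_above_fraction`` of pairs.
    """
    rng = cfg._rng(6)
    refs = {
        t: float(rng.normal(100.0, 10.0)) for t in sorted(assoc["target"].unique())
    }
    above = rng.random(len(assoc)) < cfg.dock_above_fraction
    rows = []
    for (_, r), hi in zip(assoc.iterrows(), above):
        ref = refs[r["target"]]
        score = ref + abs(rng.normal(8.0, 5.0)) * (1 if hi else -1)
        rows.append(
            {
                "compound_id": r["compound_id"],
                "target": r["target"],
                "libdock_score": round(score, 2),
                "reference_score": round(ref, 2),
            }
        )
    return pd.DataFrame(rows)


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate the full input bundle for one seed."""
    herbs, compounds, formulary = gen_formulary(cfg)
    ppi, ppi_nodes = gen_ppi(cfg)
    targets = gen_targets(cfg, ppi_nodes)
    assoc = gen_assoc(cfg, compounds, targets)
    hub_lists = gen_hubs(cfg, ppi)
    # disease targets for annotation ground truth: targets adjacent to hubs
    hub_set = {h for lst in hub_lists.values() for h in lst}
    adj = set(ppi[ppi["protein_a"].isin(hub_set)]["protein_b"]) | set(
        ppi[ppi["protein_b"].isin(hub_set)]["protein_a"]
    )
    disease_targets = sorted((adj | hub_set) & set(targets))
    annotation = gen_annotations(cfg, targets, disease_targets)
    docking = gen_docking(cfg, assoc)
    return SyntheticBundle(
        herbs=herbs,
        compounds=compounds,
        formulary=formulary,
        assoc=assoc,
        ppi=ppi,
        hub_lists=hub_lists,
        annotation=annotation,
        docking=docking,
        targets=targets,
        disease_targets=disease_targets,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the pipeline reads; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "formulary": outdir / "formulary.tsv",
        "assoc": outdir / "associations.tsv",
        "ppi": outdir / "ppi.tsv",
        "annotation": outdir / "annotation.tsv",
        "docking": outdir / "docking.tsv",
    }
    bundle.formulary.to_csv(paths["formulary"], sep="\t", index=False)
    bundle.assoc.to_csv(paths["assoc"], sep="\t", index=False)
    bundle.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    bundle.docking.to_csv(paths["docking"], sep="\t", index=False)
    for tag, symbols in bundle.hub_lists.items():
        p = outdir / f"hubs_{tag.replace('-', '_').lower()}.txt"
        p.write_text("\n".join(symbols) + "\n")
        paths[f"hubs_{tag}"] = p
    return paths
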