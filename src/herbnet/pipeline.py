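"""End-to-end pipeline: screen -> role sets -> disease network -> tripartite
network -> disease restriction -> centrality -> target-process network ->
enrichment -> optional docking filter, with a run report whose counts are
recomputable from the written output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, disease, io, netcore, role_sets, stats
from .adme import ScreenConfig, group_descriptor_stats, screen_compounds
from .io import Role

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    formulary: str | Path
    assoc: str | Path
    ppi: str | Path | None = None
    hub_lists: dict[str, str | Path] = field(default_factory=dict)
    annotation: str | Path | None = None
    docking: str | Path | None = None
    outdir: str | Path = "herbnet_out"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    conf_min: float = 0.4
    top_k: int = 10
    sep: str = "\t"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        screen = raw.pop("screen", {})
        if isinstance(screen.get("whitelist"), list):
            screen["whitelist"] = frozenset(screen["whitelist"])
        return cls(screen=ScreenConfig(**screen), **raw)


@dataclass
class RunReport:
    counts: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    config: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "counts": self.counts,
                    "warnings": self.warnings,
                    "config": self.config,
                },
                indent=2,
                default=str,
            )
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={"conf_min": cfg.conf_min, "top_k": cfg.top_k,
                               "ob_min": cfg.screen.ob_min, "dl_min": cfg.screen.dl_min})
    counts = report.counts

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- ingest & screen -------------------------------------------------
        herbs, compounds = _stage("read_formulary")(io.read_formulary)(
            cfg.formulary, sep=cfg.sep
        )
        assoc_all = _stage("read_associations")(io.read_edge_list)(
            cfg.assoc, "association", sep=cfg.sep
        )
        counts["herbs"] = len(herbs)
        counts["compounds_total"] = len(compounds)

        passed, audit = _stage("screen")(screen_compounds)(compounds, cfg.screen)
        audit.to_csv(outdir / "screen_audit.tsv", sep="\t", index=False)
        counts["compounds_screened"] = len(passed)

        role_of = {h.name: h.role for h in herbs}
        gstats = _stage("descriptor_stats")(group_descriptor_stats)(passed, role_of)
        gstats.summary.to_csv(outdir / "table1_descriptors.tsv", sep="\t", index=False)
        gstats.anova.to_csv(outdir / "table1_anova.tsv", sep="\t", index=False)
        report.warnings += gstats.warnings

        # --- role sets & Venn ------------------------------------------------
        assoc = assoc_all[assoc_all["compound_id"].isin(passed)].reset_index(drop=True)
        counts["associations"] = len(assoc)
        role_c = role_sets.role_set_of_compounds(passed, herbs)
        role_t = role_sets.role_set_of_targets(assoc, role_c)
        venn_c = role_sets.venn7(
            role_c[Role.JUN], role_c[Role.CHEN], role_c[Role.ZUO_SHI], kind="compound"
        )
        venn_t = role_sets.venn7(
            role_t[Role.JUN], role_t[Role.CHEN], role_t[Role.ZUO_SHI], kind="target"
        )
        venn_c.to_frame().to_csv(outdir / "fig3_venn_compounds.tsv", sep="\t", index=False)
        venn_t.to_frame().to_csv(outdir / "fig3_venn_targets.tsv", sep="\t", index=False)
        counts["venn_compound_regions"] = venn_c.sizes()
        counts["venn_target_regions"] = venn_t.sizes()
        counts["targets_total"] = len(venn_t.universe)
        counts["role_target_sizes"] = {r.value: len(role_t[r]) for r in Role}

        # --- tripartite network ---------------------------------------------
        hbcct = _stage("build_hbcct")(netcore.build_hbcct)(herbs, passed, assoc)
        io.write_graph(hbcct, outdir / "hbcct.graphml", "graphml")
        io.write_graph(hbcct, outdir / "hbcct", "tsv")
        counts["hbcct_nodes"] = hbcct.number_of_nodes()
        counts["hbcct_edges"] = hbcct.number_of_edges()
        cent = netcore.centrality_table(hbcct)
        cent.to_csv(outdir / "hbcct_centrality.tsv", sep="\t", index=False)
        comp_records = cent[cent["nodetype"] == netcore.COMPOUND]
        targ_records = cent[cent["nodetype"] == netcore.TARGET]
        netcore.top_k(comp_records, "degree", cfg.top_k).to_csv(
            outdir / "table2_compound_centrality.tsv", sep="\t", index=False
        )
        netcore.top_k(targ_records, "degree", cfg.top_k).to_csv(
            outdir / "table3_target_centrality.tsv", sep="\t", index=False
        )

        # --- disease network -------------------------------------------------
        disease_targets: set[str] = set()
        if cfg.ppi and cfg.hub_lists:
            if not Path(cfg.ppi).exists():
                raise StageError(f"stage 'disease_network' failed: missing PPI file {cfg.ppi}")
            ppi_df = _stage("read_ppi")(io.read_edge_list)(cfg.ppi, "ppi", sep=cfg.sep)
            lists = {
                tag: Path(p).read_text().split() for tag, p in cfg.hub_lists.items()
            }
            hubs = _stage("collect_hubs")(disease.collect_hubs)(lists)
            report.warnings += hubs.warnings
            ppi_g = disease.ppi_graph(ppi_df)
            dnet = _stage("expand_first_neighbors")(disease.expand_first_neighbors)(
                hubs, ppi_g, cfg.conf_min
            )
            io.write_graph(dnet, outdir / "disease_ppi.graphml", "graphml")
            counts["hubs"] = len(hubs.hubs)
            counts["disease_net_nodes"] = dnet.number_of_nodes()
            counts["disease_net_edges"] = dnet.number_of_edges()
            dcent = netcore.centrality_table(dnet)
            netcore.top_k(dcent, "degree", cfg.top_k).to_csv(
                outdir / "table4_disease_centrality.tsv", sep="\t", index=False
            )
            disease_targets = set(dnet.nodes())

            # --- restriction to disease targets -----------------------------
            hbpcpt = _stage("restrict_to_disease")(netcore.restrict_to_disease)(
                hbcct, disease_targets
            )
            io.write_graph(hbpcpt, outdir / "hbpcpt.graphml", "graphml")
            counts["disease_restricted_nodes"] = hbpcpt.number_of_nodes()
            counts["disease_restricted_compounds"] = sum(
                1 for _, d in hbpcpt.nodes(data=True) if d["nodetype"] == netcore.COMPOUND
            )
            counts["disease_restricted_targets"] = sum(
                1 for _, d in hbpcpt.nodes(data=True) if d["nodetype"] == netcore.TARGET
            )
            if hbpcpt.number_of_nodes():
                rc = netcore.centrality_table(hbpcpt)
                netcore.top_k(
                    rc[rc["nodetype"] == netcore.COMPOUND], "degree", cfg.top_k
                ).to_csv(outdir / "table6_disease_compounds.tsv", sep="\t", index=False)
                netcore.top_k(
                    rc[rc["nodetype"] == netcore.TARGET], "degree", cfg.top_k
                ).to_csv(outdir / "table7_disease_targets.tsv", sep="\t", index=False)

        # --- annotation: pT-F network + enrichment ---------------------------
        if cfg.annotation:
            ann_edges = _stage("read_annotation")(io.read_edge_list)(
                cfg.annotation, "annotation", sep=cfg.sep
            )
            restricted_targets = (
                {n for n, d in hbpcpt.nodes(data=True) if d["nodetype"] == netcore.TARGET}
                if disease_targets
                else set(targ_records["node"])
            )
            ptf = _stage("build_pt_f")(netcore.build_pt_f)(restricted_targets, ann_edges)
            io.write_graph(ptf, outdir / "ptf.graphml", "graphml")
            counts["ptf_nodes"] = ptf.number_of_nodes()
            counts["ptf_edges"] = ptf.number_of_edges()

            ann = stats.AnnotationCollection.from_edges(ann_edges)
            query = set(restricted_targets) & set(ann.universe)
            if query:
                enr = _stage("enrichment")(stats.hypergeom_enrich)(query, ann)
                enr.to_csv(outdir / "table5_enrichment.tsv", sep="\t", index=False)
                counts["enriched_terms_fdr05"] = int((enr["fdr"] < 0.05).sum())

        # --- docking filter ---------------------------------------------------
        if cfg.docking:
            dock = _stage("read_docking")(io.read_edge_list)(cfg.docking, "docking", sep=cfg.sep)
            kept = _stage("docking_filter")(netcore.docking_filter)(dock)
            kept.to_csv(outdir / "ct_network_edges.tsv", sep="\t", index=False)
            counts["docking_pairs_total"] = len(dock)
            counts["docking_pairs_retained"] = len(kept)

        report.warnings += [str(w.message) for w in caught]

    _check_conservation(counts)
    report.to_json(outdir / "report.json")
    return report


def _check_conservation(counts: dict) -> None:
    """Internal consistency: Venn regions sum to their universes."""
    for key, total_key in (
        ("venn_compound_regions", None),
        ("venn_target_regions", "targets_total"),
    ):
        if key in counts:
            s = sum(counts[key].values())
            if total_key and s != counts[total_key]:
                raise AssertionError(f"{key} regions sum {s} != universe {counts[total_key]}")
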