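# herbnet

Network-pharmacology analysis of multi-herb formulas against a disease
protein set. The package implements, as a tested and reusable pipeline, the
analysis chain used to study how a classical multi-herb prescription acts on
a disease through many compounds hitting many targets:

1. **ADME screening** — compounds are kept when oral bioavailability
   OB ≥ 30 % and drug-likeness DL ≥ 0.18 (both inclusive), with an explicit
   whitelist for literature-supported exceptions. The drug-likeness index is
   the Tanimoto similarity between a compound's descriptor vector *x* and the
   average reference-library vector *y*:

   T(x, y) = x·y / (|x|² + |y|² − x·y)

2. **Herb-role set decomposition** — herbs carry one of the classical roles
   monarch (Jun), minister (Chen), or adjuvant/guide (Zuo-Shi); compounds and
   the targets they hit are decomposed into the seven disjoint overlap
   regions of the three role groups (a three-set Venn analysis), and the six
   molecular descriptors (MW, nHdon, nHacc, AlogP, OB, DL) are compared
   across roles by one-way ANOVA with unadjusted pairwise t-tests.

3. **Disease protein network** — curated disease-gene lists are unioned into
   hub proteins and expanded one hop through a confidence-weighted PPI graph;
   the induced subgraph (neighbor–neighbor edges kept) is the disease-specific
   interaction network.

4. **Network centrality** — the tripartite herb–compound–target network, its
   restriction to disease targets, the disease PPI network, the bipartite
   target–process network, and the docking-validated compound–target network
   are ranked by degree (all incident edges, so a compound's degree equals
   its herb memberships plus its target associations) and by shortest-path
   betweenness normalized by (n−1)(n−2)/2.

5. **Enrichment** — hypergeometric over-representation of a target set
   within annotation terms, P(X ≥ k) for X ~ Hypergeom(N, K, n), with
   Benjamini–Hochberg FDR control.

6. **Docking retention rule** — a (compound, target) pair from an ingested
   docking-score table is retained iff its score strictly exceeds the
   target's original-ligand reference score.

A seeded synthetic-data generator (`herbnet.synth`) produces every input the
pipeline reads — role-structured formulary with a planted monarch-role OB
shift, heavy-tailed compound–target associations, a scale-free PPI, disease
hubs, annotations with one planted enriched term, docking scores — so the
whole analysis runs and is tested entirely offline.

Intended users: computational systems-biology and cheminformatics
researchers who have formulary/association/PPI/annotation tables (e.g.
TCMSP-, STRING-, or GO-style extracts) and want a reproducible, auditable
version of this analysis rather than a chain of manual database exports.

## Worked example

Generate a synthetic input bundle and run the full pipeline:

```bash
herbnet synth all --seed 7 --out inputs
cat > run.yaml <<EOF
formulary: inputs/formulary.tsv
assoc: inputs/associations.tsv
ppi: inputs/ppi.tsv
hub_lists:
  ttd: inputs/hubs_ttd_like.txt
  omim: inputs/hubs_omim_like.txt
annotation: inputs/annotation.tsv
docking: inputs/docking.tsv
outdir: out
EOF
herbnet run --config run.yaml
```

This prints (abridged):

```
herbs: 11
compounds_total: 162
compounds_screened: 141
targets_total: 285
hbcct_nodes: 437
hbcct_edges: 1725
hubs: 21
disease_net_nodes: 379
disease_net_edges: 2910
disease_restricted_compounds: 65
disease_restricted_targets: 45
enriched_terms_fdr05: 1
docking_pairs_total: 1804
docking_pairs_retained: 654
```

Reading: of 162 formulary compounds, 141 pass the OB/DL gate; they hit 285
targets, forming a 437-node tripartite network. The 21 disease hub genes
expand through the PPI into a 379-node disease network; restricting the
tripartite network to its targets leaves 65 compounds acting on 45
disease-specific targets. Exactly one annotation term — the generator's
planted one — is enriched at FDR < 0.05 (`out/table5_enrichment.tsv` shows
it with k = 19 of K = 30 term genes hit by the 45-target query,
FDR ≈ 1.5 × 10⁻⁸), and 654 of 1804 docking pairs beat their reference
ligand and form the validated compound–target network. Every table
(`table1_descriptors.tsv` … `table7_disease_targets.tsv`,
`fig3_venn_*.tsv`), the GraphML/SIF networks, and `report.json` land in
`out/`; all counts in the report are recomputable from the written files.

The same steps are available individually (`herbnet screen`,
`herbnet disease-net`, `herbnet enrich`) and as library functions
(`herbnet.adme`, `herbnet.role_sets`, `herbnet.disease`, `herbnet.netcore`,
`herbnet.stats`).

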