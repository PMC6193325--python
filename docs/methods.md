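# Methods

## The analysis model

The pipeline treats a multi-herb formula as a tripartite system: herbs
contain compounds (membership edges) and compounds act on protein targets
(association edges). Disease relevance enters through a separate protein
interaction layer: curated disease genes seed a one-hop expansion in a
confidence-weighted PPI graph, and the tripartite network is restricted to
the targets appearing in that disease network. Importance at every level is
read off two centralities, and the biological interpretation of the
disease-specific target set comes from hypergeometric over-representation
against annotation terms.

Assumptions worth stating explicitly:

- **Compound identity is chemical-name based.** The same chemical listed
  under several herbs is one node with several memberships (merged
  case-insensitively; the first record's descriptors win, with a warning on
  disagreement). Overlap counts between herb-role groups are only meaningful
  under this merge.
- **Role groups overlap.** A compound contained in herbs of several roles
  belongs to each role's group, both for the Venn decomposition and for the
  descriptor statistics; group sizes therefore sum to more than the number
  of distinct compounds.
- **PPI edges are undirected**, confidence in [0, 1], duplicates collapsed
  keeping the maximum confidence, self-loops dropped.
- **Associations are consumed, not predicted.** Target prediction is outside
  the package; the association table is an input.

## Screening

A compound passes iff (OB ≥ `ob_min` AND DL ≥ `dl_min`) OR its name is
whitelisted. Defaults: `ob_min` = 30 (percent), `dl_min` = 0.18 (unitless),
whitelist = {amygdalin, hydroxysafflor yellow A}. Thresholds are inclusive.
The audit table records which clause admitted each compound. The Tanimoto
drug-likeness index `tanimoto_dl` is provided as a recomputation utility;
the pipeline trusts the DL column of the input table by default because the
descriptor composition entering the reference comparison is a modelling
choice of whoever produced the table.

## Centrality conventions

- **Degree** counts all incident edges of the typed graph. Consequently a
  compound's degree decomposes exactly as (# herbs containing it) +
  (# targets it hits); this identity is asserted network-wide in the tests.
- **Betweenness** is shortest-path betweenness on the undirected graph,
  normalized by (n−1)(n−2)/2 with n the whole graph's node count; pair
  contributions accrue only within connected components. This is the
  Cytoscape-compatible convention and keeps values in [0, 1]. The
  implementation is Brandes' algorithm (networkx); the test suite checks it
  against an independent brute-force enumeration of all shortest paths on
  random graphs of up to 12 nodes.
- **Rankings** sort descending by the chosen indicator, breaking ties by the
  other indicator (descending) and then lexicographically by label, so
  top-k tables are deterministic and stable under row shuffling.
- Targets with no association edge are not instantiated as nodes: networks
  are defined by their edges.

## Disease network construction

Hub lists are unioned with per-symbol source tags. Expansion is fixed at
first neighbors: nodes = hubs ∪ {proteins adjacent to a hub through an edge
of confidence ≥ `conf_min`}, edges = all sufficiently confident PPI edges
among retained nodes (induced subgraph — neighbor–neighbor edges are kept,
which is what makes the resulting network dense rather than a star forest).
Default `conf_min` = 0.4, the conventional "medium confidence" cut for
STRING-style scores. Hubs absent from the PPI are kept as isolated,
flagged nodes rather than silently dropped.

## Enrichment

Over-representation only: for a query of n genes in a universe of N, a term
with K genes and k query hits scores P(X ≥ k), X ~ Hypergeom(N, K, n),
computed with scipy's survival function. An EASE-style conservative variant
(score k−1) is available behind a flag and off by default. FDR is
Benjamini–Hochberg (statsmodels), input order preserved. The background
universe defaults to all genes appearing in the annotation collection and
is configurable; with a different background the absolute p-values shift,
which is why externally produced enrichment tables are not comparable
without knowing their background.

Because the hypergeometric tail is discrete, the attained level of the test
is below nominal for small terms and queries. The null-calibration check
therefore uses term size 200 and query size 300 in a 1000-gene universe,
where the attained level (~0.036–0.04) sits inside the 0.05 ± 0.02 band; at
small term sizes the test is simply conservative, never anticonservative.

## ANOVA and pairwise tests

Descriptor comparisons across the three role groups use classical one-way
ANOVA (between/within mean-square ratio, p from F with (g−1, Σnᵢ−g) df).
Zero between-group variance returns F = 0, p = 1 even when the within-group
variance is also zero. Pairwise comparisons are pooled-variance two-sample
t-tests, unadjusted, with Welch's correction behind a flag — mirroring how
such role-wise descriptor contrasts are conventionally reported (raw
pairwise p-values). Roles with fewer than two member compounds are excluded
from testing with a warning.

## Docking retention

Strictly greater than the per-target reference (original-ligand) score:
ties are dropped. Every listed target must carry exactly one reference
score; violations are data errors, not warnings.

## Synthetic data: what it emulates and what it does not

The generator draws, from one global seed split into independent
sub-streams:

| feature | default | what it emulates |
|---|---|---|
| herbs per role | 2 / 3 / 6 | an 11-herb formula's role structure |
| compounds | 162 | formulary scale |
| MW | Normal(370, 90), floored | drug-like mass range (daltons) |
| nHdon / nHacc | Poisson(2.5) / Poisson(5.4) | H-bond descriptor counts |
| AlogP | Normal(3.3, 2.5) | lipophilicity spread |
| DL | Beta(4.8, 5.2) | drug-likeness, mean ≈ 0.48 |
| OB | Normal(47, 15) + 8 for monarch-herb members, floored at 0 | percent bioavailability with a role contrast of the magnitude seen in role-annotated formularies |
| multi-role fraction | 0.06 | compounds shared across role groups (populates Venn intersections) |
| association out-degree | truncated Pareto, exponent 1.8 | a few promiscuous compounds dominate |
| hub targets | 8 at weight 30 | promiscuous proteins with elevated in-degree |
| PPI | preferential attachment, n = 500, m = 12 | dense hub-centric interactome, ~5.9 k edges |
| gene namespace | 2000 symbols | the PPI and the 285-target universe are partially overlapping slices, so the disease∩target intersection lands near one-sixth of the universe rather than engulfing it |
| disease hubs | 21, degree²-preferential | curated disease-gene lists split across two tagged sources |
| annotation | 30 terms × 30 genes; one planted term over-samples disease targets at odds 20 | ground truth for the enrichment stage |
| docking | reference ~ Normal(100, 10); ~35 % of pairs above reference | score table for the retention rule |

Not emulated: real chemistry (names and descriptors are independent draws),
gene-symbol aliasing, annotation term overlap structure, PPI confidence
correlated with topology, and any database-version effects. Passing tests
on synthetic data therefore demonstrate the correctness and calibration of
the *procedures* — set algebra, graph construction, centrality, the gate,
the statistics — not the biological conclusions any particular database
snapshot would yield.

## Verification design and problem sizes

- Betweenness and hypergeometric p-values are checked against independent
  brute-force oracles (explicit shortest-path enumeration; exhaustive
  subset enumeration) on inputs small enough for exhaustion (≤ 12 nodes /
  N ≤ 12), at 1,000 and 30 random cases respectively in the test suite.
- Recovery of the planted monarch-role OB shift averages the Jun-minus-Chen
  group-mean difference over 20 seeded draws of 500 compounds. A single
  500-compound draw has a sampling standard error near 2 OB points for this
  contrast, so the check targets the estimator's accuracy in expectation
  rather than lottery behaviour of one draw.
- Planted-term detection runs 200 seeded annotation collections; with the
  default odds the planted term is essentially always first at FDR < 0.05.
- The full-pipeline check cross-validates every reported count against a
  recomputation from the written output files.

## Known limitations

- No gene-alias resolution: symbols are uppercased and stripped, nothing
  more. Inputs using mixed nomenclatures must be harmonized upstream.
- The merge-on-name rule keeps the first descriptor record on conflict; a
  formulary with genuinely different stereoisomers under one name will be
  collapsed.
- Betweenness normalization uses the whole graph's n even when the graph is
  disconnected; values are comparable within one network, not across
  networks of different size.
- Enrichment is over-representation only; depletion is out of scope.
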