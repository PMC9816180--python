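# scdrugnet

A single-cell-led network pipeline for drug repurposing in multi-cell-type
brain disease, built around three steps:

1. **Disease-gene scoring.** Evidence sub-sources (genetics: GWAS gene-level
   associations by genomic proximity and eQTL mapping plus cell-specific
   functional genomics; expression: per-cell-type differential expression;
   literature: curated disease gene sets) are collapsed to a 0/1 indicator per
   category.  A gene's score is

   `final = Σ_c I_c + (1 − G(I))`,

   where `I ∈ {0,1}³` is the category indicator and `G` the unbiased Gini
   index, so evidence spread across categories is rewarded (diversification).
   Genes supported only by genomic proximity to a risk locus — bystanders
   under linkage disequilibrium — are not counted as disease genes.
2. **Multicellular disease network.** Per cell type, confidence-filtered
   protein–protein interactions are merged with TF→gene regulatory edges and
   restricted to expressed genes; walktrap community detection (iterated on
   modules > 500 genes) yields network modules, each tested for disease-gene
   enrichment with a one-sided Fisher exact test, BH-corrected per network
   (`p_adj < 0.05` ⇒ disease module).  Significant ligand–receptor pairs then
   wire the disease modules across cell types into a weighted module graph;
   the *core* modules are those both highly enriched and central (closeness
   centrality `CC(v) = (n−1)/Σ_u d(v,u)`).
3. **Proximity screen.** Per drug target and cell network, a drug module =
   target ∪ top-100 up/down signature genes mapped into the network ∪
   shortest-path connector genes (modules < 10 genes discarded).  Against each
   core disease module `T`, the screen computes the average closest distance
   `d_c(S,T) = mean_s min_t d(s,t)` and the best-match-average GO-BP Jaccard
   similarity, standardizes both against degree-matched random gene sets
   (log2-degree bins, 1000 permutations), and combines them as
   `z = z_dist + z_dissim` — lower means closer *and* more functionally
   similar — with an add-one empirical p-value.  Candidates whose target is
   HPA-specific for a non-brain tissue are excluded (immune tissues are
   tolerated for microglia candidates).

Because the real inputs (snRNA-seq, GWAS summary statistics, interaction
databases, LINCS signatures) cannot ship with a package, `scdrugnet` includes
a first-class synthetic generator that emulates all upstream tool outputs with
planted ground truth — stochastic-block-model communities, evidence tables
enriched in planted disease blocks, ligand–receptor pairs wiring them, and
drugs planted near (positives) or anywhere (decoys) — so every stage is
testable end to end.

## Worked example

```bash
scdrugnet run-all --seed 7 --out out/
```

runs the whole pipeline on the default synthetic conditions (6 cell types ×
300 genes, 5 blocks per cell type with 2 disease-enriched, 10 planted
proximal drugs vs 90 decoys, 1000 permutations).  Selected real output:

`out/module_stats.OLI.tsv` — both planted disease blocks are recovered as
significantly enriched modules, the three background blocks are not:

```
module_id  n_genes  n_AD  p          p_adj      is_AD_module
m_1        60       60    1.82e-14   4.55e-14   True
m_2        60       60    1.82e-14   4.55e-14   True
m_3        59       19    0.9999     0.9999     False
```

`out/multicell_nodes.tsv` — disease modules wired by ligand–receptor pairs
are central; the per-cell "other" nodes are peripheral; the core set is the
high-closeness, highly enriched quadrant:

```
node      cell  module_id  is_other  p_adj     closeness  is_core
EX:m_1    EX    m_1        False     2.50e-16  0.933      True
EX:other  EX    other      True                0.0        False
```

`out/screen_results.tsv` — per (drug, target, cell, core module):
`d_closest` (hops), `go_sim`, the combined z and its empirical p.  A planted
proximal drug typically scores `combined_z ≈ −21, p = 1/1001`, a decoy
`combined_z ≈ 0, p ≈ uniform`.  `out/candidates.tsv` aggregates the
significant pairs per (drug, target) and applies the tissue filter, e.g.

```
drug      target  cells      modules                excluded_by_tissue_filter
DRUGD006  G0109   EX,IN,MIC  EX:m_1,IN:m_1,MIC:m_1  False
```

(decoys that happen to target planted disease-block genes are genuinely
proximal and legitimately significant).

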